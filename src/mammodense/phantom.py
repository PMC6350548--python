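"""Synthetic mammogram phantoms with exact ground-truth tumor masks.

A phantom emulates the gross statistical structure of a digital
mammogram: a dark background, a bright half-elliptical breast region
with smooth multiscale parenchymal texture, an optional brighter
pectoral wedge in one corner (MLO-like), and one or more tumors
rendered as rotated ellipses with lobulated (radially perturbed)
boundaries, slightly brighter than the surrounding tissue.  Tumor
diameters are drawn from a configured range that maps the 200-800 px
interval observed at full 4096-px resolution proportionally onto the
phantom canvas.

Phantoms are test doubles: they reproduce the class imbalance and the
low tumor/tissue contrast that motivate inverse-frequency loss
weighting, not the radiographic physics of real mammograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .mammo_io import MANIFEST_COLUMNS

#: tumor height/width interval at the clinical 4096-px resolution
CLINICAL_SIZE_RANGE = (200, 800)
CLINICAL_CANVAS = 4096


def scaled_size_range(canvas_side: int) -> tuple[float, float]:
    """Map the clinical 200-800 px tumor interval onto a canvas size."""
    lo, hi = CLINICAL_SIZE_RANGE
    return (lo * canvas_side / CLINICAL_CANVAS,
            hi * canvas_side / CLINICAL_CANVAS)


@dataclass
class PhantomConfig:
    canvas_side: int = 1024
    tumor_size_range: tuple[float, float] | None = None
    n_tumors: int | tuple[int, int] = 1
    tumor_contrast: float = 0.2
    texture_scale: float = 0.06
    include_pectoral: bool = False
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.tumor_size_range is None:
            self.tumor_size_range = scaled_size_range(self.canvas_side)
        lo, hi = self.tumor_size_range
        if not (0 < lo <= hi < self.canvas_side):
            raise ValueError(
                f"tumor_size_range {self.tumor_size_range} must satisfy "
                f"0 < min <= max < canvas_side")
        if self.tumor_contrast < 0:
            raise ValueError("tumor_contrast must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Phantom:
    image: np.ndarray
    mask: np.ndarray
    tumor_specs: list[dict] = field(default_factory=list)
    view_like: str = "CC"


def _breast_region(side: int, rng) -> np.ndarray:
    """Half-ellipse anchored to the left edge, mildly randomized."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    cy = side * rng.uniform(0.45, 0.55)
    ry = side * rng.uniform(0.40, 0.48)
    rx = side * rng.uniform(0.70, 0.85)
    return ((yy - cy) / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def _pectoral_wedge(side: int, rng) -> np.ndarray:
    """Triangular wedge in the top-left corner (pectoral muscle analog)."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    y_int = side * rng.uniform(0.35, 0.5)
    x_int = side * rng.uniform(0.25, 0.4)
    return (yy / y_int + xx / x_int) <= 1.0


def _texture(side: int, rng, amplitude: float) -> np.ndarray:
    """Sum of 3 octaves of smoothed noise, zero-mean, bounded amplitude."""
    tex = np.zeros((side, side))
    for sigma_frac, weight in ((0.08, 1.0), (0.03, 0.5), (0.012, 0.25)):
        layer = ndimage.gaussian_filter(rng.standard_normal((side, side)),
                                        sigma=max(1.0, side * sigma_frac))
        peak = np.abs(layer).max()
        if peak > 0:
            tex += weight * layer / peak
    peak = np.abs(tex).max()
    return amplitude * tex / peak if peak > 0 else tex


def _render_tumor(side: int, rng, size_range, allowed: np.ndarray):
    """One lobulated elliptical tumor placed inside ``allowed``.

    Returns (indicator mask, spec dict) or None when the size/placement
    draw lands outside the configured bounding-box range.
    """
    lo, hi = size_range
    amp = rng.uniform(0.05, 0.15)
    # guarantee the minor-axis extent stays above lo despite perturbation
    dmaj_min = min(lo * (1 + amp) / (1 - amp), hi - 2 if hi > lo + 2 else hi)
    dmaj = rng.uniform(dmaj_min, max(dmaj_min, hi - 2))
    a = dmaj / 2.0 / (1 + amp)
    q_lo = min(1.0, lo * (1 + amp) / ((1 - amp) * dmaj))
    q = rng.uniform(max(q_lo, 0.6), 1.0) if q_lo < 1.0 else 1.0
    b = q * a
    theta = rng.uniform(0, np.pi)
    # lobulation: low-order radial harmonics, total amplitude <= amp
    orders = rng.integers(2, 6, size=2)
    coeffs = rng.uniform(0.2, 1.0, size=2)
    coeffs *= amp / coeffs.sum()
    phases = rng.uniform(0, 2 * np.pi, size=2)

    margin = int(np.ceil(dmaj / 2)) + 2
    interior = ndimage.distance_transform_edt(allowed) > margin
    candidates = np.argwhere(interior)
    if len(candidates) == 0:
        return None
    cy, cx = candidates[rng.integers(len(candidates))]

    sl = (slice(max(0, cy - margin), min(side, cy + margin + 1)),
          slice(max(0, cx - margin), min(side, cx + margin + 1)))
    yy, xx = np.mgrid[sl].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    phi = np.arctan2(v, u)
    rho = 1.0
    for m, c, ph in zip(orders, coeffs, phases):
        rho = rho + c * np.sin(m * phi + ph)
    local = (u / a) ** 2 + (v / b) ** 2 <= rho ** 2
    indicator = np.zeros((side, side), dtype=bool)
    indicator[sl] = local
    ys, xs = np.nonzero(indicator)
    if len(ys) == 0:
        return None
    bbox = (ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    if not (lo <= bbox[0] <= hi and lo <= bbox[1] <= hi):
        return None
    spec = {"center": (int(cy), int(cx)), "axes": (float(a), float(b)),
            "rotation": float(theta), "bbox": bbox}
    return indicator, spec


def generate_phantom(cfg: PhantomConfig, seed: int | None = None) -> Phantom:
    """Render one paired (image, mask) phantom, reproducible given seed."""
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    side = cfg.canvas_side

    breast = _breast_region(side, rng)
    image = np.full((side, side), 0.05)
    image[breast] = 0.45
    image += breast * _texture(side, rng, cfg.texture_scale)
    view_like = "CC"
    if cfg.include_pectoral:
        wedge = _pectoral_wedge(side, rng) & breast
        image[wedge] += 0.15
        view_like = "MLO"

    if isinstance(cfg.n_tumors, tuple):
        n_tumors = int(rng.integers(cfg.n_tumors[0], cfg.n_tumors[1] + 1))
    else:
        n_tumors = int(cfg.n_tumors)

    mask = np.zeros((side, side), dtype=np.uint8)
    specs = []
    for _ in range(n_tumors):
        rendered = None
        for _attempt in range(100):
            rendered = _render_tumor(side, rng, cfg.tumor_size_range, breast)
            if rendered is not None:
                break
        if rendered is None:
            raise RuntimeError(
                "could not place a tumor inside the breast region after "
                "100 attempts; size range too large for the canvas?")
        indicator, spec = rendered
        spec["contrast"] = cfg.tumor_contrast
        # soft-edged intensity bump; the mask stays the exact support
        bump = ndimage.gaussian_filter(indicator.astype(np.float64), 1.0)
        image += cfg.tumor_contrast * bump
        mask |= indicator.astype(np.uint8)
        specs.append(spec)

    if cfg.noise_sd > 0:
        image += rng.normal(0.0, cfg.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return Phantom(image=image, mask=mask, tumor_specs=specs,
                   view_like=view_like)


def generate_dataset(n: int, cfg: PhantomConfig, seed: int,
                     out_dir=None):
    """Generate ``n`` phantoms with independent per-item seeds.

    Returns ``(phantoms, manifest_rows)``; when ``out_dir`` is given the
    images (8-bit PNG), masks ({0, 255} PNG) and a manifest CSV are also
    written there, reproducibly for a fixed (cfg, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n)]
    phantoms = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(child_seeds):
        ph = generate_phantom(cfg, seed=s)
        phantoms.append(ph)
        sample_id = f"phantom_{i:04d}"
        img_path = mask_path = ""
        if out_dir is not None:
            img_path = str(out_dir / f"{sample_id}.png")
            mask_path = str(out_dir / f"{sample_id}_mask.png")
            Image.fromarray(
                np.round(ph.image * 255).astype(np.uint8)).save(img_path)
            Image.fromarray((ph.mask * 255).astype(np.uint8)).save(mask_path)
        rows.append({"sample_id": sample_id, "image_path": img_path,
                     "mask_path": mask_path, "view": ph.view_like,
                     "patient_id": sample_id, "split": ""})
    if out_dir is not None:
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
            out_dir / "manifest.csv", index=False)
    return phantoms, rows


def tumor_size_summary(phantoms, bins=10):
    """Histogram of per-tumor mask bounding-box sides (max side each).

    Tumors are recovered from the masks by 8-connected component
    labeling, so the summary verifies what the masks actually contain.
    """
    phantoms = list(phantoms)
    if not phantoms:
        raise ValueError("no phantoms given")
    sides = []
    structure = np.ones((3, 3), dtype=int)
    for ph in phantoms:
        labeled, n = ndimage.label(ph.mask, structure=structure)
        for sl_y, sl_x in ndimage.find_objects(labeled):
            sides.append(max(sl_y.stop - sl_y.start, sl_x.stop - sl_x.start))
    if not sides:
        return np.array([], dtype=int), np.array([])
    counts, edges = np.histogram(sides, bins=bins)
    return counts, edges
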