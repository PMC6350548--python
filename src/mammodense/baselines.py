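"""Classical comparison segmentation: double thresholding and
small-connected-region removal.

The double-threshold scheme first finds a global threshold by the
iterative (ISODATA/Ridler-Calvard) scheme — the fixed point of
t <- (mean below t + mean above t) / 2 — then uses the mean intensity of
the first-pass region as a second, higher threshold applied to the
whole image.  Isolated small connected regions are then deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class ThresholdResult:
    first_threshold: float
    second_threshold: float
    mask: np.ndarray


def iterative_threshold(image: np.ndarray, tol: float = 1e-3,
                        max_iter: int = 100) -> float:
    """ISODATA fixed-point threshold starting from the global mean."""
    img = np.asarray(image, dtype=np.float64).ravel()
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        raise ValueError("constant image has no threshold")
    t = float(img.mean())
    for _ in range(max_iter):
        below = img[img < t]
        above = img[img >= t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t)


def double_threshold_segment(image: np.ndarray) -> ThresholdResult:
    """Two-pass threshold segmentation.

    Pass 1 selects pixels at or above the iterative threshold; pass 2
    re-thresholds the whole image at the mean intensity of the pass-1
    region.  Because that mean exceeds the pass-1 threshold, the result
    keeps only the brightest structures (tumor candidates).
    """
    img = np.asarray(image, dtype=np.float64)
    t1 = iterative_threshold(img)
    region1 = img >= t1
    if not region1.any():
        raise ValueError("first-pass region is empty")
    t2 = float(img[region1].mean())
    mask = (img >= t2).astype(np.uint8)
    return ThresholdResult(first_threshold=t1, second_threshold=t2, mask=mask)


def remove_small_components(mask: np.ndarray,
                            min_area: int | None = None) -> np.ndarray:
    """Delete 8-connected components smaller than ``min_area`` pixels.

    Default ``min_area`` is 0.1% of the image area.  Idempotent.
    """
    mask = np.asarray(mask).astype(bool)
    if min_area is None:
        min_area = max(1, int(0.001 * mask.size))
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.astype(np.uint8)
    areas = np.bincount(labeled.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = areas[1:] >= min_area
    return keep[labeled].astype(np.uint8)


def baseline_segment(image: np.ndarray,
                     min_area: int | None = None) -> np.ndarray:
    """Full classical pipeline: double threshold + small-region removal."""
    return remove_small_components(double_threshold_segment(image).mask,
                                   min_area=min_area)
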