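"""Reading clinical-format mammograms, preprocessing, and dataset splits.

Clinical mammograms arrive as high-resolution grayscale DICOM (typical
full-field digital resolution 3328 x 4096); phantoms and annotation
masks as PNG/TIFF.  Preprocessing follows the training convention:
resize to a square network input (default 512), rescale intensities to
[0, 1], then subtract the mean so the input is zero-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from PIL import Image
from skimage.transform import resize as _sk_resize

VIEWS = ("CC", "MLO", "unknown")


@dataclass
class MammogramImage:
    pixels: np.ndarray
    original_size: tuple[int, int]  # (width, height)
    view: str = "unknown"
    patient_id: str = ""
    source_path: str = ""

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if min(self.original_size) <= 0:
            raise ValueError("original_size must be positive")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")


def load_image(path) -> MammogramImage:
    """Load a DICOM, PNG or TIFF mammogram as a grayscale float array.

    Multi-channel images are collapsed to ITU-R 601 luminance; DICOM
    MONOCHROME1 (inverted grayscale) is flipped so higher always means
    brighter tissue.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    view = "unknown"
    patient_id = ""
    if suffix in (".dcm", ".dicom", ""):
        try:
            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(np.float64)
        except Exception as exc:
            raise ValueError(f"cannot read DICOM file {path}: {exc}") from exc
        if str(getattr(ds, "PhotometricInterpretation", "")) == "MONOCHROME1":
            arr = arr.max() - arr
        patient_id = str(getattr(ds, "PatientID", ""))
        vp = str(getattr(ds, "ViewPosition", "")).upper()
        if vp in ("CC", "MLO"):
            view = vp
    elif suffix in (".png", ".tif", ".tiff"):
        try:
            with Image.open(path) as im:
                arr = np.asarray(im).astype(np.float64)
        except Exception as exc:
            raise ValueError(f"cannot read image file {path}: {exc}") from exc
        if arr.ndim == 3:
            rgb = arr[..., :3]
            arr = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        raise ValueError(f"unsupported image format: {path}")
    h, w = arr.shape
    return MammogramImage(pixels=arr, original_size=(w, h), view=view,
                          patient_id=patient_id, source_path=str(path))


def preprocess(img: MammogramImage | np.ndarray, side: int = 512, *,
               normalization: str = "minmax",
               mean_value: float | None = None) -> np.ndarray:
    """Resize to ``side`` x ``side``, rescale to [0, 1], subtract the mean.

    ``normalization='minmax'`` rescales per image (robust to varying
    DICOM bit depths); ``'bitdepth'`` divides by the nominal maximum of
    the stored dtype range instead.  ``mean_value`` overrides the
    per-image mean with a dataset-wide constant.  Constant images map to
    all zeros.  Output values lie in [-1, 1] with mean ~0.
    """
    pixels = img.pixels if isinstance(img, MammogramImage) else np.asarray(img)
    pixels = pixels.astype(np.float64)
    resized = _sk_resize(pixels, (side, side), order=1, mode="reflect",
                         anti_aliasing=pixels.shape[0] > side,
                         preserve_range=True)
    if normalization == "minmax":
        lo, hi = resized.min(), resized.max()
        if hi - lo < 1e-12:
            return np.zeros((side, side), dtype=np.float64)
        scaled = (resized - lo) / (hi - lo)
    elif normalization == "bitdepth":
        peak = max(resized.max(), 1.0)
        # smallest containing power-of-two range (255, 4095, 65535, ...)
        bits = max(8, int(np.ceil(np.log2(peak + 1))))
        scaled = resized / (2 ** bits - 1)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    mean = scaled.mean() if mean_value is None else mean_value
    return scaled - mean


def binarize_mask(mask_image: np.ndarray, side: int | None = None) -> np.ndarray:
    """Threshold a grayscale annotation mask at zero; optional NN resize."""
    mask = (np.asarray(mask_image) > 0).astype(np.uint8)
    if side is not None and mask.shape != (side, side):
        mask = _sk_resize(mask, (side, side), order=0, preserve_range=True,
                          anti_aliasing=False).astype(np.uint8)
    return mask


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str] = field(default_factory=list)

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("split partitions must be disjoint")


def split_dataset(sample_ids, sizes: tuple[int, int, int], seed: int,
                  patient_aware: bool = False,
                  patient_of=None) -> DatasetSplit:
    """Randomly partition sample ids into train/validation/test.

    ``sizes`` must sum to the dataset size (e.g. 230/75/75 for 380
    images).  With ``patient_aware``, all samples of one patient (via
    ``patient_of``, a mapping or callable) land in the same partition.
    """
    ids = [str(s) for s in sample_ids]
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != len(ids):
        raise ValueError(
            f"sizes {sizes} do not sum to dataset size {len(ids)}")
    rng = np.random.default_rng(seed)
    if not patient_aware:
        order = list(rng.permutation(len(ids)))
        shuffled = [ids[i] for i in order]
        return DatasetSplit(train=shuffled[:n_train],
                            validation=shuffled[n_train:n_train + n_val],
                            test=shuffled[n_train + n_val:])
    if patient_of is None:
        raise ValueError("patient_aware split needs patient_of")
    get = patient_of if callable(patient_of) else patient_of.__getitem__
    groups: dict[str, list[str]] = {}
    for s in ids:
        groups.setdefault(str(get(s)), []).append(s)
    keys = sorted(groups)
    rng.shuffle(keys)
    capacity = [n_train, n_val, n_test]
    parts: list[list[str]] = [[], [], []]
    for k in keys:
        members = groups[k]
        placed = False
        for i in range(3):
            if capacity[i] >= len(members):
                parts[i].extend(members)
                capacity[i] -= len(members)
                placed = True
                break
        if not placed:
            raise ValueError(
                "cannot satisfy exact split sizes with patient grouping")
    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2])


MANIFEST_COLUMNS = ["sample_id", "image_path", "mask_path", "view",
                    "patient_id", "split"]


def write_manifest(rows, path) -> None:
    """Write a dataset manifest CSV (one row per sample)."""
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
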