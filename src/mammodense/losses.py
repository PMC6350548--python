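"""Segmentation losses: inverse-frequency weighted cross-entropy,
plain cross-entropy, and soft Dice.

The weighted loss addresses the extreme foreground/background imbalance
of whole-mammogram tumor segmentation: with class frequencies f_l
(fractions of pixels, summing to 1) the per-pixel cross-entropy term is
scaled by 1/f_{y_i}, so pixels of the rare tumor class contribute
proportionally more gradient,

    L = -(1/N) * sum_i (1/f_{y_i}) * log p_i,

where N is the pixel count, y_i the true label of pixel i, and p_i the
predicted probability of that label (natural log).  Frequencies are
computed per image by default; dataset-wide frequencies can be passed
in precomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lower clamp on predicted probabilities before taking logs
PROB_EPS = 1e-7
#: floor on class frequencies so tumor-free images yield finite weights
FREQ_FLOOR = 1e-4


@dataclass
class ClassFrequencies:
    """Per-class pixel frequencies f_l with sum_l f_l = 1."""

    f: dict[int, float]

    def __post_init__(self):
        total = sum(self.f.values())
        # tolerance admits floor-clamped frequencies on single-class masks
        if not np.isclose(total, 1.0, atol=1e-3):
            raise ValueError(f"frequencies sum to {total}, expected 1")
        if any(v <= 0 for v in self.f.values()):
            raise ValueError("all frequencies must be positive")

    def weights(self, n_classes: int) -> np.ndarray:
        return np.array([1.0 / self.f[l] for l in range(n_classes)],
                        dtype=np.float64)


@dataclass
class LossValue:
    value: float
    n_pixels: int

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"loss must be finite and >= 0, got {self.value}")


def class_frequencies(label_mask: np.ndarray, n_classes: int = 2,
                      floor: float = FREQ_FLOOR) -> ClassFrequencies:
    """Observed per-class pixel fractions of a label mask.

    Absent classes are floored at ``floor`` (and the rest renormalized
    only implicitly through the floor being tiny) so that inverse
    weights stay finite on e.g. tumor-free images.
    """
    labels = np.asarray(label_mask)
    if labels.size == 0:
        raise ValueError("empty label mask")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.bincount(labels.ravel().astype(np.int64), minlength=n_classes)
    freqs = counts / labels.size
    return ClassFrequencies(
        {l: max(float(freqs[l]), floor) for l in range(n_classes)})


def _gather_true_probs(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.shape[:-1] != labels.shape:
        raise ValueError(
            f"probs {probs.shape} do not match labels {labels.shape}")
    p = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
    return np.clip(p, PROB_EPS, 1.0)


def weighted_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                           freqs: ClassFrequencies) -> LossValue:
    """Inverse-frequency weighted cross-entropy.

    ``probs`` has shape (..., n_classes) with per-pixel distributions;
    ``labels`` the matching integer field.  With uniform frequencies
    {0.5, 0.5} this is exactly twice the unweighted cross-entropy.
    """
    p = _gather_true_probs(probs, labels)
    w = np.asarray([1.0 / freqs.f[l] for l in
                    range(probs.shape[-1])])[np.asarray(labels, np.int64)]
    value = float(np.mean(-w * np.log(p)))
    return LossValue(value=value, n_pixels=int(p.size))


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> LossValue:
    """Plain (unweighted) per-pixel cross-entropy, natural log."""
    p = _gather_true_probs(probs, labels)
    return LossValue(value=float(np.mean(-np.log(p))),
                     n_pixels=int(p.size))


def dice_loss(probs: np.ndarray, labels: np.ndarray,
              smooth: float = 1.0) -> LossValue:
    """Soft Dice loss for the binary problem (foreground class 1).

    1 - (2 * sum p_i g_i + s) / (sum p_i + sum g_i + s), with soft
    foreground probabilities p, binary ground truth g and smoothing s.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.shape[-1] < 2:
        raise ValueError("dice_loss needs a foreground class at index 1")
    p = probs[..., 1]
    g = (labels == 1).astype(np.float64)
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum())
    value = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    return LossValue(value=float(np.clip(value, 0.0, 1.0)),
                     n_pixels=int(g.size))


# ---------------------------------------------------------------------------
# gradients with respect to logits (used by the training engine)

def _softmax_grad_common(probs, labels, per_pixel_weight):
    labels = np.asarray(labels, dtype=np.int64)
    onehot = np.eye(probs.shape[-1])[labels]
    n = labels.size
    return per_pixel_weight[..., None] * (probs - onehot) / n


def weighted_cross_entropy_grad(probs, labels, freqs: ClassFrequencies):
    """d(weighted CE)/d(logits), shape (..., n_classes)."""
    probs = np.asarray(probs, dtype=np.float64)
    w = np.asarray([1.0 / freqs.f[l] for l in
                    range(probs.shape[-1])])[np.asarray(labels, np.int64)]
    return _softmax_grad_common(probs, labels, w)


def cross_entropy_grad(probs, labels):
    probs = np.asarray(probs, dtype=np.float64)
    w = np.ones(np.asarray(labels).shape)
    return _softmax_grad_common(probs, labels, w)


def dice_loss_grad(probs, labels, smooth: float = 1.0):
    """d(soft Dice)/d(logits) through the softmax, binary problem."""
    probs = np.asarray(probs, dtype=np.float64)
    g = (np.asarray(labels) == 1).astype(np.float64)
    p = probs[..., 1]
    numer = 2.0 * (p * g).sum() + smooth
    denom = p.sum() + g.sum() + smooth
    dl_dp = -(2.0 * g / denom) + numer / denom ** 2
    # chain through softmax: only class-1 prob enters the loss
    grad = np.zeros_like(probs)
    p0 = probs[..., 0]
    grad[..., 1] = dl_dp * p * (1.0 - p)
    grad[..., 0] = -dl_dp * p * p0
    return grad


LOSSES = {
    "weighted_ce": (weighted_cross_entropy, weighted_cross_entropy_grad),
    "ce": (cross_entropy, cross_entropy_grad),
    "dice": (dice_loss, dice_loss_grad),
}
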