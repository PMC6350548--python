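"""Loss functions against brute-force per-pixel oracles and hand values."""

import numpy as np
import pytest

import mammodense as md
from mammodense import losses as L


def random_prob_field(rng, shape=(8, 8), n_classes=2):
    raw = rng.random(shape + (n_classes,)) + 0.05
    return raw / raw.sum(axis=-1, keepdims=True)


def loop_weighted_ce(probs, labels, freqs):
    """Independent per-pixel loop evaluation of the weighted loss."""
    total = 0.0
    h, w = labels.shape
    for i in range(h):
        for j in range(w):
            y = int(labels[i, j])
            total += (1.0 / freqs.f[y]) * (-np.log(probs[i, j, y]))
    return total / (h * w)


class TestClassFrequencies:
    def test_balanced_mask(self):
        mask = np.repeat([0, 1], 50).reshape(10, 10)
        fr = L.class_frequencies(mask)
        assert fr.f == {0: 0.5, 1: 0.5}

    def test_imbalanced_mask(self):
        mask = np.zeros((10, 10), int)
        mask[:1] = 1
        fr = L.class_frequencies(mask)
        assert fr.f[1] == pytest.approx(0.1)
        assert fr.f[0] == pytest.approx(0.9)

    def test_all_background_floored(self):
        fr = L.class_frequencies(np.zeros((10, 10), int))
        assert fr.f[0] == 1.0
        assert fr.f[1] == L.FREQ_FLOOR  # finite inverse weight

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            L.class_frequencies(np.zeros((0, 0), int))


class TestWeightedCrossEntropy:
    def test_perfect_predictions_zero(self):
        labels = np.array([[0, 1], [1, 0]])
        probs = np.eye(2)[labels].astype(float)
        fr = L.class_frequencies(labels)
        assert L.weighted_cross_entropy(probs, labels, fr).value == \
            pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_example(self):
        """N=4, one tumor pixel, all true-class probs 0.5:
        -(1/4)(3/0.75 + 1/0.25) ln 0.5 = 2 ln 2."""
        labels = np.array([[0, 0], [0, 1]])
        probs = np.full((2, 2, 2), 0.5)
        fr = L.ClassFrequencies({0: 0.75, 1: 0.25})
        got = L.weighted_cross_entropy(probs, labels, fr).value
        assert got == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_uniform_frequencies_double_plain_ce(self, rng):
        labels = (rng.random((8, 8)) > 0.5).astype(int)
        probs = random_prob_field(rng)
        fr = L.ClassFrequencies({0: 0.5, 1: 0.5})
        wce = L.weighted_cross_entropy(probs, labels, fr).value
        ce = L.cross_entropy(probs, labels).value
        assert wce == pytest.approx(2 * ce, rel=1e-9)

    def test_matches_loop_oracle_on_random_fields(self, rng):
        for _ in range(20):
            labels = (rng.random((8, 8)) > 0.8).astype(int)
            probs = random_prob_field(rng)
            fr = L.class_frequencies(labels)
            got = L.weighted_cross_entropy(probs, labels, fr)
            assert got.value == pytest.approx(
                loop_weighted_ce(probs, labels, fr), abs=1e-6)
            assert got.n_pixels == 64

    def test_zero_probability_clamped_finite(self):
        labels = np.array([[1]])
        probs = np.array([[[1.0, 0.0]]])
        fr = L.ClassFrequencies({0: 0.5, 1: 0.5})
        v = L.weighted_cross_entropy(probs, labels, fr).value
        assert np.isfinite(v) and v > 0

    def test_imbalance_weights_gradient_99x(self):
        """With f_tumor = 0.01 the logit gradient at a tumor pixel is 99x
        that at a background pixel with equal predicted probability."""
        labels = np.array([[0, 1]])
        probs = np.full((1, 2, 2), 0.5)
        fr = L.ClassFrequencies({0: 0.99, 1: 0.01})
        g = L.weighted_cross_entropy_grad(probs, labels, fr)
        mag_bg = np.abs(g[0, 0]).max()
        mag_fg = np.abs(g[0, 1]).max()
        assert mag_fg / mag_bg == pytest.approx(99.0, rel=1e-9)


class TestCrossEntropy:
    def test_single_pixel_half_prob(self):
        got = L.cross_entropy(np.array([[[0.5, 0.5]]]), np.array([[0]]))
        assert got.value == pytest.approx(np.log(2), rel=1e-12)

    def test_perfect_zero(self):
        labels = np.array([[0, 1]])
        probs = np.eye(2)[labels].astype(float)
        assert L.cross_entropy(probs, labels).value == \
            pytest.approx(0.0, abs=1e-6)


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        labels = np.zeros((10, 10), int)
        labels[:3, :3] = 1
        probs = np.eye(2)[labels].astype(float)
        assert L.dice_loss(probs, labels).value < 0.01

    def test_complete_miss_near_one(self):
        labels = np.zeros((10, 10), int)
        labels[:5] = 1
        probs = np.eye(2)[1 - labels].astype(float)
        assert L.dice_loss(probs, labels, smooth=1e-9).value == \
            pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_uniform_half(self):
        """10 fg of 100, p = 0.5 everywhere, s = 0: 1 - 10/60 = 5/6."""
        labels = np.zeros((10, 10), int)
        labels[0] = 1
        probs = np.full((10, 10, 2), 0.5)
        got = L.dice_loss(probs, labels, smooth=0.0).value
        assert got == pytest.approx(5 / 6, rel=1e-12)


class TestMonotonicity:
    @pytest.mark.parametrize("loss_name", ["weighted_ce", "ce", "dice"])
    def test_losses_decrease_as_true_probs_increase(self, loss_name, rng):
        """Raising every true-class probability elementwise can only
        lower each loss (nonnegative throughout)."""
        loss_fn = L.LOSSES[loss_name][0]
        fr = L.ClassFrequencies({0: 0.9, 1: 0.1})
        for _ in range(10):
            labels = (rng.random((6, 6)) > 0.7).astype(int)
            p_true = 0.2 + 0.5 * rng.random((6, 6))
            boost = rng.random((6, 6)) * (0.98 - p_true)
            losses = []
            for pt in (p_true, p_true + boost):
                probs = np.empty((6, 6, 2))
                np.put_along_axis(probs, labels[..., None], pt[..., None], -1)
                np.put_along_axis(probs, 1 - labels[..., None],
                                  1 - pt[..., None], -1)
                args = (probs, labels, fr) if loss_name == "weighted_ce" \
                    else (probs, labels)
                losses.append(loss_fn(*args).value)
            assert losses[0] >= 0 and losses[1] >= 0
            assert losses[1] <= losses[0] + 1e-12


class TestLossGradients:
    @pytest.mark.parametrize("loss_name", ["weighted_ce", "ce", "dice"])
    def test_grads_match_finite_differences_through_softmax(self, loss_name,
                                                            rng):
        loss_fn, grad_fn = L.LOSSES[loss_name]
        labels = (rng.random((5, 5)) > 0.7).astype(int)
        logits = rng.standard_normal((5, 5, 2))
        fr = L.class_frequencies(labels)

        def softmax(z):
            e = np.exp(z - z.max(axis=-1, keepdims=True))
            return e / e.sum(axis=-1, keepdims=True)

        def value(z):
            p = softmax(z)
            args = (p, labels, fr) if loss_name == "weighted_ce" \
                else (p, labels)
            return loss_fn(*args).value

        g = grad_fn(softmax(logits), labels, fr) \
            if loss_name == "weighted_ce" else grad_fn(softmax(logits), labels)
        eps = 1e-6
        for idx in [(0, 0, 0), (2, 3, 1), (4, 4, 0)]:
            z = logits.copy()
            z[idx] += eps
            f1 = value(z)
            z[idx] -= 2 * eps
            f0 = value(z)
            assert (f1 - f0) / (2 * eps) == pytest.approx(
                g[idx], rel=1e-4, abs=1e-8)
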