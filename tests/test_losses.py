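"""Loss formulas against independent scalar-loop oracles, and weight rules."""

import math

import numpy as np
import pytest

from lsmunet.losses import (
    ClassWeights,
    combined_loss,
    compute_class_weights,
    cross_entropy_loss,
    dice_loss,
    one_hot,
)
from lsmunet.nn.core import softmax

# --- independent oracles: plain python loops written from the formulas -----


def ce_oracle(logits, target, omega):
    """Per-image sum of -omega_c y_ic log softmax(logits)_ic, batch-averaged."""
    b, c, h, w = logits.shape
    total = 0.0
    for bi in range(b):
        acc = 0.0
        for i in range(h):
            for j in range(w):
                z = [logits[bi, ci, i, j] for ci in range(c)]
                m = max(z)
                denom = sum(math.exp(v - m) for v in z)
                for ci in range(c):
                    if target[bi, ci, i, j] == 1:
                        logp = (z[ci] - m) - math.log(denom)
                        acc -= omega[ci] * logp
        total += acc
    return total / b


def dice_oracle(probs, target, omega, eps=1e-5):
    b, c, h, w = probs.shape
    total = 0.0
    for bi in range(b):
        for ci in range(c):
            num = den = 0.0
            for i in range(h):
                for j in range(w):
                    y = target[bi, ci, i, j]
                    p = probs[bi, ci, i, j]
                    num += y * p
                    den += y * y + p * p
            total += omega[ci] * (1.0 - (2.0 * num + eps) / (den + eps))
    return total / b


def random_instance(rng, b=2, c=5, h=3, w=3):
    logits = rng.normal(size=(b, c, h, w))
    labels = rng.integers(0, c, size=(b, h, w))
    target = one_hot(labels, c).astype(np.float64)
    omega = rng.uniform(0.1, 1.0, size=c)
    weights = ClassWeights(omega=tuple(omega), counts=(0,) * 5, total=0)
    return logits, target, weights


class TestClassWeights:
    def test_large_region_offset(self):
        # class 1 at 10% of pixels -> 1 - 0.10 - 0.20
        lab = np.zeros((1, 10, 10), dtype=np.int64)
        lab[0, :1, :] = 1  # 10 px of 100
        w = compute_class_weights([lab])
        assert w.omega[1] == pytest.approx(0.70)

    def test_psoas_branch_without_offset(self):
        lab = np.zeros((1, 10, 10), dtype=np.int64)
        lab[0, 0, :2] = 2  # 2% of pixels
        w = compute_class_weights([lab])
        assert w.omega[2] == pytest.approx(0.98)

    def test_equal_counts_differ_by_exactly_offset(self):
        lab = np.zeros((1, 10, 10), dtype=np.int64)
        lab[0, 0, :5] = 1
        lab[0, 1, :5] = 2
        w = compute_class_weights([lab])
        assert w.omega[2] - w.omega[1] == pytest.approx(0.2, abs=1e-15)

    def test_background_uses_no_offset_branch(self):
        lab = np.zeros((2, 4, 4), dtype=np.int64)
        lab[0] = 1
        w = compute_class_weights([lab])
        assert w.omega[0] == pytest.approx(1.0 - 0.5)

    def test_dominant_class_with_offset_rejected(self):
        lab = np.ones((1, 10, 10), dtype=np.int64)  # class 1 at 100%
        with pytest.raises(ValueError, match="class"):
            compute_class_weights([lab])

    def test_counts_pooled_over_volumes(self):
        a = np.zeros((1, 4, 4), dtype=np.int64)
        b = np.full((1, 4, 4), 2, dtype=np.int64)
        w = compute_class_weights([a, b])
        assert w.omega[2] == pytest.approx(0.5)
        assert w.total == 32


class TestCrossEntropy:
    def test_uniform_logits_closed_form(self):
        # all-equal logits: per-pixel CE = omega_{c(i)} * log 5
        lab = np.array([[[0, 1], [2, 3]]])
        target = one_hot(lab).astype(np.float64)
        logits = np.zeros((1, 5, 2, 2))
        omega = np.array([0.5, 0.7, 0.9, 1.0, 0.8])
        w = ClassWeights(omega=tuple(omega), counts=(0,) * 5, total=0)
        expected = (omega[0] + omega[1] + omega[2] + omega[3]) * math.log(5)
        assert cross_entropy_loss(logits, target, w) == pytest.approx(expected)

    def test_confident_correct_prediction_vanishes(self):
        lab = np.zeros((1, 2, 2), dtype=np.int64)
        target = one_hot(lab).astype(np.float64)
        logits = np.zeros((1, 5, 2, 2))
        logits[:, 0] = 200.0
        assert cross_entropy_loss(logits, target) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_weights(self, rng):
        logits, target, w = random_instance(rng)
        doubled = ClassWeights(
            omega=tuple(2 * o for o in w.omega), counts=w.counts, total=w.total
        )
        assert cross_entropy_loss(logits, target, doubled) == pytest.approx(
            2 * cross_entropy_loss(logits, target, w)
        )

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            logits, target, w = random_instance(rng)
            mine = cross_entropy_loss(logits, target, w)
            ref = ce_oracle(logits, target, w.omega)
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_rejects_non_onehot(self, rng):
        logits = rng.normal(size=(1, 5, 2, 2))
        bad = np.ones((1, 5, 2, 2))
        with pytest.raises(ValueError, match="one-hot"):
            cross_entropy_loss(logits, bad)


class TestDice:
    def test_perfect_prediction_zero(self):
        lab = np.array([[[0, 1], [1, 0]]])
        target = one_hot(lab).astype(np.float64)
        assert dice_loss(target.copy(), target) == pytest.approx(0.0, abs=1e-4)

    def test_complete_miss_costs_full_weight(self):
        # 2-class toy: prediction is the complement of the target
        target = np.zeros((1, 5, 2, 2))
        target[0, 0] = 1.0
        pred = np.zeros((1, 5, 2, 2))
        pred[0, 1] = 1.0
        omega = (0.3, 0.4, 1.0, 1.0, 1.0)
        w = ClassWeights(omega=omega, counts=(0,) * 5, total=0)
        # classes 0 and 1: zero overlap -> term ~ omega_c; classes 2-4 empty-empty -> 0
        assert dice_loss(pred, target, w) == pytest.approx(0.3 + 0.4, abs=1e-4)

    def test_empty_empty_class_contributes_nothing(self):
        target = np.zeros((1, 5, 1, 1))
        target[0, 0] = 1.0
        pred = target.copy()
        assert dice_loss(pred, target) == pytest.approx(0.0, abs=1e-4)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            logits, target, w = random_instance(rng, h=4, w=4)
            probs = softmax(logits, axis=1)
            mine = dice_loss(probs, target, w)
            ref = dice_oracle(probs, target, w.omega)
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_rejects_invalid_probabilities(self, rng):
        _, target, w = random_instance(rng)
        bad = np.full(target.shape, 1.5)
        with pytest.raises(ValueError, match="probabilities"):
            dice_loss(bad, target, w)


class TestCombined:
    def test_total_is_sum_of_terms(self, rng):
        logits, target, w = random_instance(rng)
        lv = combined_loss(logits, target, w)
        assert lv.total == pytest.approx(lv.ce_term + lv.dice_term)
        assert lv.total >= 0

    def test_weight_toggle_consistent_with_uniform(self, rng):
        logits, target, _ = random_instance(rng)
        uniform = ClassWeights.uniform()
        a = combined_loss(logits, target, uniform, use_weights=True)
        b = combined_loss(logits, target, uniform, use_weights=False)
        assert a.total == pytest.approx(b.total)

    def test_perfect_prediction_limit(self):
        lab = np.array([[[0, 1], [2, 0]]])
        target = one_hot(lab).astype(np.float64)
        logits = 300.0 * (2 * target - 1)
        lv = combined_loss(logits, target)
        assert lv.total == pytest.approx(0.0, abs=1e-3)


def test_gradient_descent_reduces_loss_on_toy_volume(rng):
    """Optimization sanity: 50 Adam steps overfit a single tiny phantom."""
    from autograd import value_and_grad

    from lsmunet.losses import combined_loss_scalar, compute_class_weights
    from lsmunet.network import NetworkConfig, build_lsmu_net
    from lsmunet.nn import Adam

    cfg = NetworkConfig.scaled(8, in_plane_size=(32, 32), seed=2)
    model = build_lsmu_net(cfg)
    vol = rng.uniform(size=(1, 1, 8, 32, 32)).astype(np.float32)
    lab = np.zeros((8, 32, 32), dtype=np.int64)
    lab[:, 8:16, 8:24] = 1
    lab[:, 20:26, 4:12] = 2
    lab[:, 20:26, 20:28] = 3
    lab[:, 26:30, 12:20] = 4
    target = one_hot(lab)
    w = compute_class_weights([lab])

    def obj(params):
        return combined_loss_scalar(model.apply(params, vol), target, w)

    gf = value_and_grad(obj)
    opt = Adam(model.params, lr=0.001)
    params = model.params
    losses = []
    for _ in range(50):
        loss, g = gf(params)
        params = opt.step(params, g)
        losses.append(float(loss))
    assert losses[-1] < losses[0]
    assert np.isfinite(losses).all()
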