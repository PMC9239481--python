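"""Class-weight strategies, the weighted CRF objective, and baseline losses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wcrf.crf import PotentialTables
from wcrf.io import LabelAlphabet
from wcrf.losses import (
    ClassWeights,
    TokenClassCounts,
    compute_class_weights,
    dice_loss,
    dice_loss_gradient,
    focal_loss,
    focal_loss_from_logits,
    weighted_crf_nll,
    weighted_crf_nll_gradient,
    weighted_softmax_ce,
)

counts_strategy = st.lists(st.integers(1, 10_000), min_size=2, max_size=6)


class TestClassWeights:
    def test_two_class_arithmetic(self):
        counts = TokenClassCounts(("majority", "minority"), (90, 10))
        w = compute_class_weights(counts, "balanced").weights
        assert w == pytest.approx((100 / (2 * 90), 5.0))

    def test_balanced_counts_give_unit_weights(self):
        counts = TokenClassCounts(("a", "b", "c"), (40, 40, 40))
        for strategy in ("balanced", "uniform"):
            w = compute_class_weights(counts, strategy).weights
            assert w == pytest.approx((1.0, 1.0, 1.0) if strategy == "balanced" else w)
        assert compute_class_weights(counts, "balanced").weights == (1.0, 1.0, 1.0)

    def test_twitter_style_pooled_counts(self):
        # N=16,023 over classes O/ADR/Indication -> w_O = 16023/(3*13852)
        counts = TokenClassCounts(("ADR", "Indication", "O"), (1970, 201, 13852))
        w = compute_class_weights(counts, "balanced")
        assert w.weight_of_class("O") == pytest.approx(0.3856, abs=5e-5)
        assert w.weight_of_class("ADR") == pytest.approx(16023 / (3 * 1970), rel=1e-12)

    @given(counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_conservation_sum_wk_nk_equals_n(self, counts):
        tcc = TokenClassCounts(tuple(f"c{i}" for i in range(len(counts))), tuple(counts))
        w = np.array(compute_class_weights(tcc, "balanced").weights)
        assert float(w @ np.array(counts)) == pytest.approx(tcc.n, rel=1e-12)

    @given(counts_strategy)
    @settings(max_examples=50, deadline=None)
    def test_strategy_scale_relations(self, counts):
        tcc = TokenClassCounts(tuple(f"c{i}" for i in range(len(counts))), tuple(counts))
        balanced = np.array(compute_class_weights(tcc, "balanced").weights)
        inv_count = np.array(compute_class_weights(tcc, "inverse_count").weights)
        inv_ratio = np.array(compute_class_weights(tcc, "inverse_ratio").weights)
        assert np.allclose(inv_ratio, tcc.k * balanced, rtol=1e-12)
        assert np.allclose(inv_count, balanced / (tcc.n / tcc.k), rtol=1e-12)
        # minority classes get weight > 1 under balanced and inverse_ratio
        for nk, wb, wr in zip(counts, balanced, inv_ratio):
            if nk < tcc.n / tcc.k:
                assert wb > 1.0 and wr > 1.0

    def test_zero_count_errors_without_smoothing(self):
        counts = TokenClassCounts(("a", "b"), (10, 0))
        with pytest.raises(ValueError, match="zero token count"):
            compute_class_weights(counts, "balanced")
        smoothed = compute_class_weights(counts, "balanced", smooth=True)
        assert all(w > 0 for w in smoothed.weights)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            ClassWeights(("a",), (0.0,), "uniform")


class TestWeightedCrf:
    def setup_method(self):
        self.alphabet = LabelAlphabet(("ADR",))
        self.rng = np.random.default_rng(0)

    def _random_pot(self, n=5):
        k = self.alphabet.size
        return PotentialTables(
            self.rng.normal(size=(n, k)), self.rng.normal(size=(k + 2, k + 2))
        )

    def test_degenerates_to_softmax_ce_at_zero_transitions(self):
        k = self.alphabet.size
        emis = self.rng.normal(size=(6, k))
        pot = PotentialTables(emis, np.zeros((k + 2, k + 2)))
        y = self.rng.integers(0, k, size=6)
        uniform = ClassWeights.uniform(("ADR", "O"))
        wl = weighted_crf_nll(pot, y, uniform, self.alphabet)
        ce = weighted_softmax_ce(emis, y, np.ones(6))
        assert wl == pytest.approx(ce, abs=1e-10)

    def test_linear_in_weights(self):
        pot = self._random_pot()
        y = self.rng.integers(0, self.alphabet.size, size=5)
        w1 = ClassWeights(("ADR", "O"), (2.0, 0.5), "balanced")
        w2 = ClassWeights(("ADR", "O"), (4.0, 1.0), "balanced")
        assert weighted_crf_nll(pot, y, w2, self.alphabet) == pytest.approx(
            2 * weighted_crf_nll(pot, y, w1, self.alphabet), rel=1e-12
        )

    def test_monotone_in_gold_marginal(self):
        """Raising the gold label's emission strictly lowers its loss term."""
        pot = self._random_pot(4)
        y = np.array([1, 0, 2, 1])
        w = ClassWeights.uniform(("ADR", "O"))
        base = weighted_crf_nll(pot, y, w, self.alphabet)
        boosted = PotentialTables(pot.emissions.copy(), pot.transitions)
        boosted.emissions[2, y[2]] += 0.5
        assert weighted_crf_nll(boosted, y, w, self.alphabet) < base

    def test_gradient_matches_central_differences(self):
        for trial in range(20):
            pot = self._random_pot(4)
            y = self.rng.integers(0, self.alphabet.size, size=4)
            cw = ClassWeights(("ADR", "O"), (5.0, 0.4), "balanced")
            d_p, d_a = weighted_crf_nll_gradient(pot, y, cw, self.alphabet)
            eps = 1e-6
            for _ in range(5):
                i, j = self.rng.integers(4), self.rng.integers(pot.k)
                up = PotentialTables(pot.emissions.copy(), pot.transitions)
                up.emissions[i, j] += eps
                dn = PotentialTables(pot.emissions.copy(), pot.transitions)
                dn.emissions[i, j] -= eps
                num = (
                    weighted_crf_nll(up, y, cw, self.alphabet)
                    - weighted_crf_nll(dn, y, cw, self.alphabet)
                ) / (2 * eps)
                assert abs(num - d_p[i, j]) < 1e-4 * max(1.0, abs(num))


class TestWeightedSoftmax:
    def test_uniform_weights_is_plain_ce(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(5, 3))
        y = rng.integers(0, 3, size=5)
        from scipy.special import log_softmax

        expected = -log_softmax(logits, axis=1)[np.arange(5), y].sum()
        assert weighted_softmax_ce(logits, y, np.ones(5)) == pytest.approx(expected)

    def test_confident_correct_logits_drive_loss_to_zero(self):
        logits = np.array([[100.0, 0.0]])
        assert weighted_softmax_ce(logits, [0], [1.0]) < 1e-10

    def test_two_class_arithmetic(self):
        loss = weighted_softmax_ce(np.zeros((1, 2)), [0], [2.0])
        assert loss == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            weighted_softmax_ce(np.zeros((2, 2)), [0], [1.0])


class TestFocal:
    def test_gamma_zero_is_cross_entropy(self):
        p = np.array([0.3, 0.9, 0.5])
        assert focal_loss(p, gamma=0.0) == pytest.approx(float(-np.log(p).sum()))

    def test_perfect_prediction_contributes_nothing(self):
        assert focal_loss(np.array([1.0]), gamma=2.0) == 0.0

    def test_half_probability_gamma_two(self):
        assert focal_loss(np.array([0.5]), gamma=2.0) == pytest.approx(
            0.25 * math.log(2), abs=1e-12
        )

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([0.0]), gamma=1.0)

    def test_logit_form_consistent(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(4, 3))
        y = [0, 2, 1, 1]
        from scipy.special import softmax

        p = softmax(logits, axis=1)[np.arange(4), y]
        assert focal_loss_from_logits(logits, y, 2.0) == pytest.approx(
            focal_loss(p, 2.0)
        )


class TestDice:
    def test_perfect_overlap_approaches_zero(self):
        y = np.zeros((4, 3))
        y[np.arange(4), [0, 1, 2, 0]] = 1.0
        assert dice_loss(y, y, eps=1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_approaches_one(self):
        p = np.zeros((3, 2))
        p[:, 0] = 1.0
        y = np.zeros((3, 2))
        y[:, 1] = 1.0
        assert dice_loss(p, y, eps=1e-9) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(3)
        p = rng.random((5, 3))
        y = np.zeros((5, 3))
        y[np.arange(5), rng.integers(0, 3, 5)] = 1.0
        inter = float((p * y).sum())
        expected = 1 - (2 * inter + 1.0) / (float((p**2).sum()) + 5 + 1.0)
        assert dice_loss(p, y) == pytest.approx(expected, rel=1e-12)

    def test_gradient_central_difference(self):
        rng = np.random.default_rng(4)
        p = rng.random((4, 3)) * 0.9 + 0.05
        y = np.zeros((4, 3))
        y[np.arange(4), rng.integers(0, 3, 4)] = 1.0
        g = dice_loss_gradient(p, y)
        eps = 1e-7
        for _ in range(6):
            i, j = rng.integers(4), rng.integers(3)
            up, dn = p.copy(), p.copy()
            up[i, j] += eps
            dn[i, j] -= eps
            num = (dice_loss(up, y) - dice_loss(dn, y)) / (2 * eps)
            assert abs(num - g[i, j]) < 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 3)), np.zeros((3, 2)))
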