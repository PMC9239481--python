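"""Exact CRF computations against the brute-force enumeration oracle."""

import math

import numpy as np
import pytest

from wcrf.crf import (
    PotentialTables,
    crf_nll,
    enumerate_oracle,
    log_partition,
    posterior_marginals,
    score_path,
    viterbi_decode,
)

from conftest import random_potentials


def zeros(n, k):
    return PotentialTables(np.zeros((n, k)), np.zeros((k + 2, k + 2)))


class TestScorePath:
    def test_all_zero_potentials(self):
        assert score_path(zeros(3, 2), [0, 1, 0]) == 0.0

    def test_direct_sum(self):
        pot = PotentialTables([[1.0, 0.0], [0.0, 1.0]], np.zeros((4, 4)))
        assert score_path(pot, [0, 1]) == 2.0

    def test_matches_manual_summation(self):
        rng = np.random.default_rng(42)
        pot = random_potentials(rng, n=5, k=3)
        y = rng.integers(0, 3, size=5)
        expected = pot.transitions[pot.start, y[0]] + pot.transitions[y[-1], pot.end]
        for i in range(5):
            expected += pot.emissions[i, y[i]]
            if i > 0:
                expected += pot.transitions[y[i - 1], y[i]]
        assert score_path(pot, y) == pytest.approx(expected, abs=1e-12)

    def test_label_out_of_range(self):
        with pytest.raises(IndexError):
            score_path(zeros(2, 2), [0, 2])


class TestLogPartition:
    @pytest.mark.parametrize("n,k", [(1, 2), (2, 2), (3, 4)])
    def test_uniform_potentials_give_n_log_k(self, n, k):
        assert log_partition(zeros(n, k)) == pytest.approx(n * math.log(k), abs=1e-12)

    def test_nonfinite_potential_rejected(self):
        with pytest.raises(ValueError):
            PotentialTables(np.full((2, 2), np.nan), np.zeros((4, 4)))

    def test_emission_shift_adds_constant(self):
        rng = np.random.default_rng(3)
        pot = random_potentials(rng, n=4, k=3)
        shifted = PotentialTables(
            pot.emissions + np.array([0, 1.7, 0, 0])[:, None], pot.transitions
        )
        assert log_partition(shifted) == pytest.approx(
            log_partition(pot) + 1.7, abs=1e-10
        )


class TestAgainstEnumeration:
    """log_partition / marginals / Viterbi vs exhaustive path enumeration."""

    def test_200_seeded_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            pot = random_potentials(rng)
            log_z, best, marg = enumerate_oracle(pot)
            assert log_partition(pot) == pytest.approx(log_z, abs=1e-8)
            assert viterbi_decode(pot) == best
            assert np.abs(posterior_marginals(pot) - marg).max() < 1e-8

    def test_path_probabilities_sum_to_one(self):
        from itertools import product

        rng = np.random.default_rng(7)
        pot = random_potentials(rng, n=4, k=3)
        log_z = log_partition(pot)
        total = sum(
            math.exp(score_path(pot, path) - log_z)
            for path in product(range(3), repeat=4)
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_oracle_refuses_large_instances(self):
        with pytest.raises(ValueError):
            enumerate_oracle(zeros(30, 4))

    def test_single_tag_partition_is_path_score(self):
        rng = np.random.default_rng(8)
        pot = random_potentials(rng, n=4, k=1)
        assert log_partition(pot) == pytest.approx(score_path(pot, [0] * 4), abs=1e-10)


class TestMarginals:
    def test_uniform_for_zero_potentials(self):
        m = posterior_marginals(zeros(3, 4))
        assert np.allclose(m, 0.25, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = posterior_marginals(random_potentials(rng))
            assert np.abs(m.sum(axis=1) - 1.0).max() < 1e-12


class TestNll:
    def test_single_tag_nll_is_zero(self):
        rng = np.random.default_rng(12)
        pot = random_potentials(rng, n=5, k=1)
        assert crf_nll(pot, [0] * 5) == pytest.approx(0.0, abs=1e-10)

    def test_nonnegative(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pot = random_potentials(rng)
            y = rng.integers(0, pot.k, size=pot.n)
            assert crf_nll(pot, y) >= -1e-10

    def test_equals_minus_log_enumerated_path_probability(self):
        rng = np.random.default_rng(14)
        pot = random_potentials(rng, n=4, k=3)
        y = [1, 0, 2, 1]
        log_z, _, _ = enumerate_oracle(pot)
        prob = math.exp(score_path(pot, y) - log_z)
        assert crf_nll(pot, y) == pytest.approx(-math.log(prob), abs=1e-8)


class TestViterbi:
    def test_zero_transitions_reduce_to_emission_argmax(self):
        rng = np.random.default_rng(15)
        emis = rng.normal(size=(6, 3))
        pot = PotentialTables(emis, np.zeros((5, 5)))
        assert viterbi_decode(pot) == list(np.argmax(emis, axis=1))

    def test_tie_break_lowest_index(self):
        assert viterbi_decode(zeros(3, 3)) == [0, 0, 0]

    def test_viterbi_score_dominates_all_paths(self):
        from itertools import product

        rng = np.random.default_rng(16)
        pot = random_potentials(rng, n=4, k=3)
        best_score = score_path(pot, viterbi_decode(pot))
        for path in product(range(3), repeat=4):
            assert best_score >= score_path(pot, path) - 1e-10
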