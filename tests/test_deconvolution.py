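"""Bernoulli-mixture EM, validity-probability DP, and BIC selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmsensemble.bitvectors import BitMatrix
from dmsensemble.deconvolution import (
    _em_single,
    bic,
    cluster_abundances,
    em_fit,
    select_k,
    valid_read_probability,
)
from dmsensemble.reference import ReferenceWindow
from dmsensemble.simulate import SimulationSpec, simulate_bitvectors
from tests.conftest import matrix_from_strings


def enumerate_valid_probability(mu, min_gap):
    """Exhaustive enumeration over all 2^M outcomes."""
    M = len(mu)
    total = 0.0
    for bits in itertools.product([0, 1], repeat=M):
        idx = [i for i, b in enumerate(bits) if b]
        if any(j - i < min_gap for i, j in zip(idx, idx[1:])):
            continue
        p = 1.0
        for i, b in enumerate(bits):
            p *= mu[i] if b else 1 - mu[i]
        total += p
    return total


class TestValidReadProbability:
    def test_two_positions_half(self):
        assert valid_read_probability(np.array([0.5, 0.5]), 4) == pytest.approx(0.75)

    def test_five_positions_seven_thirtyseconds(self):
        # valid outcomes: empty set, five singletons, and {1, 5}
        assert valid_read_probability(np.full(5, 0.5), 4) == pytest.approx(7 / 32)

    def test_zero_rates_certain(self):
        assert valid_read_probability(np.zeros(9), 4) == 1.0

    def test_min_gap_one_no_constraint(self):
        rng = np.random.default_rng(0)
        assert valid_read_probability(rng.uniform(0, 1, 8), 1) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            valid_read_probability(np.array([1.2]), 4)
        with pytest.raises(ValueError):
            valid_read_probability(np.array([0.5]), 0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 15), st.integers(1, 6))
    def test_dp_equals_enumeration(self, seed, m, gap):
        mu = np.random.default_rng(seed).uniform(0, 1, m)
        assert valid_read_probability(mu, gap) == pytest.approx(
            enumerate_valid_probability(mu, gap), abs=1e-12
        )

    def test_batched_matches_scalar(self):
        rng = np.random.default_rng(1)
        batch = rng.uniform(0, 0.5, size=(6, 10))
        p = valid_read_probability(batch, 4)
        for row, expect in zip(batch, p):
            assert valid_read_probability(row, 4) == pytest.approx(expect)


class TestBic:
    def test_hand_arithmetic(self):
        assert bic(-1000.0, 2, 50, 500) == pytest.approx(
            2000 + 101 * np.log(500), abs=1e-9
        )

    def test_k1_m0_reduces_to_deviance(self):
        assert bic(-123.0, 1, 0, 50) == pytest.approx(246.0)

    def test_penalty_prefers_smaller_k_at_equal_fit(self):
        assert bic(-500.0, 1, 30, 100) < bic(-500.0, 2, 30, 100)

    def test_requires_reads(self):
        with pytest.raises(ValueError):
            bic(-1.0, 1, 10, 0)


def two_profile_matrix(n_reads, seed, delta=0.10, width=40, pi=(0.6, 0.4)):
    """A small synthetic mixture over an all-A/C window (no filtering).

    The profiles differ by ``delta`` at half the positions — comfortably
    above the identifiability floor (>= 10 positions by >= 0.08).
    """
    window = ReferenceWindow("toy2", "AC" * (width // 2), 1, width)
    base = np.full(width, 0.01)
    other = base.copy()
    other[: width // 2] += delta
    spec = SimulationSpec(
        window=window,
        profiles=(tuple(base), tuple(other)),
        pi_true=pi,
        n_reads=n_reads,
        seed=seed,
        uninformative_rate=0.0,
        error_rate=0.0,
    )
    return simulate_bitvectors(spec)


class TestEmFit:
    def test_k1_closed_form_matches_iterative(self, small_window):
        rng = np.random.default_rng(8)
        codes = rng.choice([0, 1], size=(500, 10), p=[0.92, 0.08]).astype(np.int8)
        matrix = matrix_from_strings(
            small_window, ["".join("01"[c] for c in row) for row in codes]
        )
        closed = em_fit(matrix, 1, validity_correction=False)
        mask_idx = np.flatnonzero(matrix.informative_mask)
        Mut = (matrix.codes[:, mask_idx] == 1).astype(float)
        Match = (matrix.codes[:, mask_idx] == 0).astype(float)

        class SeededRng:
            def uniform(self, lo, hi, size):
                return np.random.default_rng(0).uniform(lo, hi, size)

        iterative = _em_single(
            Mut, Match, matrix.weights, 1, SeededRng(), 1e-12, 500, False, 4,
            mask_idx, matrix.window.width,
        )
        assert iterative["logL"] == pytest.approx(closed.log_likelihood, abs=1e-9)
        ac = matrix.informative_mask
        assert iterative["mu"][0] == pytest.approx(closed.mu[0][ac], abs=1e-9)

    def test_two_cluster_mixing_recovery(self):
        matrix, truth = two_profile_matrix(20_000, seed=60)
        model = em_fit(matrix, 2, restarts=5, seed=3, validity_correction=False)
        # clusters ordered by descending pi; truth major is cluster 0
        assert model.pi[0] == pytest.approx(truth.realized_pre_filter.max(), abs=0.02)

    def test_loglik_monotone_with_correction(self):
        matrix, _ = two_profile_matrix(2000, seed=61)
        model = em_fit(matrix, 2, restarts=2, seed=4, validity_correction=True)
        assert (np.diff(model.loglik_history) >= -1e-8).all()

    def test_read_order_permutation_invariant(self):
        matrix, _ = two_profile_matrix(1500, seed=62)
        model_a = em_fit(matrix, 2, restarts=3, seed=5, validity_correction=False)
        perm = np.random.default_rng(0).permutation(len(matrix))
        shuffled = BitMatrix(
            matrix.window,
            matrix.codes[perm],
            [matrix.read_ids[i] for i in perm],
            matrix.weights[perm],
        )
        model_b = em_fit(shuffled, 2, restarts=3, seed=5, validity_correction=False)
        assert model_b.pi == pytest.approx(model_a.pi, abs=1e-9)
        assert model_b.log_likelihood == pytest.approx(model_a.log_likelihood, abs=1e-6)

    def test_k_exceeding_distinct_vectors_rejected(self, small_window):
        matrix = matrix_from_strings(small_window, ["0000000000"] * 50)
        with pytest.raises(ValueError):
            em_fit(matrix, 2)

    def test_near_degenerate_collapses_and_bic_prefers_k1(self, small_window):
        # 499 identical vectors plus one variant: K=2 is overparameterized
        rows = ["0000000000"] * 499 + ["0100000000"]
        matrix = matrix_from_strings(small_window, rows)
        m1 = em_fit(matrix, 1, validity_correction=False)
        m2 = em_fit(matrix, 2, restarts=3, seed=1, validity_correction=False)
        assert m1.bic < m2.bic

    def test_dedup_loglik_equivalence(self):
        from dmsensemble.bitvectors import deduplicate

        matrix, _ = two_profile_matrix(1200, seed=63)
        dedup = deduplicate(matrix)
        a = em_fit(matrix, 2, restarts=2, seed=7, validity_correction=False)
        b = em_fit(dedup, 2, restarts=2, seed=7, validity_correction=False)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-9)


class TestSelectK:
    def test_single_profile_selects_k1(self):
        hits = 0
        for seed in range(10):
            matrix, _ = two_profile_matrix(1500, seed=100 + seed, pi=(1.0, 0.0))
            model, _ = select_k(
                matrix, k_max=2, restarts=3, seed=seed, validity_correction=False
            )
            hits += model.K == 1
        assert hits >= 9

    def test_separated_two_profiles_select_k2(self):
        hits = 0
        for seed in range(10):
            matrix, _ = two_profile_matrix(4000, seed=200 + seed)
            model, _ = select_k(
                matrix, k_max=3, restarts=3, seed=seed, validity_correction=False
            )
            hits += model.K == 2
        assert hits >= 9

    def test_kmax_one_single_row(self, small_window):
        rng = np.random.default_rng(2)
        codes = rng.choice([0, 1], size=(100, 10), p=[0.9, 0.1]).astype(np.int8)
        matrix = matrix_from_strings(
            small_window, ["".join("01"[c] for c in row) for row in codes]
        )
        model, table = select_k(matrix, k_max=1, validity_correction=False)
        assert model.K == 1 and len(table) == 1


class TestClusterAbundances:
    def _model_with_pi(self, pi):
        matrix, _ = two_profile_matrix(500, seed=64)
        model = em_fit(matrix, 1, validity_correction=False)
        model.pi = np.array(pi)
        return model

    def test_descending_percentages(self):
        assert cluster_abundances(self._model_with_pi([0.13, 0.87])) == pytest.approx(
            [87.0, 13.0]
        )

    def test_tie_and_sum(self):
        pct = cluster_abundances(self._model_with_pi([0.5, 0.5]))
        assert pct == pytest.approx([50.0, 50.0]) and pct.sum() == 100.0

    def test_k1_is_hundred(self):
        assert cluster_abundances(self._model_with_pi([1.0])) == pytest.approx([100.0])
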