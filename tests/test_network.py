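"""Soft thresholding, scale-free fitting and TOM, against verbatim oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcncalib import (
    ValidationError,
    fit_power_law,
    pick_soft_threshold,
    power_adjacency,
    scale_free_fit,
    tom,
)
from gcncalib.network import AdjacencyMatrix
from gcncalib.similarity import SimilarityMatrix


def _sim(values):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(
        values=values, gene_ids=[f"g{j}" for j in range(values.shape[0])], method="test"
    )


def _adj(values, beta=1):
    values = np.asarray(values, dtype=float)
    np.fill_diagonal(values, 0.0)
    return AdjacencyMatrix(
        values=values, gene_ids=[f"g{j}" for j in range(values.shape[0])], beta=beta
    )


def random_adj(rng, n):
    A = rng.uniform(0.0, 1.0, size=(n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


def tom_oracle(A):
    """Triple-loop reference implementation of the topological overlap."""
    n = A.shape[0]
    W = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                W[i, j] = 1.0
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(A[i, u] for u in range(n) if u != i)
            k_j = sum(A[j, u] for u in range(n) if u != j)
            W[i, j] = (l_ij + A[i, j]) / (min(k_i, k_j) + 1.0 - A[i, j])
    return W


class TestPowerAdjacency:
    def test_beta_one_is_identity_off_diagonal(self, rng):
        M = random_adj(rng, 8)
        np.fill_diagonal(M, 1.0)
        out = power_adjacency(_sim(M), 1).values
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_array_equal(out[off], M[off])
        assert np.all(np.diag(out) == 0.0)

    def test_direct_exponentiation(self):
        M = np.full((3, 3), 0.5)
        np.fill_diagonal(M, 1.0)
        out = power_adjacency(_sim(M), 6).values
        assert out[0, 1] == pytest.approx(0.015625, abs=1e-15)

    @pytest.mark.parametrize("beta", [0, -3, 2.5, True])
    def test_invalid_beta_rejected(self, beta):
        M = np.eye(3)
        with pytest.raises(ValidationError):
            power_adjacency(_sim(M), beta)

    def test_powers_stay_in_unit_interval_and_decrease(self, rng):
        M = random_adj(rng, 10)
        np.fill_diagonal(M, 1.0)
        prev = power_adjacency(_sim(M), 1).values
        for beta in (2, 3, 5, 8):
            cur = power_adjacency(_sim(M), beta).values
            assert cur.min() >= 0.0 and cur.max() <= 1.0
            assert np.array_equal(cur, cur.T)
            assert np.all(cur <= prev + 1e-15)
            prev = cur


class TestScaleFreeFit:
    def test_exact_power_law_degrees_fit_near_perfectly(self):
        # node counts proportional to k^-2 at evenly spaced degree values:
        # the regression of log p on log k is then an exact straight line
        ks = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        counts = (3600 / ks**2).round().astype(int)  # 3600,900,400,225,144
        degrees = np.repeat(ks, counts)
        r2, slope = fit_power_law(degrees, n_bins=5)
        assert r2 >= 0.99
        assert slope == pytest.approx(-2.0, abs=0.05)

    def test_uniform_degrees_fit_worse_than_power_law(self, rng):
        ks = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        counts = (3600 / ks**2).round().astype(int)
        pl_degrees = np.repeat(ks, counts)
        r2_pl, _ = fit_power_law(pl_degrees, n_bins=5)
        uni_degrees = rng.uniform(1.0, 5.0, size=pl_degrees.size)
        r2_uni, _ = fit_power_law(uni_degrees, n_bins=5)
        assert r2_uni < r2_pl

    def test_equal_degrees_error(self):
        A = np.full((3, 3), 0.4)
        with pytest.raises(ValidationError):
            scale_free_fit(_adj(A))

    def test_too_few_usable_bins_error(self):
        degrees = np.array([1.0] * 50 + [10.0] * 50)
        with pytest.raises(ValidationError, match="usable"):
            fit_power_law(degrees, n_bins=10)


def _power_law_similarity(rng, n=120):
    """Similarity whose degree sequence is power-law-ish already at beta=1."""
    # hub structure: gene i has base weight w_i ~ i^-0.8; edge = w_i * w_j
    w = (np.arange(1, n + 1) ** -0.8) * rng.uniform(0.95, 1.05, n)
    M = np.sqrt(np.outer(w, w))
    M = np.clip((M + M.T) / 2, 0.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return _sim(M)


class TestPickSoftThreshold:
    def test_smallest_qualifying_beta_chosen(self, rng):
        sim = _power_law_similarity(rng)
        report = pick_soft_threshold(sim, beta_grid=range(1, 11), r2_cut=0.85)
        qualifying = [
            c["beta"] for c in report.candidates if c["r2"] is not None and c["r2"] >= 0.85
        ]
        assert qualifying, "constructed similarity should pass the cut somewhere"
        assert report.chosen_beta == min(qualifying)
        assert not report.flagged

    def test_beta_one_chosen_when_it_already_qualifies(self, rng):
        sim = _power_law_similarity(rng)
        r2_b1, _ = scale_free_fit(power_adjacency(sim, 1))
        assert r2_b1 >= 0.85
        report = pick_soft_threshold(sim, beta_grid=range(1, 11), r2_cut=0.85)
        assert report.chosen_beta == 1

    def test_no_fit_flags_and_argmax_fallback(self, rng):
        # a strongly modular similarity is not scale-free at any power
        block = np.kron(np.eye(2), np.full((10, 10), 0.9))
        noise = rng.uniform(0.0, 0.1, size=(20, 20))
        M = np.clip(block + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(M, 1.0)
        report = pick_soft_threshold(
            _sim(M), beta_grid=range(1, 6), r2_cut=0.999, fallback="argmax"
        )
        assert report.flagged
        r2s = {c["beta"]: c["r2"] for c in report.candidates if c["r2"] is not None}
        assert report.chosen_beta == max(r2s, key=r2s.get)
        assert report.argmax_beta == report.chosen_beta

    def test_no_fit_heuristic_fallback_uses_sample_count(self, rng):
        block = np.kron(np.eye(2), np.full((10, 10), 0.9))
        noise = rng.uniform(0.0, 0.1, size=(20, 20))
        M = np.clip(block + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(M, 1.0)
        report = pick_soft_threshold(
            _sim(M), beta_grid=range(1, 21), r2_cut=0.999, n_samples=25
        )
        assert report.flagged
        assert report.chosen_beta == 8  # 20 <= n_samples < 30

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValidationError):
            pick_soft_threshold(_power_law_similarity(rng), beta_grid=[])


class TestTOM:
    def test_two_node_closed_form_is_identity(self):
        for a in (0.1, 0.5, 0.9):
            A = np.array([[0.0, a], [a, 0.0]])
            W = tom(_adj(A)).values
            assert W[0, 1] == pytest.approx(a, abs=1e-15)

    def test_perfect_clique_has_unit_overlap(self):
        A = np.ones((4, 4))
        np.fill_diagonal(A, 0.0)
        W = tom(_adj(A)).values
        np.testing.assert_allclose(W, 1.0)

    def test_matches_triple_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(555)
        for n in (3, 6, 12, 30):
            A = random_adj(rng, n)
            got = tom(_adj(A)).values
            np.testing.assert_allclose(got, tom_oracle(A), atol=1e-10)

    def test_bounds_hold_for_unit_interval_adjacency(self, rng):
        for _ in range(10):
            A = random_adj(rng, 15)
            W = tom(_adj(A)).values
            assert W.min() >= 0.0 and W.max() <= 1.0 + 1e-12
            assert np.array_equal(W, W.T)

    def test_monotone_in_single_edge_weight(self, rng):
        A = random_adj(rng, 8)
        prev = None
        for a in np.linspace(0.05, 0.95, 7):
            A[2, 5] = A[5, 2] = a
            w = tom(_adj(A.copy())).values[2, 5]
            if prev is not None:
                assert w >= prev - 1e-12
            prev = w

    def test_out_of_range_adjacency_rejected(self):
        A = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValidationError):
            tom(_adj(A))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=1, max_value=8))
def test_tom_oracle_equivalence_property(seed, beta):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 15))
    A = random_adj(rng, n) ** beta
    got = tom(_adj(A, beta=beta)).values
    np.testing.assert_allclose(got, tom_oracle(A), atol=1e-10)
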