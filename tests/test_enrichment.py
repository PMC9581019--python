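"""Hypergeometric enrichment against exact combinatorial oracles; Q scoring."""

import math
from fractions import Fraction

import numpy as np
import pytest

from gcncalib import (
    AnnotationMap,
    ModuleAssignment,
    ValidationError,
    clustering_summary,
    compare_top_terms,
    enrich_module,
    hypergeom_test,
    module_quality,
    pipeline_quality,
    score_modules,
)
from gcncalib.enrichment import EnrichmentResult, ModuleQuality, ModuleQualityReport


def hypergeom_tail_oracle(N, K, n, k, direction):
    """Exact factorial-sum tail probability as a rational number."""
    denom = math.comb(N, n)
    ks = range(k, min(K, n) + 1) if direction == "over" else range(0, k + 1)
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in ks)
    return Fraction(num, denom)


def _sets(N, K, n, k):
    universe = {f"g{i}" for i in range(N)}
    term = {f"g{i}" for i in range(K)}
    module = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
    assert len(module) == n and len(module & term) == k
    return module, term, universe


class TestHypergeomTest:
    def test_worked_example_module_inside_term(self):
        # N=20, K=10, n=5, k=5: p = C(10,5)/C(20,5)
        module, term, universe = _sets(20, 10, 5, 5)
        res = hypergeom_test(module, term, universe, direction="over")
        assert res.p_value == pytest.approx(252 / 15504, rel=1e-12)
        assert res.p_value == pytest.approx(0.016254, abs=1e-6)

    def test_full_under_tail_is_one(self):
        module, term, universe = _sets(20, 10, 5, 5)
        res = hypergeom_test(module, term, universe, direction="under")
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_factorial_oracle_on_sampled_configurations(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k_lo, k_hi = max(0, n + K - N), min(n, K)
            k = int(rng.integers(k_lo, k_hi + 1))
            universe = {f"g{i}" for i in range(N)}
            term = set(rng.choice(sorted(universe), size=K, replace=False))
            rest = sorted(universe - term)
            module = set(list(rng.choice(sorted(term), size=k, replace=False)) +
                         list(rng.choice(rest, size=n - k, replace=False)))
            for direction in ("over", "under"):
                got = hypergeom_test(module, term, universe, direction=direction)
                want = float(hypergeom_tail_oracle(N, K, n, k, direction))
                assert abs(got.p_value - want) < 1e-12

    def test_tail_complement_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            N = int(rng.integers(4, 50))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k_lo, k_hi = max(0, n + K - N), min(n, K)
            k = int(rng.integers(k_lo, k_hi + 1))
            over = float(hypergeom_tail_oracle(N, K, n, k, "over"))
            under = float(hypergeom_tail_oracle(N, K, n, k, "under"))
            pmf = float(
                Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))
            )
            module, term, universe = _sets(N, K, n, k)
            got_o = hypergeom_test(module, term, universe, "over").p_value
            got_u = hypergeom_test(module, term, universe, "under").p_value
            assert got_o + got_u - pmf == pytest.approx(1.0, abs=1e-10)
            assert got_o == pytest.approx(over, abs=1e-12)
            assert got_u == pytest.approx(under, abs=1e-12)

    def test_empty_universe_and_disjoint_module_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_test({"a"}, {"a"}, set())
        with pytest.raises(ValidationError):
            hypergeom_test({"x"}, {"a"}, {"a", "b"})


def _anno():
    return AnnotationMap(
        {
            "B1": ("BP", frozenset({"g0", "g1", "g2"})),
            "B2": ("BP", frozenset({"g3", "g4"})),
            "C1": ("CC", frozenset({"g0", "g5"})),
            "M1": ("MF", frozenset({"g6", "g7"})),
        }
    )


class TestEnrichModule:
    def test_each_term_tested_in_both_directions(self):
        universe = {f"g{i}" for i in range(10)}
        results = enrich_module({"g0", "g1", "g5"}, _anno(), universe)
        assert len(results) == 8  # 4 terms x 2 directions
        assert {(r.term_id, r.direction) for r in results} == {
            (t, d) for t in ("B1", "B2", "C1", "M1") for d in ("over", "under")
        }

    def test_term_outside_universe_skipped(self):
        universe = {f"g{i}" for i in range(6)}  # M1 has no overlap
        results = enrich_module({"g0", "g1"}, _anno(), universe)
        assert {r.term_id for r in results} == {"B1", "B2", "C1"}

    def test_annotation_disjoint_from_universe_rejected(self):
        universe = {"x1", "x2"}
        with pytest.raises(ValidationError):
            enrich_module({"x1"}, _anno(), universe)


def _res(term, p, direction="over", ns="BP"):
    return EnrichmentResult(
        term_id=term,
        namespace=ns,
        direction=direction,
        p_value=p,
        overlap=1,
        module_size=10,
        term_size=5,
        universe_size=100,
    )


class TestModuleQuality:
    def test_five_equal_pvalues_closed_form(self):
        retained, q, flagged = module_quality([_res(f"T{i}", 1e-3) for i in range(5)])
        assert q == pytest.approx(3.0, abs=1e-12)
        assert not flagged

    def test_log_decade_ladder_averages_to_four(self):
        ps = [1e-2, 1e-3, 1e-4, 1e-5, 1e-6]
        retained, q, _ = module_quality([_res(f"T{i}", p) for i, p in enumerate(ps)])
        assert q == pytest.approx(4.0, abs=1e-12)

    def test_only_five_smallest_enter_the_score(self):
        ps = [1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 0.5, 0.9]
        full = [_res(f"T{i}", p) for i, p in enumerate(ps)]
        _, q_full, _ = module_quality(full)
        _, q_trim, _ = module_quality(full[:5])
        assert q_full == pytest.approx(q_trim, abs=1e-12)

    def test_fewer_than_five_terms_flagged_with_shrunk_divisor(self):
        results = [_res("T1", 1e-4), _res("T2", 1e-2)]
        retained, q, flagged = module_quality(results)
        assert flagged
        assert q == pytest.approx((4 + 2) / 2, abs=1e-12)

    def test_tie_break_by_term_id_is_deterministic(self):
        results = [_res(t, 1e-3) for t in ("TB", "TA", "TD", "TC", "TE", "TF")]
        retained, _, _ = module_quality(results)
        assert [r.term_id for r in retained] == ["TA", "TB", "TC", "TD", "TE"]

    def test_term_level_dedup_keeps_best_direction(self):
        results = [_res("T1", 0.5, "over"), _res("T1", 1e-4, "under"),
                   _res("T2", 1e-2, "over")]
        retained, _, _ = module_quality(results, dedup="term")
        assert [(r.term_id, r.direction) for r in retained] == [
            ("T1", "under"), ("T2", "over"),
        ]


class TestPipelineQuality:
    def test_single_module(self):
        assert pipeline_quality([4.0]) == pytest.approx(4.0)

    def test_average_of_two(self):
        assert pipeline_quality([2.0, 4.0]) == pytest.approx(3.0)

    def test_order_invariant(self):
        assert pipeline_quality([1.0, 5.0, 3.0]) == pipeline_quality([5.0, 3.0, 1.0])

    def test_zero_modules_rejected(self):
        with pytest.raises(ValidationError):
            pipeline_quality([])


def _quality_report(term_sets, qs):
    mods = []
    for lab, (terms, q) in enumerate(zip(term_sets, qs), start=1):
        retained = [_res(t, 1e-3) for t in terms]
        mods.append(ModuleQuality(label=lab, size=40, retained=retained, q=q))
    return ModuleQualityReport(modules=mods, q_bar=float(np.mean(qs)))


class TestCompareTopTerms:
    def test_identical_reports_share_all_five(self):
        r = _quality_report([["a", "b", "c", "d", "e"]], [4.0])
        assert compare_top_terms(r, r) == 5

    def test_disjoint_sets_share_none(self):
        a = _quality_report([["a", "b", "c", "d", "e"]], [4.0])
        b = _quality_report([["v", "w", "x", "y", "z"]], [4.0])
        assert compare_top_terms(a, b) == 0

    def test_partial_overlap_counted(self):
        a = _quality_report([["a", "b", "c", "d", "e"]], [4.0])
        b = _quality_report([["a", "b", "x", "y", "z"]], [4.0])
        assert compare_top_terms(a, b) == 2

    def test_top_module_is_max_quality(self):
        a = _quality_report(
            [["a", "b", "c", "d", "e"], ["v", "w", "x", "y", "z"]], [2.0, 6.0]
        )
        b = _quality_report([["v", "w", "x", "y", "z"]], [4.0])
        assert compare_top_terms(a, b) == 5


class TestClusteringSummary:
    def test_counts_and_percentage(self):
        labels = {f"g{i}": 0 for i in range(18)}
        labels.update({f"h{i}": 1 + (i % 3) for i in range(82)})
        rows = clustering_summary({"alpha": ModuleAssignment(labels)})
        assert rows[0]["n_modules"] == 3
        assert rows[0]["pct_unassigned"] == 18.0

    def test_all_assigned_and_none_assigned(self):
        full = ModuleAssignment({f"g{i}": 1 for i in range(40)})
        empty = ModuleAssignment({f"g{i}": 0 for i in range(40)})
        rows = clustering_summary({"a": full, "b": empty})
        assert rows[0]["pct_unassigned"] == 0.0
        assert rows[1] == {"pipeline": "b", "n_modules": 0, "pct_unassigned": 100.0}

    def test_mismatched_universes_rejected(self):
        a = ModuleAssignment({"g1": 1, "g2": 1})
        b = ModuleAssignment({"g1": 1, "g3": 1})
        with pytest.raises(ValidationError):
            clustering_summary({"a": a, "b": b})


def test_score_modules_end_to_end_planted(tiny_benchmark):
    spec, expr, anno, truth = tiny_benchmark
    assignment = ModuleAssignment(dict(truth.labels))
    report = score_modules(assignment, anno)
    assert report.n_modules == 2
    # each planted module's best over-represented term is its planted term
    for mod in report.modules:
        best = mod.retained[0]
        assert best.term_id in truth.planted_terms[mod.label]
        assert best.direction == "over"
    assert report.q_bar == pytest.approx(np.mean([m.q for m in report.modules]))
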