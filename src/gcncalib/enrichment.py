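"""Hypergeometric term enrichment and module-quality scoring.

Each module is tested against every annotation term in six batteries: the
three namespaces (BP, CC, MF) crossed with two tail directions
(over-representation P(X >= k) and under-representation P(X <= k), X
hypergeometric).  Tails are exact sums — no normal approximation — so
p-values are always strictly positive.

A module's quality is the negative log10 of the geometric mean of its five
smallest p-values pooled across the six batteries:

    Q_j = -(sum_{i=1..5} log10 p_i) / 5

and a pipeline's aggregate quality is the plain average of Q_j over its
modules (unassigned genes, label 0, excluded).  No multiple-testing
correction is applied before the five-smallest selection: raw p-values are
ranked, with ties broken by (term id, direction) for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AnnotationMap, ModuleAssignment, ValidationError, NAMESPACES

__all__ = [
    "EnrichmentResult",
    "ModuleQuality",
    "ModuleQualityReport",
    "hypergeom_test",
    "enrich_module",
    "module_quality",
    "pipeline_quality",
    "score_modules",
    "compare_top_terms",
    "clustering_summary",
]

N_RETAINED = 5  # p-values kept per module for the quality score


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one hypergeometric test of a module against a term."""

    term_id: str
    namespace: str
    direction: str  # "over" | "under"
    p_value: float
    overlap: int
    module_size: int
    term_size: int
    universe_size: int


@dataclass
class ModuleQuality:
    """Per-module quality: the retained p-values and Q_j."""

    label: int
    size: int
    retained: list[EnrichmentResult]
    q: float
    flagged_few_terms: bool = False

    @property
    def top_terms(self) -> list[str]:
        return [r.term_id for r in self.retained]


@dataclass
class ModuleQualityReport:
    """All module qualities for one pipeline plus the aggregate Q-bar."""

    modules: list[ModuleQuality] = field(default_factory=list)
    q_bar: float = float("nan")

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def top_module(self) -> ModuleQuality:
        if not self.modules:
            raise ValidationError("report has no modules")
        return max(self.modules, key=lambda m: m.q)


def hypergeom_test(
    module_genes: frozenset[str] | set[str],
    term_genes: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    direction: str = "over",
    term_id: str = "",
    namespace: str = "BP",
) -> EnrichmentResult:
    """Exact hypergeometric tail test of a module against one term.

    With N = |universe|, K = |term ∩ universe|, n = |module|,
    k = |module ∩ term|: over-representation is P(X >= k) and
    under-representation P(X <= k) for X ~ Hypergeometric(N, K, n).
    """
    if direction not in ("over", "under"):
        raise ValidationError(f"direction must be 'over' or 'under', got {direction!r}")
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty universe")
    module = frozenset(module_genes) & universe
    if not module:
        raise ValidationError("module has no genes in the universe")
    term = frozenset(term_genes) & universe
    N, K, n = len(universe), len(term), len(module)
    if K == 0:
        raise ValidationError("term has no genes in the universe")
    k = len(module & term)
    if direction == "over":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    else:
        p = float(stats.hypergeom.cdf(k, N, K, n))
    p = min(max(p, 5e-324), 1.0)  # exact tails are > 0; guard rounding
    return EnrichmentResult(
        term_id=term_id,
        namespace=namespace,
        direction=direction,
        p_value=p,
        overlap=k,
        module_size=n,
        term_size=K,
        universe_size=N,
    )


def enrich_module(
    module_genes: frozenset[str] | set[str],
    annotation: AnnotationMap,
    universe: frozenset[str] | set[str],
) -> list[EnrichmentResult]:
    """Run the six test batteries (3 namespaces x 2 directions) on a module.

    Every term with at least one universe gene is tested in its namespace
    in both directions; terms with no universe overlap are skipped.
    Results are pooled across batteries.
    """
    if not len(annotation):
        raise ValidationError("empty annotation map")
    universe = frozenset(universe)
    results: list[EnrichmentResult] = []
    any_term = False
    for term_id, (ns, genes) in annotation.entries.items():
        if not (genes & universe):
            continue  # K = 0: skipped
        any_term = True
        for direction in ("over", "under"):
            results.append(
                hypergeom_test(
                    module_genes,
                    genes,
                    universe,
                    direction=direction,
                    term_id=term_id,
                    namespace=ns,
                )
            )
    if not any_term:
        raise ValidationError("no annotation term overlaps the universe")
    return results


def module_quality(
    results: list[EnrichmentResult],
    dedup: str = "pair",
) -> tuple[list[EnrichmentResult], float, bool]:
    """Retain the five smallest p-values and compute Q_j.

    Q_j = -(sum of log10 of the retained p-values) / (number retained).
    With fewer than five distinct testable units the available p-values are
    all retained, the divisor shrinks accordingly and the module is flagged.

    ``dedup`` chooses the unit of selection: ``"pair"`` (default) keeps
    (term, direction) pairs distinct; ``"term"`` keeps only the best
    direction per term.  Ties are broken by (p, term, direction) so the
    retained set is deterministic.
    """
    if not results:
        raise ValidationError("no enrichment results for the module")
    if dedup not in ("pair", "term"):
        raise ValidationError(f"unknown dedup {dedup!r}")
    if dedup == "term":
        best: dict[str, EnrichmentResult] = {}
        for r in results:
            cur = best.get(r.term_id)
            if cur is None or (r.p_value, r.direction) < (cur.p_value, cur.direction):
                best[r.term_id] = r
        pool = list(best.values())
    else:
        pool = list({(r.term_id, r.direction): r for r in results}.values())
    pool.sort(key=lambda r: (r.p_value, r.term_id, r.direction))
    retained = pool[:N_RETAINED]
    if any(r.p_value <= 0.0 for r in retained):
        raise ValidationError("retained p-value of 0 (tails must be exact)")
    q = -sum(math.log10(r.p_value) for r in retained) / len(retained)
    flagged = len(retained) < N_RETAINED
    return retained, q, flagged


def pipeline_quality(qualities: list[float]) -> float:
    """Q-bar: plain average of module qualities over a pipeline's modules."""
    if not qualities:
        raise ValidationError("zero modules: average quality undefined")
    return float(np.mean(qualities))


def score_modules(
    assignment: ModuleAssignment,
    annotation: AnnotationMap,
    universe: frozenset[str] | set[str] | None = None,
    annotated_only: bool = False,
    dedup: str = "pair",
) -> ModuleQualityReport:
    """Score every module of an assignment and aggregate into Q-bar.

    ``universe`` defaults to all genes in the assignment; with
    ``annotated_only=True`` it is intersected with the annotated genes
    (whether unannotated genes count in N is a modelling choice; the
    default keeps them, matching the usual gene-universe semantics).
    """
    if universe is None:
        universe = frozenset(assignment.labels)
    universe = frozenset(universe)
    if annotated_only:
        universe = universe & annotation.genes()
    report = ModuleQualityReport()
    for lab in range(1, assignment.n_modules + 1):
        members = frozenset(assignment.module_members(lab))
        results = enrich_module(members, annotation, universe)
        retained, q, flagged = module_quality(results, dedup=dedup)
        report.modules.append(
            ModuleQuality(
                label=lab,
                size=len(members),
                retained=retained,
                q=q,
                flagged_few_terms=flagged,
            )
        )
    report.q_bar = pipeline_quality([m.q for m in report.modules])
    return report


def compare_top_terms(report_a: ModuleQualityReport, report_b: ModuleQualityReport) -> int:
    """How many of the five retained terms of the two top modules are shared."""
    top_a = report_a.top_module()
    top_b = report_b.top_module()
    return len(set(top_a.top_terms) & set(top_b.top_terms))


def clustering_summary(
    assignments: dict[str, ModuleAssignment],
) -> list[dict]:
    """Per-pipeline module count and percent of unassigned genes.

    All assignments must cover the same gene universe.  The percentage is
    reported to one decimal place.
    """
    if not assignments:
        raise ValidationError("no assignments to summarize")
    universes = {frozenset(a.labels) for a in assignments.values()}
    if len(universes) != 1:
        raise ValidationError("assignments cover different gene universes")
    rows = []
    for name, a in assignments.items():
        rows.append(
            {
                "pipeline": name,
                "n_modules": a.n_modules,
                "pct_unassigned": round(100.0 * a.unassigned_fraction(), 1),
            }
        )
    return rows
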