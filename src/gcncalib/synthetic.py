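"""Synthetic expression matrices with planted co-expression modules.

The generator emulates the structure a curated microarray series is
assumed to have: a positive samples x genes intensity grid in which groups
of genes co-vary because they respond to a shared latent driver, embedded
in a background of independent genes.  Each planted module m draws one
latent sample profile z_m ~ N(0, 1)^samples; a member gene j is

    g_ij = baseline_j + amplitude * (sqrt(rho) * z_m[i] + sqrt(1-rho) * e_ij)

with e_ij ~ N(0, 1), so any two same-module genes have correlation rho in
expectation while background genes (baseline + amplitude * e only) are
uncorrelated.  The matrix is then shifted, if needed, so every value is
strictly positive (shift rather than truncation, which would distort the
planted correlations).

A matched annotation map plants one term per module whose gene set
overlaps the module at a configurable precision and recall, plus random
decoy terms spread over the three namespaces, so enrichment scoring has a
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationMap, ExpressionMatrix, ValidationError, NAMESPACES

__all__ = ["SyntheticSpec", "GroundTruth", "generate_expression", "generate_annotation", "generate_benchmark"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module benchmark.

    Defaults are the standard desk-scale benchmark: 1000 genes, 50
    samples, 5 modules of 150 genes (250 background genes), within-module
    correlation 0.7.
    """

    n_genes: int = 1000
    n_samples: int = 50
    module_sizes: tuple[int, ...] = (150, 150, 150, 150, 150)
    rho: float = 0.7
    amplitude: float = 1.0
    baseline_low: float = 5.0
    baseline_high: float = 9.0
    terms_per_module: int = 1
    term_precision: float = 0.9
    term_recall: float = 0.9
    n_decoy_terms: int = 30
    decoy_size_low: int = 20
    decoy_size_high: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValidationError("need at least 2 genes and 2 samples")
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ValidationError("module sizes must be positive")
        if not (0.0 < self.rho < 1.0):
            raise ValidationError(f"rho must be strictly inside (0, 1), got {self.rho}")
        if not (0.0 < self.term_precision <= 1.0 and 0.0 < self.term_recall <= 1.0):
            raise ValidationError("term precision/recall must be in (0, 1]")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)


@dataclass
class GroundTruth:
    """Planted labels (0 = background) and planted term ids per module."""

    labels: dict[str, int]
    planted_terms: dict[int, list[str]] = field(default_factory=dict)

    def labels_array(self, gene_order: list[str]) -> np.ndarray:
        return np.array([self.labels[g] for g in gene_order], dtype=int)


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a positive expression matrix with planted co-expressed modules.

    Deterministic given ``spec.seed``: the same spec yields a bit-identical
    matrix.  Gene order is module 1 genes, module 2 genes, ..., background
    genes; downstream code never relies on this ordering.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_samples, spec.n_genes
    gene_ids = [f"g{j:04d}" for j in range(n)]
    sample_ids = [f"s{i:03d}" for i in range(m)]
    baselines = rng.uniform(spec.baseline_low, spec.baseline_high, size=n)
    noise = rng.standard_normal((m, n))
    G = baselines[None, :] + spec.amplitude * np.sqrt(1.0 - spec.rho) * noise
    labels = np.zeros(n, dtype=int)
    start = 0
    for mod, size in enumerate(spec.module_sizes, start=1):
        idx = np.arange(start, start + size)
        labels[idx] = mod
        latent = rng.standard_normal(m)
        G[:, idx] += spec.amplitude * np.sqrt(spec.rho) * latent[:, None]
        start += size
    # background genes keep full-amplitude independent noise
    bg = labels == 0
    if bg.any():
        G[:, bg] = baselines[None, bg] + spec.amplitude * noise[:, bg]
    lo = G.min()
    if lo <= 0:
        G = G + (-lo + 0.1)  # shift, never truncate
    truth = GroundTruth(labels={g: int(v) for g, v in zip(gene_ids, labels)})
    return ExpressionMatrix(values=G, sample_ids=sample_ids, gene_ids=gene_ids), truth


def generate_annotation(truth: GroundTruth, spec: SyntheticSpec) -> AnnotationMap:
    """Build an annotation map with one planted-enriched term per module.

    A planted term for module m contains ``recall * |m|`` member genes plus
    enough non-member genes to bring its precision down to
    ``term_precision``.  Decoy terms are uniform random gene sets across
    all three namespaces.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 104729)))
    genes = list(truth.labels)
    entries: dict[str, tuple[str, frozenset[str]]] = {}
    truth.planted_terms = {}
    modules = sorted({v for v in truth.labels.values() if v > 0})
    for mod in modules:
        members = [g for g in genes if truth.labels[g] == mod]
        outside = [g for g in genes if truth.labels[g] != mod]
        truth.planted_terms[mod] = []
        for t in range(spec.terms_per_module):
            n_in = max(1, round(spec.term_recall * len(members)))
            chosen = list(rng.choice(members, size=n_in, replace=False))
            # precision = n_in / (n_in + n_out)  =>  n_out
            n_out = round(n_in * (1.0 - spec.term_precision) / spec.term_precision)
            if n_out > 0:
                chosen += list(rng.choice(outside, size=min(n_out, len(outside)), replace=False))
            term_id = f"TERM:M{mod}_{t}"
            ns = NAMESPACES[(mod - 1) % len(NAMESPACES)]
            entries[term_id] = (ns, frozenset(chosen))
            truth.planted_terms[mod].append(term_id)
    for dk in range(spec.n_decoy_terms):
        size = int(rng.integers(spec.decoy_size_low, spec.decoy_size_high + 1))
        size = min(size, len(genes))
        chosen = frozenset(rng.choice(genes, size=size, replace=False))
        ns = NAMESPACES[dk % len(NAMESPACES)]
        entries[f"DECOY:{dk:03d}"] = (ns, chosen)
    return AnnotationMap(entries)


def generate_benchmark(
    spec: SyntheticSpec | None = None, seed: int | None = None
) -> tuple[ExpressionMatrix, AnnotationMap, GroundTruth]:
    """One-call benchmark: expression matrix, annotation map, ground truth."""
    if spec is None:
        spec = SyntheticSpec()
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    expr, truth = generate_expression(spec)
    anno = generate_annotation(truth, spec)
    return expr, anno, truth
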