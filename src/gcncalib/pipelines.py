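"""The four end-to-end network-construction pipelines, run under one config.

All four consume the same expression matrix and emit structurally
identical results, so they differ only in how the network is built — the
controlled-comparison design:

* ``alpha`` — calibration, inner-product/min-max similarity, soft
  threshold (no TOM).
* ``beta`` — calibration, cosine similarity, soft threshold (no TOM).
* ``gamma`` — beta's network plus the topological overlap transform.
* ``wgcna`` — the correlation baseline: Pearson similarity with min-max
  rescaling, soft threshold, TOM.

Clustering (UPGMA + dynamic tree cut) and, when an annotation map is
supplied, enrichment-based quality scoring are identical across pipelines.
The pipelines are deterministic; randomness exists only in synthetic-data
generation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

from . import __version__ as _pkg_version
from .calibration import calibrate
from .clustering import (
    DEFAULT_CUT_HEIGHT,
    DEFAULT_DEEP_SPLIT,
    DEFAULT_MIN_MODULE_SIZE,
    average_linkage,
    dissimilarity,
    dynamic_tree_cut,
)
from .enrichment import ModuleQualityReport, score_modules
from .io import AnnotationMap, ExpressionMatrix, ModuleAssignment, ValidationError
from .network import (
    DEFAULT_BETA_GRID,
    DEFAULT_N_BINS,
    DEFAULT_R2_CUT,
    SoftThresholdReport,
    pick_soft_threshold,
    power_adjacency,
    tom,
)
from .similarity import (
    cosine_similarity,
    innerprod_similarity,
    pearson_minmax_similarity,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "run_pipeline",
    "run_alpha",
    "run_beta",
    "run_gamma",
    "run_wgcna_style",
    "run_all",
    "PIPELINES",
]

logger = logging.getLogger("gcncalib")

PIPELINES = ("alpha", "beta", "gamma", "wgcna")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")


@dataclass
class PipelineConfig:
    """Every tunable of a pipeline run, with documented defaults."""

    pipeline: str = "gamma"
    beta_grid: tuple[int, ...] = DEFAULT_BETA_GRID
    r2_cut: float = DEFAULT_R2_CUT
    n_bins: int = DEFAULT_N_BINS
    fixed_beta: int | None = None  # bypass the soft-threshold search
    st_fallback: str = "heuristic"  # no-fit policy: heuristic | argmax
    apply_tom: bool | None = None  # None: pipeline's own convention
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    cut_height: float = DEFAULT_CUT_HEIGHT
    deep_split: int = DEFAULT_DEEP_SPLIT
    hybrid_cut: bool = True
    variance_policy: str = "error"
    minmax_scope: str = "row_col_union"
    dedup: str = "pair"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValidationError(
                f"pipeline must be one of {PIPELINES}, got {self.pipeline!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_grid"] = list(self.beta_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "beta_grid" in d:
            d["beta_grid"] = tuple(d["beta_grid"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Assignment, soft-threshold report, optional quality, provenance."""

    pipeline: str
    assignment: ModuleAssignment
    soft_threshold: SoftThresholdReport | None
    quality: ModuleQualityReport | None
    provenance: dict = field(default_factory=dict)


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc
    logger.info("stage=%s wall=%.3fs", name, time.perf_counter() - t0)
    return out


def run_pipeline(
    expr: ExpressionMatrix,
    cfg: PipelineConfig | None = None,
    annotation: AnnotationMap | None = None,
) -> PipelineResult:
    """Run one of the four pipelines end to end.

    When ``annotation`` is given, modules are scored by hypergeometric
    enrichment and the result carries a :class:`ModuleQualityReport`.
    """
    if cfg is None:
        cfg = PipelineConfig()
    name = cfg.pipeline

    if name == "wgcna":
        sim = _stage("similarity", pearson_minmax_similarity, expr, scope=cfg.minmax_scope)
    else:
        cal = _stage("calibration", calibrate, expr, variance_policy=cfg.variance_policy)
        if name == "alpha":
            sim = _stage("similarity", innerprod_similarity, cal, scope=cfg.minmax_scope)
        else:  # beta, gamma
            sim = _stage("similarity", cosine_similarity, cal)

    if cfg.fixed_beta is not None:
        st_report = None
        chosen_beta = cfg.fixed_beta
    else:
        st_report = _stage(
            "soft_threshold",
            pick_soft_threshold,
            sim,
            beta_grid=cfg.beta_grid,
            r2_cut=cfg.r2_cut,
            n_bins=cfg.n_bins,
            fallback=cfg.st_fallback,
            n_samples=expr.n_samples,
        )
        chosen_beta = st_report.chosen_beta
    adj = _stage("adjacency", power_adjacency, sim, chosen_beta)

    use_tom = cfg.apply_tom if cfg.apply_tom is not None else name in ("gamma", "wgcna")
    net = _stage("tom", tom, adj) if use_tom else adj

    D = _stage("dissimilarity", dissimilarity, net)
    dend = _stage("linkage", average_linkage, D, list(sim.gene_ids))
    assignment = _stage(
        "tree_cut",
        dynamic_tree_cut,
        dend,
        D,
        min_module_size=cfg.min_module_size,
        cut_height=cfg.cut_height,
        deep_split=cfg.deep_split,
        hybrid=cfg.hybrid_cut,
    )
    logger.info(
        "pipeline=%s beta=%d modules=%d unassigned=%.1f%%",
        name,
        chosen_beta,
        assignment.n_modules,
        100 * assignment.unassigned_fraction(),
    )

    quality = None
    if annotation is not None:
        quality = _stage(
            "enrichment",
            score_modules,
            assignment,
            annotation,
            dedup=cfg.dedup,
        )
    provenance = {
        "pipeline": name,
        "config": cfg.to_dict(),
        "chosen_beta": chosen_beta,
        "n_samples": expr.n_samples,
        "n_genes": expr.n_genes,
        "version": _pkg_version,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return PipelineResult(
        pipeline=name,
        assignment=assignment,
        soft_threshold=st_report,
        quality=quality,
        provenance=provenance,
    )


def _named(name: str):
    def runner(
        expr: ExpressionMatrix,
        cfg: PipelineConfig | None = None,
        annotation: AnnotationMap | None = None,
    ) -> PipelineResult:
        base = cfg.to_dict() if cfg is not None else {}
        base["pipeline"] = name
        return run_pipeline(expr, PipelineConfig.from_dict(base), annotation)

    runner.__name__ = f"run_{name}"
    runner.__doc__ = f"Run the {name} pipeline (see run_pipeline)."
    return runner


run_alpha = _named("alpha")
run_beta = _named("beta")
run_gamma = _named("gamma")
run_wgcna_style = _named("wgcna")


def run_all(
    expr: ExpressionMatrix,
    cfg: PipelineConfig | None = None,
    annotation: AnnotationMap | None = None,
) -> dict[str, PipelineResult]:
    """Run all four pipelines on the same input for a side-by-side comparison."""
    out: dict[str, PipelineResult] = {}
    for name in PIPELINES:
        base = cfg.to_dict() if cfg is not None else {}
        base["pipeline"] = name
        out[name] = run_pipeline(expr, PipelineConfig.from_dict(base), annotation)
    return out
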