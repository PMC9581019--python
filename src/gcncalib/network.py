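"""Weighted-network construction: soft thresholding and topological overlap.

A similarity matrix is raised elementwise to an integer power beta ("soft
threshold") chosen so that the weighted degree distribution approximates a
power law p(k) ~ k^-Gamma.  The fit is scored by the R^2 of the linear
regression of log10 binned-degree frequency on log10 mean bin degree.
Optionally the adjacency is then reweighted by the Topological Overlap
Measure (TOM), which folds shared-neighbor (second-order) information into
each edge:

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu (the
standard convention: zero diagonal, self terms excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ValidationError
from .similarity import SimilarityMatrix, _symmetrize

__all__ = [
    "AdjacencyMatrix",
    "TOMMatrix",
    "SoftThresholdReport",
    "power_adjacency",
    "fit_power_law",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom",
]

DEFAULT_BETA_GRID = tuple(range(1, 21))
DEFAULT_R2_CUT = 0.85
DEFAULT_N_BINS = 10


@dataclass
class AdjacencyMatrix:
    """Elementwise power of a similarity matrix; zero diagonal by convention."""

    values: np.ndarray
    gene_ids: list[str]
    beta: int

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1)  # diagonal already zero


@dataclass
class TOMMatrix:
    """Topological-overlap weights; symmetric, in [0, 1], unit diagonal."""

    values: np.ndarray
    gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class SoftThresholdReport:
    """Scale-free fit per candidate beta and the chosen power.

    ``chosen_beta`` is the smallest candidate whose R^2 reaches ``r2_cut``;
    if none does, the argmax-R^2 candidate is chosen and ``flagged`` is set
    (the situation where powering never yields a good scale-free fit).
    """

    candidates: list[dict] = field(default_factory=list)
    chosen_beta: int = 1
    r2_cut: float = DEFAULT_R2_CUT
    flagged: bool = False
    argmax_beta: int | None = None  # best-R^2 candidate, kept for reporting

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "chosen_beta": self.chosen_beta,
            "r2_cut": self.r2_cut,
            "flagged": self.flagged,
            "argmax_beta": self.argmax_beta,
        }


def _heuristic_beta(n_samples: int) -> int:
    """Fallback soft power by sample count (unsigned-network convention).

    The convention, long established for correlation networks, when no
    power reaches the scale-free cut: fewer samples need a higher power.
    """
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


def power_adjacency(sim: SimilarityMatrix, beta: int) -> AdjacencyMatrix:
    """Raise similarities to the integer power beta; beta = 1 is a passthrough.

    The diagonal is stored as 0 so degree and TOM computations never count
    self-edges.  beta = 1 leaves off-diagonal values bit-identical to the
    input, which is the "drop scale-freeness" ablation.
    """
    if not isinstance(beta, (int, np.integer)) or isinstance(beta, bool) or beta < 1:
        raise ValidationError(f"beta must be an integer >= 1, got {beta!r}")
    A = sim.values.copy() if beta == 1 else sim.values**int(beta)
    np.fill_diagonal(A, 0.0)
    return AdjacencyMatrix(values=A, gene_ids=list(sim.gene_ids), beta=int(beta))


def fit_power_law(
    degrees: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> tuple[float, float]:
    """Score how power-law-like a degree sequence is.

    Degrees are binned into ``n_bins`` equal-width bins; per non-empty bin
    the frequency p(k) and mean degree are computed, and log10 p(k) is
    regressed on log10 mean degree by ordinary least squares.

    Returns
    -------
    (r2, slope)
        R^2 of the regression and its slope (the fitted exponent is
        -slope for a power law p(k) ~ k^-Gamma).

    Raises
    ------
    ValidationError
        All degrees equal (regression undefined) or fewer than 3 usable
        bins after dropping empty ones.
    """
    k = np.asarray(degrees, dtype=float)
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    if k.size < n_bins:
        raise ValidationError(f"{k.size} degrees for {n_bins} bins")
    if np.ptp(k) == 0.0:
        raise ValidationError("all degrees equal: scale-free regression undefined")
    counts, edges = np.histogram(k, bins=n_bins)
    usable = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        in_bin = (k >= edges[b]) & (k < edges[b + 1] if b < n_bins - 1 else k <= edges[b + 1])
        mean_k = k[in_bin].mean()
        if mean_k <= 0:
            continue
        usable.append((mean_k, counts[b] / k.size))
    if len(usable) < 3:
        raise ValidationError(
            f"only {len(usable)} usable degree bins (need >= 3) for the scale-free fit"
        )
    log_k = np.log10([u[0] for u in usable])
    log_p = np.log10([u[1] for u in usable])
    res = stats.linregress(log_k, log_p)
    return float(res.rvalue**2), float(res.slope)


def scale_free_fit(
    adj: AdjacencyMatrix, n_bins: int = DEFAULT_N_BINS
) -> tuple[float, float]:
    """R^2 and slope of the scale-free regression on the weighted degrees."""
    return fit_power_law(adj.degrees(), n_bins=n_bins)


def pick_soft_threshold(
    sim: SimilarityMatrix,
    beta_grid: tuple[int, ...] | list[int] = DEFAULT_BETA_GRID,
    r2_cut: float = DEFAULT_R2_CUT,
    n_bins: int = DEFAULT_N_BINS,
    fallback: str = "heuristic",
    n_samples: int | None = None,
) -> SoftThresholdReport:
    """Choose the smallest power whose network is acceptably scale-free.

    Evaluates :func:`scale_free_fit` for each beta in ``beta_grid`` and
    picks the smallest with R^2 >= ``r2_cut``.  If no candidate reaches
    the cut the report is flagged as not-scale-free and a fallback power
    is chosen: with ``fallback="heuristic"`` (default) the sample-count
    convention for unsigned networks (via ``n_samples``; 6 when unknown),
    with ``fallback="argmax"`` the best-R^2 candidate.  On a genuinely
    non-scale-free network the R^2 landscape is flat noise, so its argmax
    is arbitrary and can land on beta = 1; the heuristic default avoids
    that degeneracy.  The best-R^2 candidate is always recorded as
    ``argmax_beta``.  Candidates whose fit is degenerate are recorded
    with ``r2 = None`` and skipped.
    """
    if not beta_grid:
        raise ValidationError("empty beta grid")
    if fallback not in ("heuristic", "argmax"):
        raise ValidationError(f"unknown fallback {fallback!r}")
    grid = sorted(int(b) for b in beta_grid)
    report = SoftThresholdReport(r2_cut=r2_cut)
    best: tuple[float, int] | None = None
    chosen: int | None = None
    for b in grid:
        adj = power_adjacency(sim, b)
        entry: dict = {"beta": b, "mean_k": float(adj.degrees().mean())}
        try:
            r2, slope = scale_free_fit(adj, n_bins=n_bins)
        except ValidationError as exc:
            entry.update(r2=None, slope=None, error=str(exc))
            report.candidates.append(entry)
            continue
        entry.update(r2=r2, slope=slope)
        report.candidates.append(entry)
        if best is None or r2 > best[0]:
            best = (r2, b)
        if chosen is None and r2 >= r2_cut:
            chosen = b
    if best is None:
        raise ValidationError("scale-free fit failed for every beta in the grid")
    report.argmax_beta = best[1]
    if chosen is None:
        report.flagged = True
        if fallback == "argmax":
            report.chosen_beta = best[1]
        else:
            hb = _heuristic_beta(n_samples) if n_samples is not None else 6
            # stay inside the user's grid
            report.chosen_beta = min(grid, key=lambda b: abs(b - hb))
    else:
        report.chosen_beta = chosen
        report.flagged = False
    return report


def tom(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological Overlap Measure of a [0, 1] adjacency matrix.

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    shared-neighbor weight l_ij = sum_{u != i,j} a_iu a_uj and degree
    k_i = sum_{u != i} a_iu.  The diagonal is fixed at 1.  For adjacency in
    [0, 1] every entry is in [0, 1].
    """
    A = adj.values
    if np.any(A < 0) or np.any(A > 1):
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if np.any(np.diag(A) != 0):
        A = A.copy()
        np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    # zero diagonal makes (A @ A)_ij = sum_{u != i,j} a_iu a_uj for i != j
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    if np.any(denom <= 0):
        raise ValidationError("non-positive TOM denominator (adjacency out of range)")
    W = (L + A) / denom
    W = _symmetrize(W)
    np.fill_diagonal(W, 1.0)
    return TOMMatrix(values=W, gene_ids=list(adj.gene_ids))
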