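"""Gene-gene similarity matrices: the three variants the pipelines compare.

* ``innerprod_similarity`` — inner products of calibrated gene columns
  (S' = S^T S), rescaled per entry by the min and max over the union of
  row i and column j of S' (the "min-max" normalization).
* ``cosine_similarity`` — cosine of calibrated gene columns; strictly
  positive coordinates make every off-diagonal entry strictly positive.
* ``pearson_minmax_similarity`` — the correlation-based baseline: pairwise
  Pearson correlation of raw gene columns, then the same min-max
  normalization to map negatives into [0, 1].

All outputs are exactly symmetric (upper triangle computed, then mirrored).
The min-max normalization can attain 0 and 1 exactly at scope extremes;
endpoints are kept, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibratedMatrix
from .io import ExpressionMatrix, ValidationError

__all__ = [
    "SimilarityMatrix",
    "minmax_normalize",
    "innerprod_similarity",
    "cosine_similarity",
    "pearson_minmax_similarity",
]


@dataclass
class SimilarityMatrix:
    """Symmetric n x n similarity grid with entries in [0, 1]."""

    values: np.ndarray
    gene_ids: list[str]
    method: str  # innerprod_minmax | cosine | pearson_minmax

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def _symmetrize(M: np.ndarray) -> np.ndarray:
    """Mirror the upper triangle into the lower so symmetry is bitwise."""
    out = np.triu(M)
    return out + np.triu(M, k=1).T


def minmax_normalize(Sp: np.ndarray, scope: str = "row_col_union") -> np.ndarray:
    """Rescale a symmetric matrix entrywise into [0, 1].

    With ``scope="row_col_union"`` (default) entry (i, j) is rescaled by the
    minimum and maximum over the 2n entries of row i and column j of the
    input (diagonal included).  Because the input is symmetric this equals
    min/max over rows i and j, so the result is symmetric.  With
    ``scope="global"`` a single min/max over the whole matrix is used.

    Raises
    ------
    ValidationError
        If any entry's scope is degenerate (max equals min).
    """
    Sp = np.asarray(Sp, dtype=float)
    if scope == "global":
        lo, hi = Sp.min(), Sp.max()
        if hi == lo:
            raise ValidationError("degenerate matrix: all entries equal")
        return _symmetrize((Sp - lo) / (hi - lo))
    if scope != "row_col_union":
        raise ValidationError(f"unknown scope {scope!r}")
    row_min = Sp.min(axis=1)
    row_max = Sp.max(axis=1)
    # symmetric input: col j min == row j min
    lo = np.minimum.outer(row_min, row_min)
    hi = np.maximum.outer(row_max, row_max)
    if np.any(hi == lo):
        i, j = np.argwhere(hi == lo)[0]
        raise ValidationError(
            f"degenerate scope for entry ({i}, {j}): all entries of "
            f"row {i} and column {j} are equal"
        )
    return _symmetrize((Sp - lo) / (hi - lo))


def innerprod_similarity(
    cal: CalibratedMatrix, scope: str = "row_col_union"
) -> SimilarityMatrix:
    """Min-max-normalized inner-product similarity of calibrated genes.

    S' = S^T S, then entrywise min-max rescaling over the row/column-union
    scope.  Not invariant to rescaling a gene column (the inner product
    scales), in contrast to :func:`cosine_similarity`.
    """
    S = cal.values
    Sp = S.T @ S
    M = minmax_normalize(Sp, scope=scope)
    return SimilarityMatrix(values=M, gene_ids=list(cal.gene_ids), method="innerprod_minmax")


def cosine_similarity(cal: CalibratedMatrix) -> SimilarityMatrix:
    """Cosine similarity between calibrated gene columns.

    Diagonal is exactly 1; off-diagonal entries are strictly positive
    because calibrated coordinates are strictly positive.
    """
    S = cal.values
    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0.0):
        raise ValidationError("zero-norm gene column (invalid calibrated matrix)")
    M = (S.T @ S) / np.outer(norms, norms)
    M = _symmetrize(np.clip(M, 0.0, 1.0))
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(values=M, gene_ids=list(cal.gene_ids), method="cosine")


def pearson_minmax_similarity(
    expr: ExpressionMatrix, scope: str = "row_col_union"
) -> SimilarityMatrix:
    """Pearson correlation of raw gene columns, min-max mapped into [0, 1].

    The baseline similarity: correlations (which live in [-1, 1]) are made
    positive with the same row/column-union min-max rescaling used by
    :func:`innerprod_similarity`, not with the conventional (1 + r) / 2.
    """
    G = expr.values
    sd = G.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        names = [g for g, s in zip(expr.gene_ids, sd) if s == 0.0]
        raise ValidationError(f"constant gene(s), Pearson undefined: {names}")
    C = np.corrcoef(G, rowvar=False)
    C = np.clip(C, -1.0, 1.0)
    M = minmax_normalize(C, scope=scope)
    return SimilarityMatrix(values=M, gene_ids=list(expr.gene_ids), method="pearson_minmax")
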