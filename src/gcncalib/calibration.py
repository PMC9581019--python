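"""Per-gene logistic calibration of expression values.

Each gene column is mapped through a sigmoid centered at the gene's mean
and scaled by the gene's *variance* (not the standard deviation):

    s_ij = 1 / (1 + exp(-(g_ij - mu_j) / sigma_j^2))

The variance divisor means the transform is deliberately NOT invariant to
rescaling a gene column: multiplying a column by c rescales deviations by c
but the divisor by c^2, sharpening or flattening the sigmoid.  All outputs
lie strictly in (0, 1) and the map is strictly increasing within a column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, ValidationError

__all__ = ["CalibratedMatrix", "ConstantGeneError", "calibrate"]

# Clamp keeps outputs strictly inside (0,1) even for extreme z at float
# precision, preserving downstream log/norm safety.
_EPS = 1e-12


class ConstantGeneError(ValidationError):
    """A gene column has zero variance, so the calibration is undefined."""


@dataclass
class CalibratedMatrix:
    """Calibrated expression values, strictly in (0, 1), with per-gene stats."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    gene_means: np.ndarray
    gene_variances: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _stable_logistic(z: np.ndarray) -> np.ndarray:
    # Branch on sign so exp() never overflows.
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return np.clip(out, _EPS, 1.0 - _EPS)


def calibrate(
    expr: ExpressionMatrix,
    variance_policy: str = "error",
    ddof: int = 1,
) -> CalibratedMatrix:
    """Apply the per-gene logistic calibration to an expression matrix.

    Parameters
    ----------
    expr
        Validated samples x genes expression matrix.
    variance_policy
        ``"error"`` (default): a constant gene column raises
        :class:`ConstantGeneError` naming the gene.  ``"drop"``: constant
        genes are removed with a warning.
    ddof
        Delta degrees of freedom for the per-gene variance; 1 (default)
        gives the unbiased sample variance, 0 the population variance.

    Returns
    -------
    CalibratedMatrix
        Same shape and identifier order as ``expr`` (minus dropped genes),
        every entry strictly in (0, 1), with the per-gene means and
        variances retained for reporting.
    """
    if variance_policy not in ("error", "drop"):
        raise ValidationError(f"unknown variance_policy {variance_policy!r}")
    G = expr.values
    mu = G.mean(axis=0)
    var = G.var(axis=0, ddof=ddof)
    zero = var == 0.0
    gene_ids = list(expr.gene_ids)
    if zero.any():
        names = [g for g, z in zip(gene_ids, zero) if z]
        if variance_policy == "error":
            raise ConstantGeneError(
                f"constant expression (zero variance) for gene(s): {names}"
            )
        import warnings

        warnings.warn(
            f"dropping {len(names)} constant gene(s): {names}", stacklevel=2
        )
        keep = ~zero
        G = G[:, keep]
        mu = mu[keep]
        var = var[keep]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        if len(gene_ids) < 2:
            raise ValidationError("fewer than 2 genes remain after dropping")
    z = (G - mu) / var
    return CalibratedMatrix(
        values=_stable_logistic(z),
        sample_ids=list(expr.sample_ids),
        gene_ids=gene_ids,
        gene_means=mu,
        gene_variances=var,
    )
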