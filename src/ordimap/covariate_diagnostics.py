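"""Diagnostics for covariate-driven spurious expression structure.

In necrotic tissue the histological composition of each sample acts as a
confounder: hepatocyte transcripts fall and infiltrate transcripts rise
with the necrosis grade, so a large share of genes track the covariate
almost perfectly and gene–gene correlations are dominated by it.  This
module quantifies that effect (per-gene correlation with the covariate,
|R| screen) and estimates the expression each gene would show at zero
covariate — the intercept of the per-gene regression of expression on the
necrosis grade.  The correction is diagnostic: the main ordination removes
the covariate through partial correlations instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import kendall_tau_b
from .matrix_io import ExpressionMatrix


class DiagnosticsError(ValueError):
    pass


@dataclass
class CovariateScreen:
    r: pd.Series                 # per-gene correlation with the covariate
    flagged_ids: list[str]       # strict |R| > threshold
    threshold: float
    method: str

    @property
    def flagged_fraction(self) -> float:
        return len(self.flagged_ids) / len(self.r)


@dataclass
class InterceptCorrection:
    """Per-gene OLS fit of expression (Y) on the covariate (X).

    ``extrapolated`` records that zero covariate lies outside the observed
    covariate range, so intercepts are an extrapolation.
    """

    table: pd.DataFrame          # columns intercept, slope, residual_sd
    extrapolated: bool

    @property
    def intercepts(self) -> pd.Series:
        return self.table["intercept"]


def _check_covariate(covariate: np.ndarray, n_samples: int) -> np.ndarray:
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (n_samples,):
        raise DiagnosticsError("one covariate value per sample required")
    if np.all(covariate == covariate[0]):
        raise DiagnosticsError("constant covariate")
    return covariate


def covariate_screen(
    matrix: ExpressionMatrix,
    covariate,
    threshold: float = 0.9,
    method: str = "pearson",
) -> CovariateScreen:
    """Per-gene correlation of log2 expression with the covariate.

    Flags genes with strict ``|R| > threshold``.  ``method`` is
    ``"pearson"`` (default; the covariate relations are plotted as straight
    lines) or ``"kendall"``.
    """
    X = matrix.values.to_numpy(dtype=float)
    z = _check_covariate(covariate, X.shape[1])
    if method == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        zc = z - z.mean()
        denom = np.sqrt((Xc**2).sum(axis=1) * (zc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc @ zc) / denom
    elif method == "kendall":
        r = np.array([kendall_tau_b(row, z) for row in X])
    else:
        raise DiagnosticsError(f"unknown method {method!r}")
    r = pd.Series(r, index=matrix.gene_ids)
    flagged = list(r.index[r.abs() > threshold])
    return CovariateScreen(r=r, flagged_ids=flagged, threshold=threshold, method=method)


def zero_covariate_expression(matrix: ExpressionMatrix, covariate) -> InterceptCorrection:
    """Per-gene OLS intercept/slope; the intercept predicts expression at
    zero covariate."""
    X = matrix.values.to_numpy(dtype=float)
    z = _check_covariate(covariate, X.shape[1])
    if len(np.unique(z)) < 2:
        raise DiagnosticsError("covariate needs at least 2 distinct values")
    zc = z - z.mean()
    slope = (X @ zc) / (zc**2).sum()
    intercept = X.mean(axis=1) - slope * z.mean()
    resid = X - (intercept[:, None] + slope[:, None] * z)
    dof = max(X.shape[1] - 2, 1)
    resid_sd = np.sqrt((resid**2).sum(axis=1) / dof)
    table = pd.DataFrame(
        {"intercept": intercept, "slope": slope, "residual_sd": resid_sd},
        index=matrix.gene_ids,
    )
    extrapolated = not (z.min() <= 0.0 <= z.max())
    return InterceptCorrection(table=table, extrapolated=extrapolated)


def cross_condition_agreement(control_means, corrected_case) -> float:
    """Pearson correlation between per-gene control means and corrected
    (zero-covariate) case expression, aligned on gene id."""
    a = pd.Series(control_means)
    b = pd.Series(corrected_case)
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise DiagnosticsError("gene sets differ")
        b = b.reindex(a.index)
    if len(a) < 3:
        raise DiagnosticsError("need at least 3 genes")
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
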