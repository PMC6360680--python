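"""Comparison selectors: FDR on two-sample t-tests, and STOCSY-OPLS cutoff.

Two families of per-variable selectors serve as baselines for the BCR
procedure. The FDR family applies Benjamini-Hochberg (independence) or
Benjamini-Yekutieli (arbitrary dependence) step-up control to two-sided
Welch t-test p-values between the label groups. The STOCSY-OPLS selector
("STOCSYO") thresholds the absolute Pearson correlation of each variable
with the response at the critical value corresponding to a significance
level α, computed on the OSC-corrected matrix by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import InputError
from .decomposition import FeatureTable, fit_biplot

__all__ = [
    "FdrVariant",
    "BaselineParams",
    "ttest_pvalues",
    "fdr_select",
    "correlation_cutoff",
    "stocsyo_select",
]


class FdrVariant(str, enum.Enum):
    BH = "bh"
    BY = "by"


@dataclass(frozen=True)
class BaselineParams:
    """Which baseline to run and at what level (q-value or α)."""

    method: str  # "fdr_bh" | "fdr_by" | "stocsyo"
    level: float

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie strictly in (0, 1)")


def ttest_pvalues(table: FeatureTable, equal_var: bool = False) -> np.ndarray:
    """Per-feature two-sided unpaired t-test p-values between label groups.

    Welch (unequal variance) by default. Features with zero variance in both
    groups and equal means get p = 1.
    """
    g0, g1 = table.group_values()
    X0 = table.X[table.labels == g0]
    X1 = table.X[table.labels == g1]
    if X0.shape[0] < 2 or X1.shape[0] < 2:
        raise InputError("both groups need at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(X0, X1, equal_var=equal_var, axis=0)
        pvals = np.asarray(result.pvalue, dtype=float)
    degenerate = np.isnan(pvals)
    if degenerate.any():
        equal_means = np.isclose(X0.mean(axis=0), X1.mean(axis=0))
        pvals[degenerate & equal_means] = 1.0
        pvals[degenerate & ~equal_means] = 0.0
    return pvals


def fdr_select(
    pvals: np.ndarray, q: float, variant: FdrVariant | str = FdrVariant.BH
) -> np.ndarray:
    """Step-up FDR rejection set at level ``q`` (BH or BY)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    method = {"bh": "fdr_bh", "by": "fdr_by"}[FdrVariant(variant).value]
    reject, *_ = multipletests(pvals, alpha=q, method=method)
    return reject


def correlation_cutoff(alpha: float, n: int) -> float:
    """Critical |Pearson r| at two-sided significance level ``alpha``.

    ``r_crit = t* / sqrt(n - 2 + t*^2)`` with ``t*`` the Student-t critical
    value at ``alpha`` with ``n - 2`` degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_star / np.sqrt(n - 2 + t_star**2))


def stocsyo_select(
    table: FeatureTable,
    alpha: float,
    osc_correct: bool = True,
    autoscale: bool = True,
) -> np.ndarray:
    """Select features whose |corr(x_j, Y)| reaches the α-level cutoff.

    By default the correlations are computed on the OSC-corrected matrix
    ``X - t_ortho a_orthoᵀ`` from the same decomposition BCR uses; pass
    ``osc_correct=False`` to correlate the raw centered columns instead.
    Zero-variance features are never selected.
    """
    g0, g1 = table.group_values()
    y = (table.labels == g1).astype(float)
    if osc_correct:
        model = fit_biplot(table, autoscale=autoscale)
        M = (table.X - table.X.mean(axis=0)) / model.column_scales
        M = M - np.outer(model.t_ortho, model.a_ortho)
    else:
        M = table.X - table.X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((M**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, M.T @ yc / (sx * sy), 0.0)
    r_crit = correlation_cutoff(alpha, table.n_samples)
    return (np.abs(r) >= r_crit) & (sx > 0)
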