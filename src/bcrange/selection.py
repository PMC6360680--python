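"""The biplot correlation range (BCR) selection procedure.

For each group label: fit a 95% confidence ellipse to that group's scores in
the (predictive, orthogonal) plane; take the angular wedge between the two
tangent lines from the origin to the ellipse — the *biplot correlation
range*; collect the loading arrows whose direction falls in the wedge; keep
the top fraction τ by arrow magnitude (quantile taken over all features);
drop candidates whose univariate logistic regression against the response is
weak (slope p-value above ``filter_alpha``); and finally take the union of
the per-group survivors.

Because the wedge is defined by directions through the origin, any common
positive rescaling of the scores (including the cosmetic 0.001 display
factor used in biplots) leaves the selection unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._exceptions import DegenerateGroupError
from .decomposition import BiplotModel, FeatureTable

__all__ = [
    "ConfidenceEllipse",
    "AngularRange",
    "SelectionParams",
    "GroupSelection",
    "SelectionResult",
    "fit_group_ellipse",
    "ellipse_angular_range",
    "wedge_membership",
    "magnitude_top_fraction",
    "logistic_slope_pvalue",
    "weak_filter",
    "select_features",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Per-group score ellipse: ``(x-c)ᵀ S⁻¹ (x-c) ≤ radius_sq``."""

    center: np.ndarray
    covariance: np.ndarray
    coverage: float
    radius_sq: float


@dataclass(frozen=True)
class AngularRange:
    """Angle set on the circle: either everything, or one wedge interval.

    ``intervals`` holds ``(start, width)`` pairs with ``start`` in
    [0, 2π) and ``0 < width < 2π``; membership wraps around 2π and the
    interval is closed at both boundaries.
    """

    intervals: tuple[tuple[float, float], ...]
    full_circle: bool = False

    def contains(self, angles: np.ndarray) -> np.ndarray:
        angles = np.asarray(angles, dtype=float)
        if self.full_circle:
            return np.ones(angles.shape, dtype=bool)
        result = np.zeros(angles.shape, dtype=bool)
        for start, width in self.intervals:
            offset = np.mod(angles - start, TWO_PI)
            result |= offset <= width
        return result


@dataclass(frozen=True)
class SelectionParams:
    """Tunables of the BCR procedure.

    ``tau`` is the retained top fraction of arrow magnitudes (default 5%);
    ``coverage`` the ellipse confidence level; ``filter_alpha``
    the weak-separability cutoff on the univariate logistic p-value;
    ``score_display_scale`` only affects plots, never selection;
    ``weighted_arrows`` switches the arrow coordinates to the
    covariance-weighted form ``a_j * sqrt(tᵀt)``.
    """

    tau: float = 0.05
    coverage: float = 0.95
    filter_alpha: float = 0.10
    autoscale: bool = False
    score_display_scale: float = 0.001
    weighted_arrows: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")
        if not (0.0 < self.coverage < 1.0):
            raise ValueError("coverage must lie in (0, 1)")


@dataclass
class GroupSelection:
    """Intermediate and final index sets for one group label."""

    label: object
    ellipse: ConfidenceEllipse | None
    angular_range: AngularRange | None
    wedge_members: set[int]
    top_candidates: set[int]
    filtered_out: list[tuple[int, float]]
    selected: set[int]


@dataclass
class SelectionResult:
    """Full output of :func:`select_features`."""

    per_group: dict[object, GroupSelection]
    union_selected: set[int]
    magnitudes: np.ndarray
    angles: np.ndarray

    def union_filtered(self) -> set[int]:
        """Features filtered in some group and not selected in any."""
        dropped: set[int] = set()
        for sel in self.per_group.values():
            dropped.update(j for j, _ in sel.filtered_out)
        return dropped - self.union_selected


def fit_group_ellipse(
    scores: np.ndarray, group_mask: np.ndarray, coverage: float = 0.95
) -> ConfidenceEllipse:
    """Fit a multivariate-normal confidence ellipse to one group's scores.

    The boundary is the Mahalanobis contour at the chi-square(2 df)
    quantile of ``coverage`` (5.9915 at 95%).
    """
    pts = np.asarray(scores, dtype=float)[np.asarray(group_mask, dtype=bool)]
    if pts.shape[0] < 3:
        raise DegenerateGroupError("need at least 3 samples in the group")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 0:
        raise DegenerateGroupError(
            "singular score covariance (collinear or duplicate scores)"
        )
    radius_sq = float(stats.chi2.ppf(coverage, df=2))
    return ConfidenceEllipse(
        center=center, covariance=cov, coverage=coverage, radius_sq=radius_sq
    )


def ellipse_angular_range(e: ConfidenceEllipse) -> AngularRange:
    """Wedge between the two tangent lines from the origin to the ellipse.

    A direction u is tangent when ``(uᵀS⁻¹c)² = (uᵀS⁻¹u)(cᵀS⁻¹c − r²)``.
    If the origin lies inside (or on) the ellipse every direction meets it
    and the range is the full circle.
    """
    Q = np.linalg.inv(e.covariance)
    c = e.center
    d = float(c @ Q @ c) - e.radius_sq
    if d <= 0:
        warnings.warn(
            "origin inside the confidence ellipse: full-circle range",
            stacklevel=2,
        )
        return AngularRange(intervals=(), full_circle=True)
    qc = Q @ c
    # u^T K u = 0 with K = qc qc^T - d Q encodes the two tangent lines.
    # K is indefinite for an exterior origin; in its eigenbasis the null
    # directions are w1^2 / w2^2 = -lam2 / lam1 with lam2 < 0 < lam1.
    K = np.outer(qc, qc) - d * Q
    eigvals, eigvecs = np.linalg.eigh(K)
    lam2, lam1 = eigvals  # ascending
    theta_c = float(np.arctan2(c[1], c[0]))
    # lam2 * w1^2 + lam1 * w2^2 = 0 with w1^2 = lam1, w2^2 = -lam2.
    w1 = np.sqrt(max(lam1, 0.0))
    w2 = np.sqrt(max(-lam2, 0.0))
    directions = [
        eigvecs @ np.array([w1, w2]),
        eigvecs @ np.array([-w1, w2]),
    ]
    # Each tangent line has two opposite directions; the ray from the origin
    # along u meets the ellipse iff u^T Q c > 0 (the touching parameter
    # t = u^T Q c / u^T Q u must be positive), which picks the sign.
    reps = []
    for u in directions:
        if float(u @ qc) < 0:
            u = -u
        alpha = float(np.arctan2(u[1], u[0]))
        delta = np.mod(alpha - theta_c + np.pi, TWO_PI) - np.pi
        reps.append(delta)
    lo, hi = min(reps), max(reps)
    start = np.mod(theta_c + lo, TWO_PI)
    width = hi - lo
    if width <= 0:  # tangency degenerate: a single-direction sliver
        width = np.finfo(float).eps
    return AngularRange(intervals=((float(start), float(width)),))


def arrow_coordinates(
    model: BiplotModel, weighted: bool = False
) -> np.ndarray:
    """p × 2 loading arrows, optionally scaled by sqrt of the score weights."""
    arrows = model.arrows
    if weighted:
        arrows = arrows * np.sqrt([model.w_pred, model.w_ortho])
    return arrows


def wedge_membership(
    a_pred: np.ndarray, a_ortho: np.ndarray, angular_range: AngularRange
) -> np.ndarray:
    """Which loading arrows point into the wedge (zero arrows excluded)."""
    a_pred = np.asarray(a_pred, dtype=float)
    a_ortho = np.asarray(a_ortho, dtype=float)
    nonzero = (a_pred != 0) | (a_ortho != 0)
    angles = np.arctan2(a_ortho, a_pred)
    return nonzero & angular_range.contains(np.mod(angles, TWO_PI))


def magnitude_top_fraction(
    a_pred: np.ndarray,
    a_ortho: np.ndarray,
    members: np.ndarray,
    tau: float,
) -> np.ndarray:
    """The τ·p largest-magnitude arrows among the wedge members.

    The budget ``k = ceil(τ·p)`` is a fraction of *all* p features ("top τ
    of variables"), but it is spent inside the wedge: the k wedge members
    with the largest magnitudes survive (fewer if the wedge is smaller than
    k). Ties break toward the lower feature index, deterministically.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    m = np.hypot(np.asarray(a_pred, float), np.asarray(a_ortho, float))
    members = np.asarray(members, dtype=bool)
    p = m.shape[0]
    k = int(np.ceil(tau * p))
    member_idx = np.flatnonzero(members)
    if member_idx.size > k:
        order = np.argsort(-m[member_idx], kind="stable")
        member_idx = member_idx[order[:k]]
    out = np.zeros(p, dtype=bool)
    out[member_idx] = True
    return out


def logistic_slope_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wald p-value of the slope in logistic regression of y on x.

    Conventions for pathologies: a constant predictor returns 1 (no
    information); complete separation or non-convergence returns 0 (the
    predictor separates the groups perfectly or nearly so).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        return 1.0
    # Complete separation: the variable is maximally informative; the MLE
    # diverges, so short-circuit before the optimizer sees it.
    x0, x1 = x[y == 0], x[y == 1]
    if x0.max() < x1.min() or x1.max() < x0.min():
        return 0.0
    design = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return 0.0
        if not fit.mle_retvals.get("converged", False):
            return 0.0
        pval = float(fit.pvalues[1])
        lr = 2.0 * (float(fit.llf) - float(fit.llnull))
        lr_p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    if not np.isfinite(pval):
        return lr_p
    # Hauck-Donner guard: near-separation inflates the Wald standard error
    # and drives its p toward 1 for the *most* informative variables; when
    # the likelihood-ratio test flatly contradicts it, trust the latter.
    if pval > 0.05 and lr_p < 1e-4:
        return lr_p
    return pval


def weak_filter(
    table: FeatureTable,
    candidates: set[int] | np.ndarray,
    filter_alpha: float = 0.10,
    pvalue_cache: dict[int, float] | None = None,
) -> tuple[set[int], list[tuple[int, float]]]:
    """Drop candidates whose univariate logistic association with Y is weak.

    Each candidate is tested on its *raw* (uncentered, unscaled) column; it
    is removed iff the slope p-value exceeds ``filter_alpha``. A shared
    ``pvalue_cache`` keyed by feature index avoids refitting across calls on
    the same table.
    """
    g0, g1 = table.group_values()
    y = (table.labels == g1).astype(float)
    kept: set[int] = set()
    removed: list[tuple[int, float]] = []
    for j in sorted(int(j) for j in candidates):
        if pvalue_cache is not None and j in pvalue_cache:
            pval = pvalue_cache[j]
        else:
            pval = logistic_slope_pvalue(table.X[:, j], y)
            if pvalue_cache is not None:
                pvalue_cache[j] = pval
        if pval > filter_alpha:
            removed.append((j, pval))
        else:
            kept.add(j)
    return kept, removed


def select_features(
    model: BiplotModel,
    table: FeatureTable,
    params: SelectionParams | None = None,
    pvalue_cache: dict[int, float] | None = None,
) -> SelectionResult:
    """Run the full BCR pipeline for both group labels and take the union."""
    params = params or SelectionParams()
    arrows = arrow_coordinates(model, weighted=params.weighted_arrows)
    a1, a2 = arrows[:, 0], arrows[:, 1]
    magnitudes = np.hypot(a1, a2)
    angles = np.mod(np.arctan2(a2, a1), TWO_PI)
    scores = model.scores

    per_group: dict[object, GroupSelection] = {}
    union: set[int] = set()
    for label in table.group_values():
        mask = table.labels == label
        try:
            ellipse = fit_group_ellipse(scores, mask, params.coverage)
            angular_range = ellipse_angular_range(ellipse)
        except DegenerateGroupError as err:
            warnings.warn(
                f"group {label!r} degenerate ({err}); contributes no features",
                stacklevel=2,
            )
            per_group[label] = GroupSelection(
                label=label,
                ellipse=None,
                angular_range=None,
                wedge_members=set(),
                top_candidates=set(),
                filtered_out=[],
                selected=set(),
            )
            continue
        members = wedge_membership(a1, a2, angular_range)
        top = magnitude_top_fraction(a1, a2, members, params.tau)
        top_idx = set(np.flatnonzero(top).tolist())
        kept, removed = weak_filter(
            table, top_idx, params.filter_alpha, pvalue_cache
        )
        per_group[label] = GroupSelection(
            label=label,
            ellipse=ellipse,
            angular_range=angular_range,
            wedge_members=set(np.flatnonzero(members).tolist()),
            top_candidates=top_idx,
            filtered_out=removed,
            selected=kept,
        )
        union |= kept
    return SelectionResult(
        per_group=per_group,
        union_selected=union,
        magnitudes=magnitudes,
        angles=angles,
    )
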