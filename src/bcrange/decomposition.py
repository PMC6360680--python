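"""Rank-2 biplot decomposition via orthogonal signal correction plus PLS.

The model splits a centered feature matrix into one component orthogonal to
the response and one predictive component,

    X ≈ t_pred a_predᵀ + t_ortho a_orthoᵀ,

where ``t_ortho`` is the leading principal-component score of X after
projecting out the fitted response direction (direct orthogonal signal
correction), and ``(t_pred, a_pred)`` is the first PLS component of the
OSC-corrected matrix against the binary response. With the score weights
``w = tᵀt`` the biplot inner product of two loading arrows reproduces, term
by term, the Gram matrix of the rank-2 reconstruction — so arrow angles read
as correlations and arrow magnitudes as covariance contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import DegenerateModelError, InputError

__all__ = [
    "FeatureTable",
    "BiplotModel",
    "center_table",
    "project_response",
    "orthogonal_component",
    "pls_first_component",
    "fit_biplot",
    "biplot_covariance",
    "biplot_correlation",
]

#: Relative singular-value cutoff for the rank-revealing pseudo-inverse.
PINV_RTOL = 1e-10


@dataclass
class FeatureTable:
    """Sample × feature intensity matrix with ids and binary group labels."""

    X: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise InputError("id lists must match matrix dimensions")
        if self.labels.shape != (n,):
            raise InputError("labels must be one per sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        """Check the invariants required before model fitting."""
        if not np.all(np.isfinite(self.X)):
            raise InputError("intensity matrix contains non-finite entries")
        if self.n_samples < 4:
            raise InputError("at least 4 samples are required")
        values = np.unique(self.labels)
        if values.size != 2:
            raise InputError(
                f"labels must take exactly two values, got {values.tolist()}"
            )

    def group_values(self) -> tuple[object, object]:
        """The two label values, sorted."""
        values = np.unique(self.labels)
        return values[0], values[1]


@dataclass
class BiplotModel:
    """Fitted rank-2 decomposition with score weights and centering metadata."""

    t_pred: np.ndarray
    a_pred: np.ndarray
    t_ortho: np.ndarray
    a_ortho: np.ndarray
    w_pred: float
    w_ortho: float
    y_hat: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    scaled: bool

    @property
    def scores(self) -> np.ndarray:
        """n × 2 score matrix with columns (predictive, orthogonal)."""
        return np.column_stack([self.t_pred, self.t_ortho])

    @property
    def arrows(self) -> np.ndarray:
        """p × 2 loading arrows with columns (predictive, orthogonal)."""
        return np.column_stack([self.a_pred, self.a_ortho])

    def reconstruction(self) -> np.ndarray:
        """The rank-2 approximation of the centered matrix."""
        return np.outer(self.t_pred, self.a_pred) + np.outer(
            self.t_ortho, self.a_ortho
        )


def center_table(
    table: FeatureTable, autoscale: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center columns, optionally dividing by the column SD.

    Zero-variance columns are centered and left unscaled (scale 1) with a
    warning, so downstream algebra stays finite.

    Returns ``(centered_matrix, column_means, column_scales)``.
    """
    means = table.X.mean(axis=0)
    Xc = table.X - means
    scales = np.ones(table.n_features)
    if autoscale:
        sd = table.X.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} zero-variance column(s) left unscaled",
                stacklevel=2,
            )
        scales = np.where(constant, 1.0, sd)
        Xc = Xc / scales
    return Xc, means, scales


def project_response(Xc: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Orthogonal projection of the response onto the column space of Xc.

    Computed through a rank-revealing pseudo-inverse so near-null directions
    (relative singular value below 1e-10) do not contaminate the fit.
    """
    y = np.asarray(Y, dtype=float)
    if Xc.shape[0] != y.shape[0]:
        raise InputError("response length must match the number of samples")
    if not np.any(Xc):
        warnings.warn("all-zero matrix: projected response is zero", stacklevel=2)
        return np.zeros_like(y)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > PINV_RTOL * s[0]
    basis = u[:, keep]
    return basis @ (basis.T @ y)


def orthogonal_component(
    Xc: np.ndarray, y_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Leading Y-orthogonal principal component and its regression loading.

    Deflates the fitted-response direction, ``M = (I - P_ŷ) Xc``, takes the
    first principal-component score of M as ``t_ortho``, and computes
    ``a_ortho = Xcᵀ t_ortho / (t_orthoᵀ t_ortho)`` from the *full* centered
    matrix. Sign is fixed by making the largest-magnitude entry of
    ``t_ortho`` positive.
    """
    yy = float(y_hat @ y_hat)
    if yy > 0:
        M = Xc - np.outer(y_hat, y_hat @ Xc) / yy
    else:
        M = Xc.copy()
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    if s[0] <= np.finfo(float).eps * max(M.shape) * max(s[0], 1.0) or not np.any(M):
        raise DegenerateModelError(
            "no response-orthogonal variation left to extract"
        )
    t_ortho = M @ vt[0]
    if t_ortho[np.argmax(np.abs(t_ortho))] < 0:
        t_ortho = -t_ortho
    a_ortho = Xc.T @ t_ortho / float(t_ortho @ t_ortho)
    return t_ortho, a_ortho


def pls_first_component(
    X_corr: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First PLS component of the OSC-corrected matrix against the response.

    The weight vector is ``w ∝ X_corrᵀ (Y - Ȳ)`` (unit norm) — the direction
    maximizing covariance with the response — giving ``t_pred = X_corr w``
    and the regression loading ``a_pred = X_corrᵀ t_pred / (t_predᵀ t_pred)``.
    The weight construction already makes cov(t_pred, Y) nonnegative.
    """
    y = np.asarray(Y, dtype=float)
    yc = y - y.mean()
    w = X_corr.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DegenerateModelError("response carries no signal in the matrix")
    w /= norm
    t_pred = X_corr @ w
    tt = float(t_pred @ t_pred)
    if tt == 0:
        raise DegenerateModelError("predictive score vector is zero")
    a_pred = X_corr.T @ t_pred / tt
    return t_pred, a_pred


def fit_biplot(table: FeatureTable, autoscale: bool = False) -> BiplotModel:
    """Fit the full OSC + PLS rank-2 biplot model on a feature table."""
    table.validate()
    Xc, means, scales = center_table(table, autoscale=autoscale)
    g0, g1 = table.group_values()
    y = (table.labels == g1).astype(float)
    y_hat = project_response(Xc, y)
    t_ortho, a_ortho = orthogonal_component(Xc, y_hat)
    X_corr = Xc - np.outer(t_ortho, a_ortho)
    t_pred, a_pred = pls_first_component(X_corr, y)
    return BiplotModel(
        t_pred=t_pred,
        a_pred=a_pred,
        t_ortho=t_ortho,
        a_ortho=a_ortho,
        w_pred=float(t_pred @ t_pred),
        w_ortho=float(t_ortho @ t_ortho),
        y_hat=y_hat,
        column_means=means,
        column_scales=scales,
        scaled=autoscale,
    )


def biplot_covariance(model: BiplotModel, q: int, r: int) -> float:
    """Weighted inner product of loading arrows q and r.

    Equals the (q, r) entry of the Gram matrix of the rank-2 reconstruction,
    i.e. the biplot's covariance measure between the two variables.
    """
    p = model.a_pred.shape[0]
    if not (0 <= q < p and 0 <= r < p):
        raise IndexError(f"feature index out of range [0, {p})")
    return float(
        model.a_pred[q] * model.w_pred * model.a_pred[r]
        + model.a_ortho[q] * model.w_ortho * model.a_ortho[r]
    )


def biplot_correlation(model: BiplotModel, q: int, r: int) -> float:
    """Weighted cosine of the angle between loading arrows q and r."""
    vq = biplot_covariance(model, q, q)
    vr = biplot_covariance(model, r, r)
    if vq <= 0 or vr <= 0:
        raise DegenerateModelError(
            "correlation undefined for a zero-norm loading arrow"
        )
    c = biplot_covariance(model, q, r) / np.sqrt(vq * vr)
    return float(np.clip(c, -1.0, 1.0))
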