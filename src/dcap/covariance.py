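"""Window-specific covariance model for multi-track signal.

Per condition j the model factorises the P x P covariance at window i as

    Sigma_j(i) = diag(sigma_j(i)) . R_j . diag(sigma_j(i))

with a condition-level (window-independent) correlation matrix ``R_j`` and
window-specific standard deviations driven by a smooth mean -> variance
relationship fitted per (condition, factor).  ``R_j`` is estimated from the
genomic background by a covariance decomposition that strips the contribution
of binding means: Cov(X_j) = Cov(background) + Cov(binding means), with the
binding-mean term estimated by the per-factor cross-condition mean matrix.
Replicate variances are estimated after Cholesky whitening of the replicate
residuals, which removes the downward bias of the naive sample variance under
replicate correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from sklearn.base import BaseEstimator

from .layout import TrackLayout
from .normalize import _loess_curve

__all__ = [
    "nearest_correlation",
    "estimate_background_correlation",
    "estimate_peak_correlation",
    "decorrelate_replicates",
    "replicate_variances",
    "MeanVarianceCurve",
    "fit_mean_variance_curve",
    "assemble_covariance",
    "CovarianceModel",
]

VARIANCE_FLOOR = 1e-4
EIGEN_FLOOR = 1e-6


def nearest_correlation(mat: np.ndarray, eigen_floor: float = EIGEN_FLOOR) -> np.ndarray:
    """Condition a symmetric matrix into a positive-definite correlation matrix.

    Eigenvalues below ``eigen_floor`` are clipped up, then the matrix is
    rescaled to unit diagonal.  Matrices with non-positive diagonal entries
    fall back to the identity on those coordinates.
    """
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    mat = (mat + mat.T) / 2.0
    d = np.diag(mat).copy()
    bad = d <= 0
    if bad.any():
        warnings.warn("non-positive diagonal in correlation estimate; conditioning")
        d[bad] = 1.0
        mat = mat.copy()
        mat[bad, :] = 0.0
        mat[:, bad] = 0.0
        mat[np.diag_indices_from(mat)] = d
    scale = np.sqrt(np.diag(mat))
    corr = mat / np.outer(scale, scale)
    w, v = np.linalg.eigh(corr)
    if w.min() < eigen_floor:
        w = np.clip(w, eigen_floor, None)
        corr = (v * w) @ v.T
        scale = np.sqrt(np.diag(corr))
        corr = corr / np.outer(scale, scale)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _noise_share_of_factor_means(Sigma, n_conditions, n_replicates):
    """Noise contribution of the sample factor means' covariance.

    With equal per-condition noise covariance ``Sigma`` and independence
    across conditions, Cov(x-bar_k, x-bar_l) picks up the block-average of
    Sigma's (k, l) replicate block divided by C; broadcast back to the P x P
    track layout (constant within blocks).
    """
    P = Sigma.shape[0]
    R = n_replicates
    K = P // R
    block = Sigma.reshape(K, R, K, R).sum(axis=(1, 3)) / (n_conditions * R * R)
    return np.repeat(np.repeat(block, R, axis=0), R, axis=1)


def estimate_background_correlation(
    Xj: np.ndarray,
    factor_means: np.ndarray,
    n_conditions: int | None = None,
    n_replicates: int | None = None,
) -> np.ndarray:
    """Background correlation of condition j via covariance decomposition.

    ``factor_means`` is the N x P matrix of per-factor means over all
    conditions and replicates (identical within a factor's replicate columns),
    acting as the estimate of the binding-mean component.  The background
    covariance estimate Cov(Xj) - Cov(factor_means) is standardized to a
    correlation matrix and conditioned to be positive definite.

    When ``n_conditions`` and ``n_replicates`` are given, the plug-in bias of
    the decomposition is removed: the sample factor means carry a 1/(C*R)
    share of background noise, so Cov(factor_means) over-subtracts by a
    linear map N(Sigma) of the background covariance itself; the corrected
    estimate solves Sigma = D + N(Sigma) by fixed-point iteration.  Without
    the correction a spurious -1/(C*R - 1) replicate correlation appears even
    for independent tracks.
    """
    Xj = np.asarray(Xj, dtype=float)
    Fm = np.asarray(factor_means, dtype=float)
    if Xj.shape != Fm.shape:
        raise ValueError("Xj and factor_means must have identical shape")
    diff = np.atleast_2d(np.cov(Xj, rowvar=False) - np.cov(Fm, rowvar=False))
    if n_conditions is not None and n_replicates is not None:
        Sigma = diff.copy()
        for _ in range(50):
            new = diff + _noise_share_of_factor_means(
                Sigma, n_conditions, n_replicates)
            if np.max(np.abs(new - Sigma)) < 1e-12:
                Sigma = new
                break
            Sigma = new
        diff = Sigma
    return nearest_correlation(diff)


def estimate_peak_correlation(
    Xj: np.ndarray, factor_means: np.ndarray
) -> np.ndarray:
    """Correlation at pre-defined binding regions via the bottom-50% rule.

    Rows are centred by the per-factor cross-condition mean; rows are then
    ranked by their total variance (sum over columns of squared centred
    values) and the correlation is computed over the bottom 50% — the rows
    least affected by differential binding shifts.  Ties at the median are
    broken by row index.
    """
    Xj = np.asarray(Xj, dtype=float)
    Fm = np.asarray(factor_means, dtype=float)
    if Xj.shape[0] < 4:
        raise ValueError("need at least 4 rows to estimate peak correlation")
    centred = Xj - Fm
    total = (centred ** 2).sum(axis=1)
    order = np.argsort(total, kind="stable")
    keep = order[: max(Xj.shape[0] // 2, 2)]
    sub = centred[keep]
    if np.allclose(sub.std(axis=0), 0):
        warnings.warn("zero-variance centred rows; falling back to identity")
        return np.eye(Xj.shape[1])
    return nearest_correlation(np.cov(sub, rowvar=False))


def decorrelate_replicates(residuals: np.ndarray, R_sub: np.ndarray) -> np.ndarray:
    """Whiten replicate residuals with the Cholesky factor of their correlation.

    ``residuals`` is (N, R) of per-window deviations from the replicate mean;
    ``R_sub`` the R x R replicate sub-correlation.  Returns z = residuals
    multiplied on the right by (L^{-1})' where R_sub = L L', so that under the
    model the entries of z are uncorrelated with unchanged marginal variance
    scale; ``sum(z**2) / (R-1)`` is then an (approximately) unbiased
    per-window variance estimate even under replicate correlation.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    R_sub = np.asarray(R_sub, dtype=float)
    L = cholesky(R_sub, lower=True)
    # z' = L^{-1} e  for each row e
    return solve_triangular(L, residuals.T, lower=True).T


def replicate_variances(
    block: np.ndarray, R_sub: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window replicate mean and decorrelated variance estimate.

    ``block`` is (N, R), one factor's replicates in one condition.  Returns
    (means, variances) with variances from the whitened residuals.
    """
    block = np.asarray(block, dtype=float)
    n, r = block.shape
    if r < 2:
        raise ValueError("replicate_variances requires R >= 2")
    means = block.mean(axis=1)
    resid = block - means[:, None]
    z = decorrelate_replicates(resid, R_sub)
    return means, (z ** 2).sum(axis=1) / (r - 1)


@dataclass
class MeanVarianceCurve:
    """Fitted mean -> variance relationship for one (condition, factor).

    Piecewise-linear interpolation between LOESS knots, clamped at the support
    boundaries and floored at ``floor`` so downstream covariances stay
    positive definite.
    """

    knots_x: np.ndarray
    knots_y: np.ndarray
    floor: float = VARIANCE_FLOOR

    def __call__(self, x: np.ndarray) -> np.ndarray:
        v = np.interp(np.asarray(x, dtype=float), self.knots_x, self.knots_y)
        return np.maximum(v, self.floor)

    def to_dict(self) -> dict:
        return {
            "knots_x": np.asarray(self.knots_x).tolist(),
            "knots_y": np.asarray(self.knots_y).tolist(),
            "floor": self.floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeanVarianceCurve":
        return cls(np.asarray(d["knots_x"]), np.asarray(d["knots_y"]), d["floor"])


def fit_mean_variance_curve(
    means: np.ndarray,
    variances: np.ndarray,
    span: float = 0.5,
    sample_frac: float = 0.01,
    n_bins: int = 25,
    seed: int = 0,
    min_points: int = 300,
) -> MeanVarianceCurve:
    """LOESS fit of per-window variance on per-window mean.

    Uses the same binned-subsample local-linear scheme as the normalization
    step; fitted values are floored at a small positive constant.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if means.shape != variances.shape:
        raise ValueError("means and variances must have equal length")
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    if np.all(variances == 0):
        warnings.warn("all-zero variances; curve pinned at the floor")
        return MeanVarianceCurve(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
    if np.ptp(means) == 0:
        v = float(variances.mean())
        return MeanVarianceCurve(np.array([means[0] - 1, means[0] + 1]),
                                 np.array([v, v]))
    rng = np.random.default_rng(seed)
    xs, ys = _loess_curve(means, variances, span, sample_frac, n_bins,
                          min_points, rng)
    if len(xs) == 1:
        xs = np.array([xs[0] - 1, xs[0] + 1])
        ys = np.array([ys[0], ys[0]])
    return MeanVarianceCurve(xs, ys)


def assemble_covariance(sigma: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Sigma = diag(sigma) . R . diag(sigma) for one window/condition."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return R * np.outer(sigma, sigma)


class CovarianceModel(BaseEstimator):
    """Condition-level correlations plus per-(condition, factor) variance curves.

    Parameters
    ----------
    layout : TrackLayout
    mode : {"background", "peaks"}
        "background" estimates each condition's correlation by the covariance
        decomposition over all windows; "peaks" uses the bottom-50%-variance
        rule appropriate when the matrix holds pre-called binding regions.
    control_values : optional N x (C*P) matrix of input-control signal; when
        given, each condition's correlation is taken directly from the
        controls and no decomposition is performed.
    span, sample_frac, n_bins, min_points, seed : LOESS settings shared with
        the normalization step.

    Fitted attributes
    -----------------
    correlations_ : list of P x P correlation matrices, one per condition.
    curves_ : dict (j, k) -> MeanVarianceCurve.
    provenance_ : how the correlations were obtained.
    """

    def __init__(self, layout: TrackLayout | None = None, mode: str = "background",
                 control_values: np.ndarray | None = None, span: float = 0.5,
                 sample_frac: float = 0.01, n_bins: int = 25,
                 min_points: int = 300, seed: int = 0):
        self.layout = layout
        self.mode = mode
        self.control_values = control_values
        self.span = span
        self.sample_frac = sample_frac
        self.n_bins = n_bins
        self.min_points = min_points
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        layout = self.layout
        if layout is None:
            raise ValueError("CovarianceModel requires a TrackLayout")
        C, K, R = layout.n_conditions, layout.n_factors, layout.n_replicates
        fm = layout.factor_means(X)
        self.correlations_ = []
        if self.control_values is not None:
            self.provenance_ = "control_tracks"
            for j in range(C):
                block = np.asarray(self.control_values)[:, layout.condition_slice(j)]
                self.correlations_.append(nearest_correlation(np.cov(block, rowvar=False)))
        elif self.mode == "peaks":
            self.provenance_ = "peak_bottom50"
            for j in range(C):
                sl = layout.condition_slice(j)
                self.correlations_.append(estimate_peak_correlation(X[:, sl], fm[:, sl]))
        elif C == 1:
            # the decomposition needs cross-condition factor means; with a
            # single condition fall back to the (binding-inflated) naive
            # correlation of the data matrix
            warnings.warn(
                "single condition: background correlation from naive Cor(X)"
            )
            self.provenance_ = "naive_single_condition"
            self.correlations_.append(nearest_correlation(np.cov(X, rowvar=False)))
        else:
            self.provenance_ = "decomposition"
            for j in range(C):
                sl = layout.condition_slice(j)
                self.correlations_.append(
                    estimate_background_correlation(
                        X[:, sl], fm[:, sl], n_conditions=C, n_replicates=R)
                )
        self.curves_ = {}
        self.replicate_means_ = np.empty((X.shape[0], C, K))
        for j in range(C):
            for k in range(K):
                cols = layout.replicate_columns(j, k)
                block = X[:, cols]
                if R >= 2:
                    sub = self.correlations_[j][np.ix_(k * R + np.arange(R),
                                                       k * R + np.arange(R))]
                    means, variances = replicate_variances(block, sub)
                else:
                    means, variances = self._no_replicate_variances(X, j, k)
                self.replicate_means_[:, j, k] = means
                self.curves_[(j, k)] = fit_mean_variance_curve(
                    means, variances, span=self.span,
                    sample_frac=self.sample_frac, n_bins=self.n_bins,
                    seed=self.seed + j * K + k, min_points=self.min_points,
                )
        return self

    def _no_replicate_variances(self, X, j, k):
        """R=1 fallback: variance from residuals across conditions per factor.

        With a single track per (condition, factor), replicate residuals do
        not exist; instead each factor's per-window squared deviation from the
        cross-condition mean, scaled by C/(C-1) for unbiasedness under equal
        means, supplies the variance observations for the curve fit.
        """
        layout = self.layout
        C = layout.n_conditions
        if C < 2:
            raise ValueError("cannot estimate variances with R=1 and C=1")
        cols = [layout.replicate_columns(jj, k)[0] for jj in range(C)]
        block = X[:, cols]
        cross_mean = block.mean(axis=1)
        resid = block[:, list(cols).index(layout.replicate_columns(j, k)[0])] - cross_mean
        variances = resid ** 2 * C / (C - 1)
        means = X[:, layout.replicate_columns(j, k)[0]]
        return means, variances

    def sigma(self, X: np.ndarray) -> np.ndarray:
        """Per-window standard deviations, N x (C*P).

        Entries are constant within each factor's replicate block: the square
        root of the fitted variance curve evaluated at the replicate mean.
        """
        X = np.asarray(X, dtype=float)
        layout = self.layout
        out = np.empty_like(X)
        for j in range(layout.n_conditions):
            for k in range(layout.n_factors):
                cols = layout.replicate_columns(j, k)
                means = X[:, cols].mean(axis=1)
                sd = np.sqrt(self.curves_[(j, k)](means))
                out[:, cols] = sd[:, None]
        return out

    def window_covariance(self, sigma_j: np.ndarray, j: int) -> np.ndarray:
        """Sigma_j(i) for one window given its length-P sigma vector."""
        return assemble_covariance(sigma_j, self.correlations_[j])

    def to_json(self) -> str:
        payload = {
            "layout": self.layout.to_dict(),
            "provenance": self.provenance_,
            "correlations": [c.tolist() for c in self.correlations_],
            "curves": {f"{j},{k}": c.to_dict() for (j, k), c in self.curves_.items()},
        }
        return json.dumps(payload, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CovarianceModel":
        with open(path) as fh:
            payload = json.load(fh)
        layout = TrackLayout.from_dict(payload["layout"])
        model = cls(layout)
        model.provenance_ = payload["provenance"]
        model.correlations_ = [np.asarray(c) for c in payload["correlations"]]
        model.curves_ = {}
        for key, c in payload["curves"].items():
            j, k = map(int, key.split(","))
            model.curves_[(j, k)] = MeanVarianceCurve.from_dict(c)
        return model
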