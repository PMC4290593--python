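"""Signal normalization chain: log2 + pseudocount, per-factor quantile
normalization, and per-track LOESS normalization against the factor mean.

The chain makes tracks comparable across conditions before multivariate
testing: the log2 transform tames the skew of density sums, quantile
normalization equalises the marginal distribution of every track of the same
factor, and the LOESS step removes each track's residual intensity-dependent
bias relative to its factor mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .layout import TrackLayout
from .windows import GenomeWindows

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "loess_normalize",
    "binned_subsample",
    "SignalMatrix",
    "QuantileFactorNormalizer",
    "LoessSignalNormalizer",
    "normalize_signal",
]


def log2_transform(values: np.ndarray, pseudocount: float = 0.1) -> np.ndarray:
    """Elementwise log2(value + pseudocount); values must be non-negative."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("log2_transform requires non-negative input")
    return np.log2(values + pseudocount)


def _quantile_reference(mat: np.ndarray) -> np.ndarray:
    """Mean of order statistics across columns: the reference distribution."""
    return np.sort(mat, axis=0).mean(axis=1)


def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of an N x M matrix to a shared reference.

    The reference is the across-column mean of sorted values; each column's
    entries are replaced by the reference value at their rank, with tied
    entries receiving the mean of their reference quantiles.  With a single
    column the input is returned unchanged.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, m = mat.shape
    if m <= 1:
        return mat.copy()
    ref = _quantile_reference(mat)
    out = np.empty_like(mat)
    for c in range(m):
        col = mat[:, c]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = ref
        # ties: average the reference quantiles over each tied block
        s = pd.Series(mapped)
        out[:, c] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return out


def binned_subsample(
    x: np.ndarray,
    sample_frac: float = 0.01,
    n_bins: int = 25,
    min_points: int = 300,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Indices of a subsample drawn with equal frequency from bins of ``x``.

    The target size is ``sample_frac * len(x)`` (floored at ``min_points`` so
    the scheme stays usable on small inputs); each of ``n_bins`` equal-width
    bins contributes at most ``target / n_bins`` points.  This balances the
    fit support along the signal range, where raw data are dense at low
    signal and sparse at high signal.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    rng = rng or np.random.default_rng(0)
    target = min(n, max(int(round(sample_frac * n)), min_points))
    cap = max(int(np.ceil(target / n_bins)), 2)
    lo, hi = np.min(x), np.max(x)
    if hi <= lo:
        return rng.choice(n, size=min(n, target), replace=False)
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    picks = []
    for b in range(n_bins):
        members = np.flatnonzero(which == b)
        if len(members) == 0:
            continue
        if len(members) <= cap:
            picks.append(members)
        else:
            picks.append(rng.choice(members, size=cap, replace=False))
    return np.sort(np.concatenate(picks))


def _loess_curve(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    sample_frac: float = 0.01,
    n_bins: int = 25,
    min_points: int = 300,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local-linear fit of y on x over a binned subsample.

    Returns (xs, ys) knots of the fitted curve, sorted in x; evaluation
    elsewhere is linear interpolation clamped at the boundary knots.
    """
    idx = binned_subsample(x, sample_frac, n_bins, min_points, rng)
    fitted = lowess(y[idx], x[idx], frac=span, it=0, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x knots for strict interpolation support
    xs, keep = np.unique(xs, return_index=True)
    return xs, ys[keep]


def loess_normalize(
    track: np.ndarray,
    factor_mean: np.ndarray,
    span: float = 0.5,
    degree: int = 1,
    sample_frac: float = 0.01,
    n_bins: int = 25,
    seed: int = 0,
    min_points: int = 300,
) -> np.ndarray:
    """Remove a track's intensity-dependent bias against its factor mean.

    Regresses the residual ``track - factor_mean`` on ``factor_mean`` by a
    local-linear (degree 1) LOESS fit over a binned subsample, and subtracts
    the fitted trend so the corrected residual has mean ~0 at every level of
    the factor mean.  Evaluation outside the fit support uses the nearest
    boundary value (no extrapolation).
    """
    if degree != 1:
        raise NotImplementedError("only locally linear fits (degree=1) are supported")
    track = np.asarray(track, dtype=float)
    factor_mean = np.asarray(factor_mean, dtype=float)
    if track.shape != factor_mean.shape:
        raise ValueError("track and factor_mean must have equal length")
    resid = track - factor_mean
    if np.ptp(factor_mean) == 0:
        return track - resid.mean()
    rng = np.random.default_rng(seed)
    xs, ys = _loess_curve(factor_mean, resid, span, sample_frac, n_bins,
                          min_points, rng)
    trend = np.interp(factor_mean, xs, ys)
    return track - trend


class QuantileFactorNormalizer(TransformerMixin, BaseEstimator):
    """Per-factor quantile normalization of a track matrix.

    ``fit`` learns, for each factor, the reference distribution (mean of order
    statistics over that factor's tracks); ``transform`` maps every track of
    the factor onto its reference.  Follows the scikit-learn transformer
    protocol; X is the N x (C*P) track matrix in layout order.
    """

    def __init__(self, layout: TrackLayout | None = None):
        self.layout = layout

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        layout = self._layout(X)
        self.references_ = {}
        for k in range(layout.n_factors):
            cols = layout.factor_columns(k)
            self.references_[k] = _quantile_reference(X[:, cols])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        layout = self._layout(X)
        out = X.copy()
        for k in range(layout.n_factors):
            cols = layout.factor_columns(k)
            if len(cols) <= 1:
                continue
            ref = self.references_[k]
            if len(ref) != X.shape[0]:
                raise ValueError("transform requires same N as fit")
            for c in cols:
                col = X[:, c]
                order = np.argsort(col, kind="stable")
                mapped = np.empty(len(col))
                mapped[order] = ref
                s = pd.Series(mapped)
                out[:, c] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
        return out

    def _layout(self, X) -> TrackLayout:
        if self.layout is not None:
            return self.layout
        # single anonymous factor spanning all columns
        return TrackLayout(["c1"], ["f1"], X.shape[1])


class LoessSignalNormalizer(TransformerMixin, BaseEstimator):
    """Per-track LOESS normalization against the factor mean (fit_transform).

    The correction curve of each track is a function of the *current* factor
    mean, so this transformer is meaningful as ``fit_transform`` on the matrix
    it was fitted on.
    """

    def __init__(self, layout: TrackLayout | None = None, span: float = 0.5,
                 sample_frac: float = 0.01, n_bins: int = 25, seed: int = 0,
                 min_points: int = 300):
        self.layout = layout
        self.span = span
        self.sample_frac = sample_frac
        self.n_bins = n_bins
        self.seed = seed
        self.min_points = min_points

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        layout = self.layout
        if layout is None:
            raise ValueError("LoessSignalNormalizer requires a TrackLayout")
        fm = layout.factor_means(X)
        out = np.empty_like(X)
        for c in range(X.shape[1]):
            out[:, c] = loess_normalize(
                X[:, c], fm[:, c], span=self.span,
                sample_frac=self.sample_frac, n_bins=self.n_bins,
                seed=self.seed + c, min_points=self.min_points,
            )
        return out


@dataclass
class SignalMatrix:
    """N windows x (C*P) tracks of signal with genomic coordinates.

    ``stage`` records how far along the normalization chain the values are:
    raw -> log2 -> quantile -> loess.
    """

    windows: GenomeWindows
    values: np.ndarray
    layout: TrackLayout
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.windows), self.layout.n_tracks):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.windows)}, {self.layout.n_tracks})"
            )

    def to_frame(self) -> pd.DataFrame:
        df = self.windows.df[["chrom", "start", "end"]].copy()
        for name, col in zip(self.layout.track_names, self.values.T):
            df[name] = col
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def normalize_signal(
    signal: SignalMatrix,
    pseudocount: float = 0.1,
    span: float = 0.5,
    sample_frac: float = 0.01,
    n_bins: int = 25,
    seed: int = 0,
    min_points: int = 300,
) -> SignalMatrix:
    """Run the full chain raw -> log2 -> quantile -> loess on a SignalMatrix."""
    if signal.stage != "raw":
        raise ValueError(f"expected raw signal, got stage={signal.stage!r}")
    vals = log2_transform(signal.values, pseudocount)
    vals = QuantileFactorNormalizer(signal.layout).fit_transform(vals)
    vals = LoessSignalNormalizer(
        signal.layout, span=span, sample_frac=sample_frac, n_bins=n_bins,
        seed=seed, min_points=min_points,
    ).fit_transform(vals)
    if not np.all(np.isfinite(vals)):
        warnings.warn("non-finite values after normalization")
    return SignalMatrix(signal.windows, vals, signal.layout, stage="loess")
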