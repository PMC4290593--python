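"""Three-step likelihood-ratio testing cascade for multi-condition occupancy.

Per window i the signal of condition j is modelled as multivariate normal,
x_j(i) ~ N(u_j(i), Sigma_j(i)), with the replicate-equality constraint
u_j = A u_jA (A the P x K replicate design).  Three nested tests are run:

* Test 1 (occupancy): H0 pins every condition mean at the local background
  mean (per-factor median over the +-5 kb neighbourhood across all
  conditions); the statistic T1 = 2(L1 - L0) is asymptotically chi-square
  with C*K degrees of freedom.
* Test 2 (differential): H0 pins every condition at the precision-weighted
  pooled mean u_0; chi-square with (C-1)*K df; run only on Test-1 rejections.
* Test 3 (condition specificity): C leave-one-out repeats of Test 2, each
  with (C-2)*K df; a window is specific to condition j when dropping j — and
  only j — renders the remaining conditions consistent.

Because Sigma_j(i) factorises as diag(sigma) R_j diag(sigma) with a shared
correlation R_j, all quadratic forms are computed on sigma-standardized
residuals against a single R_j^{-1} per condition, which makes the
genome-wide pass a handful of einsums.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .covariance import CovarianceModel
from .layout import TrackLayout
from .normalize import SignalMatrix
from .windows import GenomeWindows

__all__ = [
    "background_mean",
    "mle_condition_mean",
    "mle_pooled_mean",
    "log_likelihood",
    "test1_binding",
    "test2_differential",
    "test3_condition_specific",
    "bonferroni_adjust",
    "bh_adjust",
    "compute_statistics",
    "run_cascade",
    "merge_contiguous_windows",
    "DCaP",
]

LABEL_NONE = "none"
LABEL_UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# single-window operations (reference semantics; the genome pass vectorises)

def mle_condition_mean(xj: np.ndarray, Sigma_j: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Constrained MLE of one condition's factor means: GLS under u = A u_A.

    u_A = (A' Sigma^{-1} A)^{-1} A' Sigma^{-1} x — the unique maximizer of the
    MVN likelihood with replicate means tied within each factor.
    """
    SiA = np.linalg.solve(Sigma_j, A)
    M = A.T @ SiA
    b = SiA.T @ xj
    return np.linalg.solve(M, b)


def mle_pooled_mean(xs, Sigmas, A: np.ndarray) -> np.ndarray:
    """Pooled factor means under H0 of equal condition means.

    u_0A = (sum_j A' Sigma_j^{-1} A)^{-1} sum_j A' Sigma_j^{-1} x_j — the
    precision-weighted combination across conditions.
    """
    M = np.zeros((A.shape[1], A.shape[1]))
    b = np.zeros(A.shape[1])
    for xj, Sj in zip(xs, Sigmas):
        SiA = np.linalg.solve(Sj, A)
        M += A.T @ SiA
        b += SiA.T @ xj
    return np.linalg.solve(M, b)


def log_likelihood(xj: np.ndarray, mu: np.ndarray, Sigma_j: np.ndarray) -> float:
    """Multivariate-normal log-density of one condition's signal vector."""
    xj = np.asarray(xj, dtype=float)
    p = len(xj)
    sign, logdet = np.linalg.slogdet(Sigma_j)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    r = xj - mu
    quad = r @ np.linalg.solve(Sigma_j, r)
    return -0.5 * (p * np.log(2 * np.pi) + logdet + quad)


def _loglik_sum(X_i, means, Sigmas):
    return sum(log_likelihood(x, m, S) for x, m, S in zip(X_i, means, Sigmas))


def test1_binding(X_i, u_bck, Sigmas, A, enriched_only: bool = False):
    """Occupancy test for one window.

    X_i is (C, P); u_bck length P (identical across conditions).  Returns
    (T1, p) with p from chi-square on C*K df.  Under ``enriched_only``
    negative residuals x_j - u are zeroed inside both quadratic forms, so a
    window depleted relative to its background contributes no evidence and
    only enrichment over background scores.
    """
    X_i = np.asarray(X_i, dtype=float)
    C, P = X_i.shape
    K = A.shape[1]

    def half_loglik(x, u, S):
        r = x - u
        if enriched_only:
            r = np.maximum(r, 0.0)
        p_dim = len(x)
        sign, logdet = np.linalg.slogdet(S)
        return -0.5 * (p_dim * np.log(2 * np.pi) + logdet
                       + r @ np.linalg.solve(S, r))

    L0 = sum(half_loglik(x, u_bck, S) for x, S in zip(X_i, Sigmas))
    L1 = sum(
        half_loglik(x, A @ mle_condition_mean(x, S, A), S)
        for x, S in zip(X_i, Sigmas)
    )
    T = max(2.0 * (L1 - L0), 0.0)
    return T, stats.chi2.sf(T, C * K)


def test2_differential(X_i, Sigmas, A):
    """Differential-vs-common test for one window: (T2, p), df (C-1)*K."""
    X_i = np.asarray(X_i, dtype=float)
    C, P = X_i.shape
    K = A.shape[1]
    u0 = A @ mle_pooled_mean(list(X_i), Sigmas, A)
    L0 = _loglik_sum(X_i, [u0] * C, Sigmas)
    L1 = _loglik_sum(
        X_i, [A @ mle_condition_mean(x, S, A) for x, S in zip(X_i, Sigmas)], Sigmas
    )
    T = max(2.0 * (L1 - L0), 0.0)
    return T, stats.chi2.sf(T, (C - 1) * K)


def test3_condition_specific(X_i, Sigmas, A, alpha: float = 0.05,
                             m: int | None = None):
    """Leave-one-out specificity for one window.

    Computes the C statistics T_{-j} (Test 2 on the remaining C-1 conditions,
    (C-2)*K df), Bonferroni-adjusts with family size ``m`` (default C) and
    labels the window: the left-out condition whose removal — and only whose
    removal — makes the rest consistent; 'none' if every T_{-j} stays
    significant; 'unclassified' if two or more become insignificant.
    """
    X_i = np.asarray(X_i, dtype=float)
    C = X_i.shape[0]
    if C < 3:
        raise ValueError("Test 3 requires at least 3 conditions")
    m = C if m is None else m
    T_minus = np.empty(C)
    p_adj = np.empty(C)
    for j in range(C):
        keep = [l for l in range(C) if l != j]
        T, p = test2_differential(X_i[keep], [Sigmas[l] for l in keep], A)
        # df of the reduced test is (C-2)K — test2 on C-1 conditions
        T_minus[j] = T
        p_adj[j] = min(1.0, p * m)
    insignificant = np.flatnonzero(p_adj > alpha)
    if len(insignificant) == 1:
        label = int(insignificant[0])
    elif len(insignificant) == 0:
        label = LABEL_NONE
    else:
        label = LABEL_UNCLASSIFIED
    return T_minus, p_adj, label


def bonferroni_adjust(p: np.ndarray, m: int) -> np.ndarray:
    """min(1, p*m) elementwise."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (secondary correction option)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# genome-wide vectorised pass

def background_mean(signal: SignalMatrix, halfspan: int = 5000) -> np.ndarray:
    """Local background means: per-factor medians over +-halfspan bp.

    For each factor the median is taken over all conditions, replicates and
    windows within the neighbourhood (window i inclusive), restricted to the
    same chromosome; truncated at chromosome ends.  Returned as an
    N x (C*P) matrix with identical factor entries across conditions.
    """
    values, layout, windows = signal.values, signal.layout, signal.windows
    h = max(int(round(halfspan / max(windows.width, 1))), 0)
    win = 2 * h + 1
    out = np.empty_like(values)
    segments = windows.chromosome_segments()
    for k in range(layout.n_factors):
        cols = layout.factor_columns(k)
        mat = values[:, cols]
        med = np.empty(len(mat))
        for rows in segments:
            seg = mat[rows]
            n = len(seg)
            if win == 1 or n == 1:
                med[rows] = np.median(seg, axis=1)
                continue
            if n >= win:
                # gather each neighbourhood offset by contiguous slices:
                # (n-2h, win, tracks) -> median over neighbourhood x tracks
                m = n - win + 1
                sw = np.empty((m, win, seg.shape[1]))
                for o in range(win):
                    sw[:, o, :] = seg[o:o + m]
                med[rows[h:n - h]] = np.median(sw.reshape(m, -1), axis=1,
                                               overwrite_input=True)
            # truncated neighbourhoods at the segment edges
            for i in list(range(min(h, n))) + list(range(max(n - h, 0), n)):
                med[rows[i]] = np.median(seg[max(i - h, 0):i + h + 1])
        out[:, cols] = med[:, None]
    return out


def compute_statistics(
    values: np.ndarray,
    sigma: np.ndarray,
    layout: TrackLayout,
    correlations: list[np.ndarray],
    u_bck: np.ndarray | None = None,
    enriched_only: bool = False,
) -> dict:
    """All per-window LRT statistics in one vectorised pass.

    Returns a dict with T1 (N,), T1_single (N, C), T2 (N,), T_minus (N, C),
    condition means u (N, C, P) and pooled means u0 (N, P).  T1 entries are
    NaN when ``u_bck`` is None (peaks-only mode).
    """
    layout_P = layout.tracks_per_condition
    N = values.shape[0]
    C, K = layout.n_conditions, layout.n_factors
    A = layout.design_matrix
    X = values.reshape(N, C, layout_P)
    S = sigma.reshape(N, C, layout_P)
    Rinv = [np.linalg.inv(c) for c in correlations]

    M = np.empty((N, C, K, K))
    b = np.empty((N, C, K))
    Q1 = np.empty((N, C))
    Q1e = np.empty((N, C)) if enriched_only else None
    U = np.empty((N, C, layout_P))
    for j in range(C):
        Bn = A[None, :, :] / S[:, j, :, None]          # D^{-1} A per window
        M[:, j] = np.einsum("npk,pq,nql->nkl", Bn, Rinv[j], Bn, optimize=True)
        xs = X[:, j] / S[:, j]
        b[:, j] = np.einsum("npk,pq,nq->nk", Bn, Rinv[j], xs, optimize=True)
        uA = np.linalg.solve(M[:, j], b[:, j][..., None])[..., 0]
        U[:, j] = uA @ A.T
        r = (X[:, j] - U[:, j]) / S[:, j]
        Q1[:, j] = np.einsum("np,pq,nq->n", r, Rinv[j], r, optimize=True)
        if enriched_only:
            re = np.maximum(X[:, j] - U[:, j], 0.0) / S[:, j]
            Q1e[:, j] = np.einsum("np,pq,nq->n", re, Rinv[j], re, optimize=True)

    def quad_at(mean, j):
        r = (X[:, j] - mean) / S[:, j]
        return np.einsum("np,pq,nq->n", r, Rinv[j], r, optimize=True)

    out = {"u": U}

    def quad_enriched(mean, j):
        r = np.maximum(X[:, j] - mean, 0.0) / S[:, j]
        return np.einsum("np,pq,nq->n", r, Rinv[j], r, optimize=True)

    if u_bck is not None:
        Ub = u_bck.reshape(N, C, layout_P)
        q0f = quad_enriched if enriched_only else quad_at
        Q0 = np.stack([q0f(Ub[:, j], j) for j in range(C)], axis=1)
        Q1_t1 = Q1e if enriched_only else Q1
        out["T1_single"] = np.maximum(Q0 - Q1_t1, 0.0)
        out["T1"] = np.maximum((Q0 - Q1_t1).sum(axis=1), 0.0)
    else:
        out["T1"] = np.full(N, np.nan)
        out["T1_single"] = np.full((N, C), np.nan)

    # pooled mean under H0 of Test 2 (precision-weighted across conditions)
    M_sum = M.sum(axis=1)
    b_sum = b.sum(axis=1)
    u0A = np.linalg.solve(M_sum, b_sum[..., None])[..., 0]
    u0 = u0A @ A.T
    out["u0"] = u0
    Q00 = np.stack([quad_at(u0, j) for j in range(C)], axis=1)
    out["T2"] = np.maximum((Q00 - Q1).sum(axis=1), 0.0)

    # leave-one-out pooled means and statistics
    T_minus = np.full((N, C), np.nan)
    if C >= 3:
        for j in range(C):
            Mj = M_sum - M[:, j]
            bj = b_sum - b[:, j]
            u0j = np.linalg.solve(Mj, bj[..., None])[..., 0] @ A.T
            acc = np.zeros(N)
            for l in range(C):
                if l == j:
                    continue
                acc += quad_at(u0j, l) - Q1[:, l]
            T_minus[:, j] = np.maximum(acc, 0.0)
    out["T_minus"] = T_minus
    return out


def run_cascade(
    signal: SignalMatrix,
    model: CovarianceModel | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    enriched_only: bool = False,
    peaks_mode: bool = False,
    halfspan: int = 5000,
    test3_family: str = "genome",
    statistics: dict | None = None,
) -> pd.DataFrame:
    """Run the full Test 1 -> 2 -> 3 cascade over a signal matrix.

    Multiplicity families: Test 1 over all N windows (Bonferroni m = N);
    Test 2 over Test-1 rejections (m = their count, or BH when
    ``correction='bh'``); Test 3 over Test-2 rejections with m = C x count
    (``test3_family='genome'``) or m = C per window (``'window'``).  In
    ``peaks_mode`` Test 1 is skipped and every region enters Test 2.
    """
    layout = signal.layout
    values = signal.values
    N = len(values)
    C, K = layout.n_conditions, layout.n_factors
    if statistics is not None:
        st = statistics
    else:
        if model is None:
            model = CovarianceModel(layout, mode="peaks" if peaks_mode else "background")
            model.fit(values)
        sigma = model.sigma(values)
        u_bck = None if peaks_mode else background_mean(signal, halfspan)
        st = compute_statistics(values, sigma, layout, model.correlations_,
                                u_bck, enriched_only)

    res = signal.windows.df[["chrom", "start", "end"]].copy()
    res["T1"] = st["T1"]
    if peaks_mode:
        res["p1"] = np.nan
        res["p1_adj"] = np.nan
        bound = np.ones(N, dtype=bool)
    else:
        p1 = stats.chi2.sf(st["T1"], C * K)
        res["p1"] = p1
        res["p1_adj"] = bonferroni_adjust(p1, N)
        bound = res["p1_adj"].to_numpy() <= alpha
    res["bound"] = bound

    res["T2"] = np.where(bound, st["T2"], np.nan) if C >= 2 else np.nan
    p2 = np.full(N, np.nan)
    p2_adj = np.full(N, np.nan)
    if C >= 2 and bound.any():
        p2_raw = stats.chi2.sf(st["T2"][bound], (C - 1) * K)
        p2[bound] = p2_raw
        if correction == "bh":
            p2_adj[bound] = bh_adjust(p2_raw)
        else:
            p2_adj[bound] = bonferroni_adjust(p2_raw, int(bound.sum()))
    res["p2"] = p2
    res["p2_adj"] = p2_adj
    differential = bound & (p2_adj <= alpha)
    res["differential"] = differential

    labels = np.full(N, "", dtype=object)
    labels[differential] = LABEL_NONE
    n_diff = int(differential.sum())
    for j, cond in enumerate(layout.conditions):
        res[f"T_minus_{cond}"] = np.where(differential, st["T_minus"][:, j], np.nan)
    if n_diff and C >= 3:
        m3 = C * n_diff if test3_family == "genome" else C
        p3 = stats.chi2.sf(st["T_minus"][differential], (C - 2) * K)
        p3_adj = bonferroni_adjust(p3, m3)
        insig = p3_adj > alpha
        count = insig.sum(axis=1)
        sub = np.full(n_diff, LABEL_UNCLASSIFIED, dtype=object)
        sub[count == 0] = LABEL_NONE
        one = count == 1
        if one.any():
            which = insig[one].argmax(axis=1)
            sub[one] = np.asarray(layout.conditions)[which]
        labels[differential] = sub
    elif n_diff and C == 2:
        warnings.warn(
            "Test 3 is undefined with 2 conditions: differential windows are "
            "trivially condition-specific"
        )
        labels[differential] = "condition-specific"
    res["label"] = labels
    return res


def merge_contiguous_windows(flagged: pd.DataFrame, label_col: str | None = "label") -> pd.DataFrame:
    """Merge adjacent flagged windows into maximal intervals.

    Windows merge when on the same chromosome, exactly abutting
    (end == next start) and — when ``label_col`` is given — sharing a label.
    """
    if len(flagged) == 0:
        cols = ["chrom", "start", "end"] + ([label_col] if label_col else [])
        return pd.DataFrame(columns=cols)
    df = flagged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    rows = []
    cur = None
    for rec in df.itertuples(index=False):
        lab = getattr(rec, label_col) if label_col else None
        if (cur is not None and rec.chrom == cur["chrom"]
                and rec.start == cur["end"] and lab == cur["label"]):
            cur["end"] = rec.end
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": rec.chrom, "start": rec.start, "end": rec.end,
                   "label": lab}
    rows.append(cur)
    out = pd.DataFrame(rows)
    if label_col is None:
        out = out.drop(columns=["label"])
    else:
        out = out.rename(columns={"label": label_col})
    return out


class DCaP(BaseEstimator):
    """Estimator interface to the full testing cascade.

    ``fit(X)`` accepts a :class:`SignalMatrix` (or a bare N x (C*P) array with
    a ``layout``, treated as consecutive 1-kb tiles on one chromosome),
    estimates the covariance model unless one is supplied, and runs the
    cascade.  Fitted attributes: ``results_`` (per-window table),
    ``statistics_`` (raw statistic arrays), ``model_`` (covariance model).
    """

    def __init__(self, layout: TrackLayout | None = None,
                 covariance_model: CovarianceModel | None = None,
                 alpha: float = 0.05, correction: str = "bonferroni",
                 enriched_only: bool = False, peaks_mode: bool = False,
                 halfspan: int = 5000, test3_family: str = "genome",
                 span: float = 0.5, sample_frac: float = 0.01,
                 n_bins: int = 25, min_points: int = 300, seed: int = 0):
        self.layout = layout
        self.covariance_model = covariance_model
        self.alpha = alpha
        self.correction = correction
        self.enriched_only = enriched_only
        self.peaks_mode = peaks_mode
        self.halfspan = halfspan
        self.test3_family = test3_family
        self.span = span
        self.sample_frac = sample_frac
        self.n_bins = n_bins
        self.min_points = min_points
        self.seed = seed

    def _as_signal(self, X) -> SignalMatrix:
        if isinstance(X, SignalMatrix):
            return X
        X = np.asarray(X, dtype=float)
        if self.layout is None:
            raise ValueError("array input requires a TrackLayout")
        width = 1000
        df = pd.DataFrame({
            "chrom": np.repeat("sim", len(X)),
            "start": np.arange(len(X)) * width,
            "end": (np.arange(len(X)) + 1) * width,
        })
        return SignalMatrix(GenomeWindows(df, width), X, self.layout, stage="loess")

    def fit(self, X, y=None):
        signal = self._as_signal(X)
        model = self.covariance_model
        if model is None:
            model = CovarianceModel(
                signal.layout, mode="peaks" if self.peaks_mode else "background",
                span=self.span, sample_frac=self.sample_frac,
                n_bins=self.n_bins, min_points=self.min_points, seed=self.seed,
            ).fit(signal.values)
        self.model_ = model
        sigma = model.sigma(signal.values)
        u_bck = None if self.peaks_mode else background_mean(signal, self.halfspan)
        self.statistics_ = compute_statistics(
            signal.values, sigma, signal.layout, model.correlations_,
            u_bck, self.enriched_only,
        )
        self.results_ = run_cascade(
            signal, model, alpha=self.alpha, correction=self.correction,
            enriched_only=self.enriched_only, peaks_mode=self.peaks_mode,
            halfspan=self.halfspan, test3_family=self.test3_family,
            statistics=self.statistics_,
        )
        return self

    def decision_function(self, X=None) -> np.ndarray:
        """Per-window occupancy score (the Test-1 statistic) from the fit."""
        return self.statistics_["T1"]

    def predict(self, X=None) -> np.ndarray:
        """Per-window occupancy calls from the fitted cascade."""
        return self.results_["bound"].to_numpy()
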