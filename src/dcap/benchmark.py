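"""Benchmarking: ROC / precision-recall scoring and ANOVA / MANOVA baselines.

``run_benchmark`` reproduces the simulation comparison: the joint occupancy
test against its per-condition-merged variant on the any-binding task, and
the differential test against one-way MANOVA (plus per-factor ANOVA) on the
differential task, at the three binding strengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve

from .covariance import CovarianceModel
from .layout import TrackLayout
from .lrt import DCaP
from .simulate import BINDING_REGIMES, SimulationSpec, simulate_mvn_dataset

__all__ = ["roc_prc", "CurveResult", "baseline_anova", "baseline_manova",
           "anova_stats", "manova_stats", "t1_single_scores", "run_benchmark"]


@dataclass
class CurveResult:
    """ROC and precision-recall curves with trapezoidal areas (in [0, 1])."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    recall: np.ndarray
    precision: np.ndarray
    auprc: float

    def curves_frame(self) -> pd.DataFrame:
        roc = pd.DataFrame({"curve": "roc", "x": self.fpr, "y": self.tpr})
        prc = pd.DataFrame({"curve": "prc", "x": self.recall, "y": self.precision})
        return pd.concat([roc, prc], ignore_index=True)


def roc_prc(scores: np.ndarray, labels: np.ndarray) -> CurveResult:
    """Threshold-sweep ROC and precision-recall evaluation of a ranking.

    Ties are grouped at a single threshold; the precision-recall area is the
    trapezoidal integral over the full ranking.  Raises on single-class
    labels, for which both curves are undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("labels must contain both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    auroc = float(np.trapezoid(tpr, fpr))
    prec, rec, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve returns recall descending; integrate over recall
    auprc = float(-np.trapezoid(prec, rec))
    return CurveResult(fpr, tpr, auroc, rec, prec, auprc)


# ---------------------------------------------------------------------------
# classical baselines

def anova_stats(X: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way fixed-effects ANOVA over windows.

    ``X`` is (N, n_groups * r) with group-major columns; returns (F, p).
    Zero within-group variance with unequal means yields F = inf, p = 0.
    """
    X = np.asarray(X, dtype=float)
    N, total = X.shape
    r = total // n_groups
    if n_groups < 2 or r < 2:
        raise ValueError("ANOVA needs >= 2 groups and >= 2 observations each")
    G = X.reshape(N, n_groups, r)
    gmean = G.mean(axis=2)
    grand = X.mean(axis=1)
    ssb = r * ((gmean - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((G - gmean[:, :, None]) ** 2).sum(axis=(1, 2))
    df1, df2 = n_groups - 1, n_groups * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(F, df1, df2))
    return F, p


def baseline_anova(x: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA p-value for a single window (group-major vector)."""
    _, p = anova_stats(np.asarray(x, dtype=float)[None, :], n_groups)
    return float(p[0])


def manova_stats(values: np.ndarray, layout: TrackLayout,
                 ridge: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way MANOVA (Wilks' lambda) over windows.

    Observations are the R replicate K-vectors per condition (n = C*R per
    window); Wilks' lambda is referred to an F distribution via Rao's
    approximation, which is exact for K = 1 (reducing to one-way ANOVA) and
    for C = 2.  A small ridge is added to singular within-group scatter
    matrices.  Returns (F, p).
    """
    values = np.asarray(values, dtype=float)
    N = values.shape[0]
    C, K, R = layout.n_conditions, layout.n_factors, layout.n_replicates
    if C * (R - 1) < K:
        raise ValueError("within-group scatter is rank deficient: need C*(R-1) >= K")
    # reorder to (N, C, R, K): observation r in condition j is a K-vector
    obs = np.empty((N, C, R, K))
    for j in range(C):
        for k in range(K):
            obs[:, j, :, k] = values[:, layout.replicate_columns(j, k)]
    n = C * R
    gmean = obs.mean(axis=2)                       # (N, C, K)
    grand = obs.reshape(N, n, K).mean(axis=1)      # (N, K)
    d_w = obs - gmean[:, :, None, :]
    W = np.einsum("njrk,njrl->nkl", d_w, d_w, optimize=True)
    d_b = gmean - grand[:, None, :]
    B = R * np.einsum("njk,njl->nkl", d_b, d_b, optimize=True)
    detW = np.linalg.det(W)
    bad = ~(detW > 0)
    if bad.any():
        W[bad] += ridge * np.eye(K)
        detW = np.linalg.det(W)
    lam = detW / np.linalg.det(W + B)
    lam = np.clip(lam, np.finfo(float).tiny, 1.0)
    # Rao's F approximation for Wilks' lambda
    p_dim, q = K, C - 1                       # response dim, hypothesis df
    v = n - C                                  # error df
    if p_dim ** 2 + q ** 2 - 5 > 0:
        t = np.sqrt((p_dim ** 2 * q ** 2 - 4.0) / (p_dim ** 2 + q ** 2 - 5.0))
    else:
        t = 1.0
    w = v + q - (p_dim + q + 1) / 2.0
    df1 = p_dim * q
    df2 = w * t - (p_dim * q) / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    with np.errstate(divide="ignore"):
        F = (1.0 - lam_t) / lam_t * (df2 / df1)
    p = stats.f.sf(F, df1, df2)
    return F, p


def baseline_manova(values_row: np.ndarray, layout: TrackLayout) -> float:
    """One-way MANOVA p-value for a single window."""
    _, p = manova_stats(np.asarray(values_row, dtype=float)[None, :], layout)
    return float(p[0])


# ---------------------------------------------------------------------------
# benchmark driver

def t1_single_scores(values: np.ndarray, layout: TrackLayout,
                     **dcap_kwargs) -> np.ndarray:
    """Occupancy scores from separate single-condition analyses, max-merged.

    Runs the full occupancy test once per condition (C = 1: each condition's
    own background medians and correlation estimate, which cannot use the
    cross-condition decomposition), then merges per window by the maximum
    statistic — the natural union-of-single-condition-calls ranking.
    """
    values = np.asarray(values, dtype=float)
    scores = np.empty((values.shape[0], layout.n_conditions))
    for j, cond in enumerate(layout.conditions):
        sub = TrackLayout([cond], layout.factors, layout.n_replicates)
        block = values[:, layout.condition_slice(j)]
        with np.errstate(all="ignore"):
            est = DCaP(layout=sub, **dcap_kwargs).fit(block)
        scores[:, j] = est.statistics_["T1"]
    return scores.max(axis=1)


def run_benchmark(
    strengths=("strong", "medium", "weak"),
    methods=("t1all", "t1single", "t2all", "anova", "manova"),
    seed: int = 0,
    n_seeds: int = 1,
    spec: SimulationSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate datasets, run the methods, and score ROC / PRC areas.

    Occupancy methods (t1all, t1single) are scored against the any-binding
    truth; differential methods (t2all, manova, anova) against the
    differential truth.  ``anova`` uses the first factor's tracks.  Returns a
    tidy table of areas (one row per strength x method x seed) and a dict of
    the full curves for the last seed per (strength, method).
    """
    base = spec or SimulationSpec()
    rows, curves = [], {}
    for strength in strengths:
        mean, var = BINDING_REGIMES[strength]
        for s in range(n_seeds):
            sp = SimulationSpec(**{**base.__dict__, "binding_mean": mean,
                                   "binding_var": var, "seed": seed + s})
            values, layout, truth = simulate_mvn_dataset(sp)
            est = DCaP(layout=layout).fit(values)
            st = est.statistics_
            y_bind = truth["is_binding"].to_numpy()
            y_diff = truth["is_differential"].to_numpy()
            for method in methods:
                if method == "t1all":
                    scores, y = st["T1"], y_bind
                elif method == "t1single":
                    scores, y = t1_single_scores(values, layout), y_bind
                elif method == "t2all":
                    scores, y = st["T2"], y_diff
                elif method == "manova":
                    scores, y = manova_stats(values, layout)[0], y_diff
                elif method == "anova":
                    cols = layout.factor_columns(0)
                    scores, y = anova_stats(values[:, cols], layout.n_conditions)[0], y_diff
                else:
                    raise ValueError(f"unknown method {method!r}")
                cr = roc_prc(scores, y)
                rows.append({"strength": strength, "method": method,
                             "seed": sp.seed, "auroc": cr.auroc,
                             "auprc": cr.auprc})
                curves[(strength, method)] = cr
    return pd.DataFrame(rows), curves
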