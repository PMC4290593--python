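"""Independent reference implementations used as test oracles.

These deliberately avoid the package's closed-form code paths: constrained
means come from a generic numerical optimizer over the factor-mean
parameters, log-densities from scipy's multivariate_normal, and ROC /
precision-recall areas from exhaustive threshold enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal


def numeric_condition_mean(x, Sigma, A):
    """Maximize the MVN likelihood over constrained means numerically."""
    K = A.shape[1]

    def negloglik(theta):
        return -multivariate_normal.logpdf(x, mean=A @ theta, cov=Sigma)

    start = np.array([x[A[:, k] == 1].mean() for k in range(K)])
    res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000})
    return res.x


def numeric_pooled_mean(xs, Sigmas, A):
    """Numerically maximize the joint likelihood under equal condition means."""
    K = A.shape[1]

    def negloglik(theta):
        mu = A @ theta
        return -sum(multivariate_normal.logpdf(x, mean=mu, cov=S)
                    for x, S in zip(xs, Sigmas))

    start = np.mean([[x[A[:, k] == 1].mean() for k in range(K)] for x in xs],
                    axis=0)
    res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000})
    return res.x


def numeric_T1(X_i, u_bck, Sigmas, A):
    """Occupancy LRT statistic via numeric MLEs and scipy log-densities."""
    L0 = sum(multivariate_normal.logpdf(x, mean=u_bck, cov=S)
             for x, S in zip(X_i, Sigmas))
    L1 = sum(
        multivariate_normal.logpdf(x, mean=A @ numeric_condition_mean(x, S, A), cov=S)
        for x, S in zip(X_i, Sigmas)
    )
    return 2.0 * (L1 - L0)


def numeric_T2(X_i, Sigmas, A):
    """Differential LRT statistic via numeric MLEs and scipy log-densities."""
    u0 = A @ numeric_pooled_mean(list(X_i), Sigmas, A)
    L0 = sum(multivariate_normal.logpdf(x, mean=u0, cov=S)
             for x, S in zip(X_i, Sigmas))
    L1 = sum(
        multivariate_normal.logpdf(x, mean=A @ numeric_condition_mean(x, S, A), cov=S)
        for x, S in zip(X_i, Sigmas)
    )
    return 2.0 * (L1 - L0)


def enumerate_roc_prc(scores, labels):
    """ROC / PR areas by exhaustive threshold enumeration (small inputs).

    Sweeps every distinct score as a 'predict positive if score >= t'
    threshold (ties grouped), building the ROC and PR point sets explicitly,
    then integrates both by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = labels.sum(), (1 - labels).sum()
    thresholds = np.unique(scores)[::-1]
    tprs, fprs, precs, recs = [0.0], [0.0], [], []
    for t in thresholds:
        called = scores >= t
        tp = int((called & (labels == 1)).sum())
        fp = int((called & (labels == 0)).sum())
        tprs.append(tp / pos)
        fprs.append(fp / neg)
        precs.append(tp / (tp + fp))
        recs.append(tp / pos)
    tprs.append(1.0)
    fprs.append(1.0)
    auroc = np.trapezoid(tprs, fprs)
    # anchor the PR curve at recall 0 with the first precision value
    recs = [0.0] + recs
    precs = [precs[0]] + precs
    auprc = np.trapezoid(precs, recs)
    return float(auroc), float(auprc)


def random_layout_instance(rng, C=None, K=None, R=None):
    """A random small (layout, per-condition data, covariances) instance."""
    from dcap import TrackLayout

    C = C or int(rng.integers(2, 6))
    K = K or int(rng.integers(1, 4))
    R = R or int(rng.integers(1, 4))
    layout = TrackLayout([f"c{j}" for j in range(C)],
                         [f"f{k}" for k in range(K)], R)
    P = K * R
    X = rng.normal(0, 2, size=(C, P))
    Sigmas = []
    for _ in range(C):
        G = rng.normal(size=(P, P + 2))
        S = G @ G.T / (P + 2) + 0.5 * np.eye(P)
        Sigmas.append(S)
    return layout, X, Sigmas
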