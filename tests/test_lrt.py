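import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from dcap import (DCaP, SignalMatrix, TrackLayout, background_mean,
                  bonferroni_adjust, log_likelihood, merge_contiguous_windows,
                  mle_condition_mean, mle_pooled_mean, run_cascade)
from dcap.lrt import test1_binding as lrt_test1
from dcap.lrt import test2_differential as lrt_test2
from dcap.lrt import test3_condition_specific as lrt_test3
from dcap.covariance import CovarianceModel, assemble_covariance
from dcap.lrt import compute_statistics
from dcap.windows import GenomeWindows

from _oracles import (numeric_condition_mean, numeric_pooled_mean,
                      random_layout_instance)


def make_signal(values, layout, width=1000, chrom="c1"):
    n = len(values)
    df = pd.DataFrame({"chrom": [chrom] * n, "start": np.arange(n) * width})
    df["end"] = df["start"] + width
    return SignalMatrix(GenomeWindows(df, width), values, layout, stage="loess")


class TestMeanEstimates:
    def test_identity_covariance_reduces_to_replicate_means(self, rng):
        layout = TrackLayout(["a"], ["f1", "f2"], 2)
        A = layout.design_matrix
        x = rng.normal(size=4)
        uA = mle_condition_mean(x, np.eye(4), A)
        assert np.allclose(uA, [x[:2].mean(), x[2:].mean()])

    def test_exchangeable_covariance_still_averages(self, rng):
        A = TrackLayout(["a"], ["f"], 2).design_matrix
        x = rng.normal(size=2)
        for rho in (-0.5, 0.0, 0.6, 0.9):
            S = np.array([[1.0, rho], [rho, 1.0]])
            assert mle_condition_mean(x, S, A)[0] == pytest.approx(x.mean())

    def test_matches_numeric_optimizer(self, rng):
        for _ in range(5):
            layout, X, Sigmas = random_layout_instance(rng)
            A = layout.design_matrix
            uA = mle_condition_mean(X[0], Sigmas[0], A)
            assert np.allclose(uA, numeric_condition_mean(X[0], Sigmas[0], A),
                               atol=1e-6)

    def test_pooled_identity_grand_mean(self, rng):
        layout = TrackLayout(["a", "b"], ["f"], 2)
        A = layout.design_matrix
        xs = [rng.normal(size=2), rng.normal(size=2)]
        u0 = mle_pooled_mean(xs, [np.eye(2)] * 2, A)
        assert u0[0] == pytest.approx(np.concatenate(xs).mean())

    def test_pooled_precision_weighting(self, rng):
        layout = TrackLayout(["a", "b"], ["f"], 2)
        A = layout.design_matrix
        x1, x2 = rng.normal(size=2), rng.normal(size=2)
        u0 = mle_pooled_mean([x1, x2], [np.eye(2), 4 * np.eye(2)], A)
        assert u0[0] == pytest.approx((4 * x1.mean() + x2.mean()) / 5)

    def test_pooled_matches_numeric_optimizer(self, rng):
        for _ in range(5):
            layout, X, Sigmas = random_layout_instance(rng)
            A = layout.design_matrix
            u0 = mle_pooled_mean(list(X), Sigmas, A)
            assert np.allclose(u0, numeric_pooled_mean(list(X), Sigmas, A),
                               atol=1e-6)


class TestLogLikelihood:
    def test_closed_forms(self):
        assert log_likelihood(np.zeros(2), np.zeros(2), np.eye(2)) == \
            pytest.approx(-np.log(2 * np.pi))
        assert log_likelihood(np.array([2.0]), np.array([0.0]), np.eye(1)) == \
            pytest.approx(-0.5 * np.log(2 * np.pi) - 2.0)

    def test_matches_scipy_density(self, rng):
        for _ in range(10):
            layout, X, Sigmas = random_layout_instance(rng)
            mu = rng.normal(size=X.shape[1])
            ours = log_likelihood(X[0], mu, Sigmas[0])
            ref = multivariate_normal.logpdf(X[0], mean=mu, cov=Sigmas[0])
            assert ours == pytest.approx(ref, abs=1e-10)


class TestSingleWindowTests:
    def test_t1_zero_when_data_equal_background(self):
        layout = TrackLayout(["a", "b"], ["f"], 2)
        A = layout.design_matrix
        u = np.array([1.0, 1.0])
        T, p = lrt_test1(np.array([u, u]), u, [np.eye(2)] * 2, A)
        assert T == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_t1_degrees_of_freedom(self, rng):
        """C=5, K=3 must be referred to a chi-square with 15 df."""
        layout, X, Sigmas = random_layout_instance(rng, C=5, K=3, R=2)
        A = layout.design_matrix
        u_bck = np.zeros(X.shape[1])
        T, p = lrt_test1(X, u_bck, Sigmas, A)
        assert p == pytest.approx(stats.chi2.sf(T, 15))

    def test_t2_zero_for_identical_conditions(self, rng):
        layout = TrackLayout(["a", "b"], ["f"], 2)
        A = layout.design_matrix
        x = rng.normal(size=2)
        T, p = lrt_test2(np.array([x, x]), [np.eye(2)] * 2, A)
        assert T == pytest.approx(0.0, abs=1e-10)

    def test_t2_degrees_of_freedom(self, rng):
        layout, X, Sigmas = random_layout_instance(rng, C=5, K=3, R=2)
        A = layout.design_matrix
        T, p = lrt_test2(X, Sigmas, A)
        assert p == pytest.approx(stats.chi2.sf(T, 12))   # (C-1)K

    def test_enriched_only_ignores_depletion(self):
        """A depleted window scores 0 in enriched-only mode, > 0 otherwise."""
        layout = TrackLayout(["a", "b"], ["f"], 2)
        A = layout.design_matrix
        X = np.array([[-4.0, -4.0], [-4.0, -4.0]])
        u_bck = np.zeros(2)
        T_bi, _ = lrt_test1(X, u_bck, [np.eye(2)] * 2, A)
        T_en, _ = lrt_test1(X, u_bck, [np.eye(2)] * 2, A, enriched_only=True)
        assert T_bi > 10
        assert T_en == pytest.approx(0.0, abs=1e-9)

    def test_t2_monotone_in_planted_shift(self, rng):
        """Growing one condition's shift never decreases T2 (fixed Sigma)."""
        layout, X, Sigmas = random_layout_instance(rng, C=3, K=2, R=2)
        A = layout.design_matrix
        base = np.zeros_like(X)
        prev = -np.inf
        for shift in np.linspace(0, 6, 13):
            Xs = base.copy()
            Xs[0] += shift
            T, _ = lrt_test2(Xs, Sigmas, A)
            assert T >= prev - 1e-9
            prev = T


class TestTest3:
    def _toy(self, shift_conditions, C=3, shift=5.0):
        layout = TrackLayout([f"c{j}" for j in range(C)], ["f"], 2)
        A = layout.design_matrix
        X = np.zeros((C, 2))
        for j in shift_conditions:
            X[j] += shift
        Sigmas = [np.eye(2)] * C
        return X, Sigmas, A

    def test_single_shifted_condition_labelled(self):
        X, Sigmas, A = self._toy([0])
        T_minus, p_adj, label = lrt_test3(X, Sigmas, A)
        assert label == 0
        # removing the shifted condition gives the smallest statistic
        assert T_minus[0] == pytest.approx(min(T_minus))

    def test_two_identically_shifted_gives_odd_one_out(self):
        """With exactly two conditions shifted together, only removing the
        unshifted condition leaves a consistent pair."""
        X, Sigmas, A = self._toy([0, 1], C=3)
        _, _, label = lrt_test3(X, Sigmas, A)
        assert label == 2

    def test_borderline_shift_unclassified(self):
        """A moderate shift leaves several leave-one-out tests insignificant
        after adjustment: the window cannot be attributed to one condition."""
        X, Sigmas, A = self._toy([0], C=3, shift=2.0)
        _, p_adj, label = lrt_test3(X, Sigmas, A)
        assert (p_adj > 0.05).sum() >= 2
        assert label == "unclassified"

    def test_all_distinct_gives_none(self):
        layout = TrackLayout(["a", "b", "c"], ["f"], 2)
        A = layout.design_matrix
        X = np.array([[0.0, 0.0], [8.0, 8.0], [16.0, 16.0]])
        _, _, label = lrt_test3(X, [np.eye(2)] * 3, A)
        assert label == "none"

    def test_requires_three_conditions(self):
        X, Sigmas, A = self._toy([0], C=3)
        with pytest.raises(ValueError):
            lrt_test3(X[:2], Sigmas[:2], A)

    def test_leave_out_statistic_stochastically_smallest(self, rng):
        """On condition-0-specific toys, T_{-0} sits below the others."""
        wins = 0
        for _ in range(50):
            layout = TrackLayout(["a", "b", "c", "d"], ["f"], 2)
            A = layout.design_matrix
            X = rng.normal(0, 1, size=(4, 2))
            X[0] += 6.0
            T_minus, _, _ = lrt_test3(X, [np.eye(2)] * 4, A)
            wins += T_minus[0] == min(T_minus)
        assert wins >= 45


class TestVectorisedAgainstScalar:
    def test_statistics_match_single_window_functions(self, rng):
        """The einsum pass reproduces the per-window reference functions."""
        for _ in range(20):
            C = int(rng.integers(2, 6))
            K = int(rng.integers(1, 4))
            R = int(rng.integers(1, 4))
            layout = TrackLayout([f"c{j}" for j in range(C)],
                                 [f"f{k}" for k in range(K)], R)
            P = K * R
            A = layout.design_matrix
            n = 4
            values = rng.normal(0, 2, size=(n, C * P))
            # structured covariance: sigma replicate-constant x correlation
            sigma = np.empty_like(values)
            for j in range(C):
                for k in range(K):
                    cols = layout.replicate_columns(j, k)
                    sigma[:, cols] = rng.uniform(0.5, 2.0, size=(n, 1))
            corrs = []
            for j in range(C):
                G = rng.normal(size=(P, P + 3))
                corrs.append(
                    __import__("dcap").covariance.nearest_correlation(G @ G.T)
                )
            u_bck = np.tile(rng.normal(size=(n, P)), (1, C))
            st = compute_statistics(values, sigma, layout, corrs, u_bck)
            for i in range(n):
                X_i = values[i].reshape(C, P)
                Sigmas = [assemble_covariance(sigma[i].reshape(C, P)[j], corrs[j])
                          for j in range(C)]
                ub = u_bck[i].reshape(C, P)[0]
                T1_ref, _ = lrt_test1(X_i, ub, Sigmas, A)
                T2_ref, _ = lrt_test2(X_i, Sigmas, A)
                assert st["T1"][i] == pytest.approx(T1_ref, abs=1e-8)
                assert st["T2"][i] == pytest.approx(T2_ref, abs=1e-8)
                if C >= 3:
                    T_minus_ref, _, _ = lrt_test3(
                        X_i, Sigmas, A, m=C)
                    assert np.allclose(st["T_minus"][i], T_minus_ref, atol=1e-8)


class TestBackgroundMean:
    def test_constant_signal(self, rng):
        layout = TrackLayout(["a", "b"], ["f"], 2)
        values = np.full((20, 4), 3.0)
        bm = background_mean(make_signal(values, layout))
        assert np.allclose(bm, 3.0)

    def test_spike_robustness(self):
        layout = TrackLayout(["a"], ["f"], 1)
        values = np.full((11, 1), 2.0)
        values[5] = 100.0
        bm = background_mean(make_signal(values, layout))
        assert bm[0, 0] == pytest.approx(2.0)

    def test_alternating_median_midpoint(self):
        layout = TrackLayout(["a"], ["f"], 1)
        values = np.array([[0.0], [4.0]] * 6)
        bm = background_mean(make_signal(values, layout))
        # interior neighbourhoods hold 11 windows; midpoint convention on ties
        assert bm[5, 0] == pytest.approx(np.median(values[0:11, 0]))

    def test_edge_truncation(self):
        layout = TrackLayout(["a"], ["f"], 1)
        values = np.arange(30, dtype=float)[:, None]
        bm = background_mean(make_signal(values, layout))
        assert bm[0, 0] == pytest.approx(np.median(values[:6, 0]))
        assert bm[29, 0] == pytest.approx(np.median(values[24:, 0]))


class TestAdjustAndMerge:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 10, 0.1),
        (0.2, 10, 1.0),
    ])
    def test_bonferroni_scalar(self, p, m, expected):
        assert bonferroni_adjust(np.array([p]), m)[0] == pytest.approx(expected)

    def test_bonferroni_vector_matches_scalar(self, rng):
        p = rng.uniform(size=20)
        out = bonferroni_adjust(p, 7)
        assert np.allclose(out, [min(1.0, x * 7) for x in p])

    def test_merge_adjacent_same_label(self):
        df = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 1000],
                           "end": [1000, 2000], "label": ["a", "a"]})
        out = merge_contiguous_windows(df)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 2000)

    def test_gap_not_merged(self):
        df = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 2000],
                           "end": [1000, 3000], "label": ["a", "a"]})
        assert len(merge_contiguous_windows(df)) == 2

    def test_label_mismatch_not_merged(self):
        df = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 1000],
                           "end": [1000, 2000], "label": ["a", "b"]})
        assert len(merge_contiguous_windows(df)) == 2


class TestCascade:
    def _planted_signal(self, rng, bound_conditions, C=3, N=400, effect=6.0):
        layout = TrackLayout([f"c{j}" for j in range(C)], ["f1", "f2"], 2)
        values = rng.normal(0, 1, size=(N, layout.n_tracks))
        peak = N // 2
        for j in bound_conditions:
            values[peak, layout.condition_slice(j)] += effect
        return make_signal(values, layout), peak, layout

    def test_common_peak_bound_not_differential(self, rng):
        signal, peak, layout = self._planted_signal(rng, [0, 1, 2])
        res = run_cascade(signal)
        assert bool(res.loc[peak, "bound"])
        assert not bool(res.loc[peak, "differential"])

    def test_condition_specific_peak_fully_classified(self, rng):
        signal, peak, layout = self._planted_signal(rng, [0], effect=8.0)
        res = run_cascade(signal)
        assert bool(res.loc[peak, "bound"])
        assert bool(res.loc[peak, "differential"])
        assert res.loc[peak, "label"] == layout.conditions[0]

    def test_pure_noise_rejections_controlled(self, rng):
        """Bonferroni keeps genome-wide false calls to a handful; the small
        excess over nominal FWER comes from the plug-in variance curve."""
        layout = TrackLayout(["a", "b", "c"], ["f1"], 2)
        values = rng.normal(0, 1, size=(2000, layout.n_tracks))
        res = run_cascade(make_signal(values, layout))
        assert res["bound"].sum() <= 0.005 * len(res)

    def test_empty_stages_propagate(self, rng):
        layout = TrackLayout(["a", "b", "c"], ["f1"], 2)
        values = rng.normal(0, 1, size=(500, layout.n_tracks))
        res = run_cascade(make_signal(values, layout))
        assert (res.loc[~res["bound"], "p2"].isna()).all()
        assert (res.loc[~res["differential"], "label"] == "").all()

    def test_peaks_mode_skips_test1(self, rng):
        signal, peak, layout = self._planted_signal(rng, [0], N=200, effect=8.0)
        res = run_cascade(signal, peaks_mode=True)
        assert res["p1"].isna().all()
        assert res["bound"].all()
        assert bool(res.loc[peak, "differential"])

    def test_shared_l1_consistency(self, rng):
        """T1 - T2 equals the background-vs-pooled likelihood gap (shared L1)."""
        spec_vals = rng.normal(0, 1, size=(300, 12))
        layout = TrackLayout(["a", "b", "c"], ["f1", "f2"], 2)
        signal = make_signal(spec_vals, layout)
        model = CovarianceModel(layout).fit(spec_vals)
        sigma = model.sigma(spec_vals)
        u_bck = background_mean(signal)
        st = compute_statistics(spec_vals, sigma, layout, model.correlations_, u_bck)
        # identical alternative term means T1 - T2 depends only on the nulls
        diff = st["T1"] - st["T2"]
        X = spec_vals.reshape(300, 3, 4)
        S = sigma.reshape(300, 3, 4)
        Ub = u_bck.reshape(300, 3, 4)
        Rinv = [np.linalg.inv(c) for c in model.correlations_]
        q = np.zeros(300)
        for j in range(3):
            r0 = (X[:, j] - Ub[:, j]) / S[:, j]
            r2 = (X[:, j] - st["u0"]) / S[:, j]
            q += (np.einsum("np,pq,nq->n", r0, Rinv[j], r0)
                  - np.einsum("np,pq,nq->n", r2, Rinv[j], r2))
        mask = (st["T1"] > 1e-9) & (st["T2"] > 1e-9)   # away from clipping
        assert np.allclose(diff[mask], q[mask], atol=1e-8)


class TestDCaPEstimator:
    def test_sklearn_protocol(self, small_weak_dataset):
        _, values, layout, _ = small_weak_dataset
        est = DCaP(layout=layout, alpha=0.01)
        assert est.get_params()["alpha"] == 0.01
        est.set_params(alpha=0.05)
        est.fit(values)
        assert hasattr(est, "results_")
        assert est.decision_function().shape == (len(values),)
        assert est.predict().dtype == bool

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = DCaP(alpha=0.01, halfspan=3000)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
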