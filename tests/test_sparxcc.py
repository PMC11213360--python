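"""SparXCC: cross-covariances, the t identity, base/iterative estimators."""

import numpy as np
import pytest

import compocross as cc
from compocross import (SparXCC, base_vs_iterative_diagnostic,
                        cross_log_covariance, select_thresholds_case_c,
                        sparxcc_base, sparxcc_iterative, t_matrix)


def quadruple_sum(C):
    """Brute-force t_ik = sum_{j != i} sum_{l != k} of the four-term kernel."""
    p, q = C.shape
    t = np.zeros((p, q))
    for i in range(p):
        for k in range(q):
            s = 0.0
            for j in range(p):
                if j == i:
                    continue
                for l in range(q):
                    if l == k:
                        continue
                    s += C[i, k] - C[i, l] - C[j, k] + C[j, l]
            t[i, k] = s
    return t


def restricted_quadruple_sum(C, S, T, alpha, beta):
    """Brute-force restricted iterative estimate (the O(pq) path's oracle)."""
    p, q = C.shape
    out = np.zeros((p, q))
    for i in range(p):
        for k in range(q):
            js = [j for j in S if j != i]
            ls = [l for l in T if l != k]
            s = sum(C[i, k] - C[i, l] - C[j, k] + C[j, l]
                    for j in js for l in ls)
            out[i, k] = s / (len(js) * len(ls) * alpha[i] * beta[k])
    return out


class TestCrossLogCovariance:
    def test_identical_column_gives_variance(self, rng):
        X = rng.integers(0, 99, (12, 4))
        out = cross_log_covariance(X, X[:, [0]].repeat(3, axis=1))
        lx = np.log(X + 1.0)
        assert out.C[0, 0] == pytest.approx(np.var(lx[:, 0], ddof=1), abs=1e-12)

    def test_matches_brute_force_pairwise(self, rng):
        X = rng.integers(0, 200, (8, 5))
        Y = rng.integers(0, 200, (8, 6))
        out = cross_log_covariance(X, Y)
        lx, ly = np.log(X + 1.0), np.log(Y + 1.0)
        for i in range(5):
            for k in range(6):
                assert out.C[i, k] == pytest.approx(
                    np.cov(lx[:, i], ly[:, k], ddof=1)[0, 1], abs=1e-12)

    def test_marginal_sums_consistent(self, rng):
        X = rng.integers(0, 200, (10, 7))
        Y = rng.integers(0, 200, (10, 5))
        out = cross_log_covariance(X, Y)
        assert np.allclose(out.row_sums, out.C.sum(axis=1), atol=1e-9)
        assert np.allclose(out.col_sums, out.C.sum(axis=0), atol=1e-9)
        assert out.grand_sum == pytest.approx(out.C.sum(), abs=1e-9)

    def test_replicate_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="replicate mismatch"):
            cross_log_covariance(rng.integers(0, 9, (5, 3)),
                                 rng.integers(0, 9, (6, 3)))


class TestTMatrix:
    def test_zero_covariance_gives_zero(self):
        C = np.zeros((4, 5))
        cov = cc.CrossLogCovariance(C, C.sum(1), C.sum(0), 0.0)
        assert np.all(t_matrix(cov) == 0)

    def test_two_by_two_hand_expansion(self, rng):
        C = rng.standard_normal((2, 2))
        cov = cc.CrossLogCovariance(C, C.sum(1), C.sum(0), float(C.sum()))
        t = t_matrix(cov)
        assert t[0, 0] == pytest.approx(C[0, 0] - C[0, 1] - C[1, 0] + C[1, 1],
                                        abs=1e-12)

    def test_closed_form_equals_quadruple_sum(self):
        """The mandated identity check: 50 random instances up to p=q=12."""
        rng = np.random.default_rng(12345)
        for _ in range(50):
            p, q = rng.integers(2, 13, size=2)
            C = rng.standard_normal((int(p), int(q)))
            cov = cc.CrossLogCovariance(C, C.sum(1), C.sum(0), float(C.sum()))
            assert np.allclose(t_matrix(cov), quadruple_sum(C), atol=1e-10)


class TestSparxccBase:
    def test_swap_symmetry_is_exact(self, rng):
        X = rng.integers(0, 300, (20, 9))
        Y = rng.integers(0, 300, (20, 6))
        a = sparxcc_base(X, Y).rho
        b = sparxcc_base(Y, X).rho
        assert np.array_equal(a, b.T)

    def test_null_estimates_small(self):
        p = q = 50
        ds = cc.simulate_dataset(np.eye(p + q), cc.study_marginals(p, q, "C"),
                                 cc.default_library_sizes("C"), n=500,
                                 case="C", q=q, seed=13)
        res = sparxcc_base(ds.X, ds.Y)
        assert np.mean(np.abs(res.rho)) < 0.1

    def test_recovers_self_correlation_under_column_permutation(self, casec_cluster):
        """Y = column-permuted X: each in-cluster OTU's strongest partner
        should be its own permuted copy."""
        rng = np.random.default_rng(1)
        X = casec_cluster.X
        perm = rng.permutation(X.shape[1])
        Y = X.iloc[:, perm].copy()
        res = sparxcc_base(X, Y)
        n_cluster = int(round(0.3 * X.shape[1]))
        inv = np.argsort(perm)
        hits = sum(res.rho[i].argmax() == inv[i] for i in range(n_cluster))
        assert hits >= n_cluster - 1

    def test_recovers_cluster_cross_correlation(self, casec_cluster):
        truth = casec_cluster.truth_cross
        res = sparxcc_base(casec_cluster.X, casec_cluster.Y)
        # at c=0.3 the base estimator carries a compositional bias of about
        # -2*c*rho + c^2*rho; the cluster must still stand far above the rest
        assert abs(res.rho[truth == 0.75].mean() - 0.75) < 0.35
        assert res.rho[truth == 0.75].mean() > 0.4
        assert res.rho[truth == 0.75].mean() > \
            np.abs(res.rho[truth == 0]).mean() + 0.25

    def test_compositional_invariance(self, rng):
        X = rng.integers(1, 500, (15, 6)).astype(float)
        Y = rng.integers(1, 500, (15, 5)).astype(float)
        sx = rng.uniform(0.5, 20.0, 15)
        sy = rng.uniform(0.5, 20.0, 15)
        a = sparxcc_base(X, Y, pseudo_count=1e-12).rho
        b = sparxcc_base(X * sx[:, None], Y * sy[:, None],
                         pseudo_count=1e-12).rho
        assert np.allclose(a, b, atol=1e-7)


class TestSparxccIterative:
    def test_infinite_thresholds_reduce_to_base(self, rng):
        X = rng.integers(0, 300, (15, 7))
        Y = rng.integers(0, 300, (15, 5))
        base = sparxcc_base(X, Y)
        it = sparxcc_iterative(X, Y, t1=np.inf, t2=np.inf)
        assert np.array_equal(it.raw_rho, base.raw_rho)
        assert it.n_iterations == 0

    def test_restricted_step_matches_brute_force(self, rng):
        """O(pq) restricted sums against the explicit restricted loop."""
        from compocross.sparxcc import _restricted_estimate

        X = rng.integers(0, 300, (20, 7))
        Y = rng.integers(0, 300, (20, 6))
        cov = cross_log_covariance(X, Y)
        alpha = cc.basis_variances_from_counts(X).std
        beta = cc.basis_variances_from_counts(Y).std
        mask_s = np.array([1, 0, 1, 1, 0, 1, 1], dtype=bool)
        mask_t = np.array([0, 1, 1, 1, 0, 1], dtype=bool)
        fast = _restricted_estimate(cov, mask_s, mask_t, alpha, beta)
        slow = restricted_quadruple_sum(cov.C, np.flatnonzero(mask_s),
                                        np.flatnonzero(mask_t), alpha, beta)
        assert np.allclose(fast, slow, atol=1e-10)

    def test_tiny_thresholds_return_base_with_warning(self, rng):
        X = rng.integers(0, 300, (15, 6))
        Y = rng.integers(0, 300, (15, 5))
        base = sparxcc_base(X, Y)
        with pytest.warns(RuntimeWarning, match="too few features"):
            res = sparxcc_iterative(X, Y, t1=1e-12, t2=1e-12)
        assert np.array_equal(res.raw_rho, base.raw_rho)

    def test_reduces_bias_under_dense_cluster(self):
        p = q = 60
        psi = cc.cluster_correlation_matrix(p, q, c=0.4, rho=0.75, case="C")
        marg = cc.study_marginals(p, q, case="C")
        libs = cc.default_library_sizes("C")
        mae_base, mae_iter = [], []
        for s in range(8):
            ds = cc.simulate_dataset(psi, marg, libs, n=50, case="C", q=q,
                                     seed=4000 + s)
            t1, t2 = select_thresholds_case_c(ds.X, ds.Y, n_perm=20,
                                              percentile=100, seed=s)
            truth = ds.truth_cross
            mae_base.append(cc.mae_split(truth, sparxcc_base(ds.X, ds.Y).rho)[0])
            mae_iter.append(cc.mae_split(
                truth, sparxcc_iterative(ds.X, ds.Y, t1=t1, t2=t2).rho)[0])
        assert np.mean(mae_iter) < np.mean(mae_base)

    def test_loadings_truth_often_leaves_base_unchanged(self):
        """Sign-symmetric (loadings) truth has no common bias to remove, so
        the default thresholds frequently leave the base output untouched."""
        p = q = 10
        identical = 0
        for s in range(5):
            psi = cc.loadings_correlation_matrix(p + q, k=5, seed=s)
            ds = cc.simulate_dataset(psi, cc.study_marginals(p, q, "C"),
                                     cc.default_library_sizes("C"), n=50,
                                     case="C", q=q, seed=100 + s)
            t1, t2 = select_thresholds_case_c(ds.X, ds.Y, n_perm=10,
                                              percentile=80, seed=s)
            base = sparxcc_base(ds.X, ds.Y)
            try:
                it = sparxcc_iterative(ds.X, ds.Y, t1=t1, t2=t2)
            except RuntimeWarning:
                continue
            identical += np.array_equal(it.raw_rho, base.raw_rho)
        assert identical >= 1


class TestThresholdsCaseC:
    def test_deterministic_and_monotone(self, casec_cluster):
        X, Y = casec_cluster.X, casec_cluster.Y
        t80 = select_thresholds_case_c(X, Y, n_perm=5, percentile=80, seed=2)
        t100 = select_thresholds_case_c(X, Y, n_perm=5, percentile=100, seed=2)
        assert t80 == select_thresholds_case_c(X, Y, n_perm=5, percentile=80,
                                               seed=2)
        assert t80[0] <= t100[0] and t80[1] <= t100[1]

    def test_null_sets_retain_about_80_percent(self):
        p = q = 40
        ds = cc.simulate_dataset(np.eye(p + q), cc.study_marginals(p, q, "C"),
                                 cc.default_library_sizes("C"), n=50,
                                 case="C", q=q, seed=21)
        t1, t2 = select_thresholds_case_c(ds.X, ds.Y, n_perm=20,
                                          percentile=80, seed=0)
        base = sparxcc_base(ds.X, ds.Y)
        ra = np.abs(base.rho)
        frac_s = (ra.mean(axis=1) < t1).mean()
        frac_t = (ra.mean(axis=0) < t2).mean()
        assert 0.5 <= frac_s <= 1.0
        assert 0.5 <= frac_t <= 1.0


class TestDiagnostic:
    def test_identity_and_pure_shift(self, rng):
        base = rng.uniform(-1, 1, 30)
        s, i, r = base_vs_iterative_diagnostic(base, base)
        assert (s, i, r) == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)
        s, i, r = base_vs_iterative_diagnostic(base, base + 0.2)
        assert (s, i, r) == pytest.approx((1.0, 0.2, 0.0), abs=1e-12)

    def test_dense_cluster_shows_slope_one_nonzero_intercept(self):
        p = q = 60
        psi = cc.cluster_correlation_matrix(p, q, c=0.4, rho=0.75, case="C")
        ds = cc.simulate_dataset(psi, cc.study_marginals(p, q, "C"),
                                 cc.default_library_sizes("C"), n=50,
                                 case="C", q=q, seed=17)
        t1, t2 = select_thresholds_case_c(ds.X, ds.Y, n_perm=20,
                                          percentile=100, seed=0)
        base = sparxcc_base(ds.X, ds.Y)
        it = sparxcc_iterative(ds.X, ds.Y, t1=t1, t2=t2)
        slope, intercept, _ = base_vs_iterative_diagnostic(base.raw_rho,
                                                           it.raw_rho)
        assert 0.8 <= slope <= 1.2
        assert abs(intercept) > 0.05


class TestSparxccEstimatorClass:
    def test_fit_base_matches_function(self, casec_cluster):
        est = SparXCC(method="base").fit(casec_cluster.X, casec_cluster.Y)
        fn = sparxcc_base(casec_cluster.X, casec_cluster.Y)
        assert np.array_equal(est.rho_, fn.rho)
        assert est.rho_.shape == (30, 30)

    def test_fit_iterative_reproducible(self, casec_cluster):
        kw = dict(method="iterative", thresholds="auto", percentile=100,
                  n_perm=5, random_state=3)
        a = SparXCC(**kw).fit(casec_cluster.X, casec_cluster.Y)
        b = SparXCC(**kw).fit(casec_cluster.X, casec_cluster.Y)
        assert a.thresholds_ == b.thresholds_
        assert np.array_equal(a.rho_, b.rho_)
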