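"""PCA conformance monitor: limits, statistics, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from visqc import (PCAConformanceMonitor, conformance_test, fit_pca, project,
                   q_limit, t2_limit)
from visqc.exceptions import (DegreesOfFreedomError, FeatureMapError,
                              MomentError, RankError)
from visqc.mspc import control_limit_coverage, simulate_low_rank_gaussian

# Quantile values frozen from an independent oracle (R stats::qf / qchisq)
R_T2_LIMIT_7_336 = 14.5222424623     # 7*335/329 * qf(0.95, 7, 329)
R_T2_LIMIT_1_3_HALF = 0.6666666667   # 1*(3-1)/(3-1) * qf(0.5, 1, 2)
R_CHI2_95_DF5 = 11.0704976935        # qchisq(0.95, 5)
R_CHI2_95_DF1 = 3.8414588207         # qchisq(0.95, 1)


def eigendecomposition_t2_q(X_cal, X_test, A):
    """Independent T^2/Q oracle via the full covariance eigendecomposition."""
    mu = X_cal.mean(axis=0)
    sd = X_cal.std(axis=0, ddof=1)
    Z = (X_cal - mu) / sd
    w, V = np.linalg.eigh(np.cov(Z, rowvar=False))
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    T = ((X_test - mu) / sd) @ V
    t2 = np.sum(T[:, :A] ** 2 / w[:A], axis=1)
    q = np.sum(T[:, A:] ** 2, axis=1)
    return t2, q


class TestLimits:
    def test_t2_limit_matches_R_oracle(self):
        assert t2_limit(7, 336, 0.05) == pytest.approx(R_T2_LIMIT_7_336,
                                                       abs=1e-6)
        assert t2_limit(1, 3, 0.5) == pytest.approx(R_T2_LIMIT_1_3_HALF,
                                                    abs=1e-6)

    def test_t2_limit_converges_to_chi2(self):
        assert t2_limit(1, 10 ** 7, 0.05) == pytest.approx(R_CHI2_95_DF1,
                                                           abs=1e-3)

    def test_t2_limit_requires_dof(self):
        with pytest.raises(DegreesOfFreedomError):
            t2_limit(7, 7, 0.05)

    def test_q_limit_box_form(self):
        # mu=5, nu=10 gives g=1, h=5
        assert q_limit(5.0, 10.0, 0.05) == pytest.approx(R_CHI2_95_DF5,
                                                         abs=1e-6)

    def test_q_limit_sd_convention(self):
        assert q_limit(5.0, np.sqrt(10.0), 0.05, nu_convention="sd") == \
            pytest.approx(R_CHI2_95_DF5, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0), st.floats(0.1, 50.0), st.floats(2.0, 100.0))
    def test_q_limit_scaling_identity(self, mu, nu, c):
        assert q_limit(c * mu, c ** 2 * nu) == pytest.approx(
            c * q_limit(mu, nu), rel=1e-9)

    def test_q_limit_concentrates_at_mu_for_small_nu(self):
        assert q_limit(5.0, 1e-8, 0.05) == pytest.approx(5.0, abs=1e-3)

    def test_q_limit_rejects_bad_moments(self):
        with pytest.raises(MomentError):
            q_limit(0.0, 1.0)


class TestFit:
    def test_planar_data_has_zero_q(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 6))
        X = rng.standard_normal((30, 2)) @ basis + rng.standard_normal(6)
        model = PCAConformanceMonitor(n_components=2, scale=False).fit(X)
        _, q = model.t2_q(X)
        assert np.allclose(q, 0.0, atol=1e-18)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        model = fit_pca(rng.standard_normal((40, 12)), A=4)
        G = model.components_ @ model.components_.T
        assert np.allclose(G, np.eye(4), atol=1e-12)

    def test_score_variances_match_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 10)) @ np.diag(np.linspace(3, 0.5, 10))
        model = fit_pca(X, A=5)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        w = np.sort(np.linalg.eigvalsh(np.cov(Z, rowvar=False)))[::-1]
        assert np.allclose(model.score_variances_, w[:5], atol=1e-10)

    def test_rank_error(self):
        rng = np.random.default_rng(3)
        X = np.outer(rng.standard_normal(20), rng.standard_normal(5))
        with pytest.raises(RankError):
            fit_pca(X, A=4, scale=False)

    def test_too_few_samples(self):
        with pytest.raises(DegreesOfFreedomError):
            fit_pca(np.zeros((5, 10)), A=7)

    def test_zero_variance_columns_dropped(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 6))
        X[:, 2] = 7.0
        model = fit_pca(X, A=3)
        assert list(model.dropped_columns_) == [2]
        t2, q = model.t2_q(X)  # accepts full-width vectors
        assert np.all(np.isfinite(t2)) and np.all(np.isfinite(q))


class TestProjection:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(5)
        X, _ = simulate_low_rank_gaussian(60, rng, n_features=8, rank=3)
        return fit_pca(X, A=3), X

    def test_calibration_mean_is_origin(self, fitted):
        model, X = fitted
        t2, q = model.t2_q(X.mean(axis=0, keepdims=True))
        assert t2[0] == pytest.approx(0.0, abs=1e-18)
        assert q[0] == pytest.approx(0.0, abs=1e-18)

    def test_point_along_first_loading(self, fitted):
        model, _ = fitted
        c = 2.5
        z = c * model.components_[0]
        x = model.mean_ + model.scale_ * z
        t2, q = model.t2_q(x[None, :])
        assert t2[0] == pytest.approx(c ** 2 / model.score_variances_[0],
                                      rel=1e-9)
        assert q[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_in_residual_space(self, fitted):
        model, _ = fitted
        rng = np.random.default_rng(6)
        v = rng.standard_normal(model.components_.shape[1])
        v -= model.components_.T @ (model.components_ @ v)
        v *= 3.0 / np.linalg.norm(v)
        x = model.mean_ + model.scale_ * v
        t2, q = model.t2_q(x[None, :])
        assert t2[0] == pytest.approx(0.0, abs=1e-12)
        assert q[0] == pytest.approx(9.0, rel=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        X_cal = rng.standard_normal((20, 5)) * np.linspace(2, 0.5, 5)
        X_test = rng.standard_normal((15, 5))
        model = fit_pca(X_cal, A=3)
        t2, q = model.t2_q(X_test)
        t2_o, q_o = eigendecomposition_t2_q(X_cal, X_test, 3)
        assert np.allclose(t2, t2_o, rtol=1e-8)
        assert np.allclose(q, q_o, rtol=1e-8, atol=1e-10)

    def test_invariant_to_row_and_column_permutation(self):
        rng = np.random.default_rng(8)
        X_cal, _ = simulate_low_rank_gaussian(50, rng, n_features=9, rank=3)
        X_test = rng.standard_normal((10, 9))
        m1 = fit_pca(X_cal, A=3)
        rows = rng.permutation(50)
        cols = rng.permutation(9)
        m2 = fit_pca(X_cal[rows][:, cols], A=3)
        t2a, qa = m1.t2_q(X_test)
        t2b, qb = m2.t2_q(X_test[:, cols])
        assert np.allclose(t2a, t2b, rtol=1e-8)
        assert np.allclose(qa, qb, rtol=1e-8)

    def test_feature_map_mismatch(self, fitted):
        model, _ = fitted
        with pytest.raises(FeatureMapError):
            model.t2_q(np.zeros((1, 99)))

    def test_project_returns_chart_point(self, fitted):
        model, X = fitted
        pt = project(model, X[0], sample_id="s0", metadata={"day": 0})
        assert pt.sample_id == "s0"
        assert pt.conform == (pt.t2 < model.t2_limit_
                              and pt.q < model.q_limit_)


class TestVerdictsAndSummary:
    def _manual_monitor(self):
        """Hand-built unit model: 1 component on 3 features."""
        m = PCAConformanceMonitor(n_components=1)
        m.n_features_in_ = 3
        m.n_samples_ = 100
        m.kept_columns_ = np.arange(3)
        m.dropped_columns_ = np.array([], dtype=int)
        m.mean_ = np.zeros(3)
        m.scale_ = np.ones(3)
        m.components_ = np.array([[1.0, 0.0, 0.0]])
        m.score_variances_ = np.array([1.0])
        m.q_mean_ = 1.0
        m.q_var_ = 1.0
        m.t2_limit_ = 4.0
        m.q_limit_ = 1.0
        return m

    def test_sample_exactly_at_limit_is_nonconforming(self):
        m = self._manual_monitor()
        # t2 = 2^2 / 1 = 4.0 == limit; strict inequality rejects
        assert m.predict(np.array([[2.0, 0.0, 0.0]]))[0] == -1
        assert m.predict(np.array([[1.0, 0.0, 0.0]]))[0] == 1
        # q = 1.0 == limit in the residual space
        assert m.predict(np.array([[0.0, 1.0, 0.0]]))[0] == -1

    def test_rejection_percentages(self):
        df = pd.DataFrame({
            "conform": [False] * 11 + [True] + [False] * 4,
            "condition": ["TC1"] * 12 + ["TC5"] * 4,
            "storage_day": [7] * 12 + [0] * 4,
        })
        summary = conformance_test(df).set_index("condition")
        assert summary.loc["TC1", "n_rejected"] == 11
        assert round(summary.loc["TC1", "rejection_pct"], 1) == 91.7
        assert summary.loc["TC5", "rejection_pct"] == 100.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            conformance_test(pd.DataFrame({"conform": []}))


class TestEstimatorBehaviour:
    def test_sklearn_clone_and_params(self):
        m = PCAConformanceMonitor(n_components=3, alpha=0.1)
        m2 = clone(m)
        assert m2.get_params()["n_components"] == 3
        m2.set_params(alpha=0.05)
        assert m2.alpha == 0.05

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X, _ = simulate_low_rank_gaussian(40, rng, n_features=6, rank=2)
        model = fit_pca(X, A=2)
        path = tmp_path / "model.json"
        model.to_json(path, feature_names=[f"f{i}" for i in range(6)])
        back = PCAConformanceMonitor.from_json(path)
        t2a, qa = model.t2_q(X)
        t2b, qb = back.t2_q(X)
        assert np.allclose(t2a, t2b) and np.allclose(qa, qb)
        assert back.t2_limit_ == model.t2_limit_


def test_held_out_coverage_near_nominal():
    """Both limits should pass ~95% of independent in-control samples."""
    t2_cov, q_cov = control_limit_coverage(seed=0, n_test=4000)
    assert 93.0 < t2_cov < 97.0
    assert 89.0 < q_cov < 98.0
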