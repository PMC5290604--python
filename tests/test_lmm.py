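"""Mixed-model engine: likelihood exactness, GLS/OLS collapse, EBLUPs,
LRT, R^2, residual ACF and the VPC contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import circspline as cs
from circspline import lmm, models


def random_instance(rng, n_subj=4, max_obs=6, n_var_groups=1):
    """A small random mixed-model instance for dense-oracle checks."""
    blocks = []
    for i in range(n_subj):
        m = int(rng.integers(3, max_obs + 1))
        slots = np.sort(rng.choice(np.arange(12), size=m, replace=False)).astype(float)
        X = np.column_stack([np.ones(m), slots / 4.0])
        Z = X.copy()
        y = 100 + rng.normal(size=m) * 4
        blocks.append(
            lmm.SubjectBlock(f"S{i}", y, X, Z, slots, var_group=i % n_var_groups)
        )
    return lmm.MixedModelData(
        blocks, ["int", "t"], ["int", "t"], n_var_groups=n_var_groups
    )


def dense_loglik(params, data):
    """Independent oracle: stack each subject's dense MVN density."""
    total = 0.0
    beta = np.asarray(params.beta)
    for b in data.blocks:
        D = np.abs(b.slots[:, None] - b.slots[None, :])
        d = params.var_ratio[b.var_group]
        V = b.Z @ params.Sigma_b @ b.Z.T + params.sigma**2 * d**2 * params.rho**D
        total += stats.multivariate_normal.logpdf(b.y, b.X @ beta, V)
    return total


class TestMarginalLoglik:
    @pytest.mark.parametrize("trial", range(5))
    def test_ml_matches_dense_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        data = random_instance(rng, n_var_groups=2)
        A = rng.normal(size=(2, 2))
        params = lmm.make_params(
            beta=rng.normal(size=2) + [100, 0],
            Sigma_b=A @ A.T + 0.2 * np.eye(2),
            sigma=float(rng.uniform(0.5, 3)),
            rho=float(rng.uniform(-0.6, 0.8)),
            var_ratio=np.array([1.0, float(rng.uniform(0.7, 1.5))]),
        )
        ours = lmm.marginal_loglik(params, data, criterion="ML")
        assert ours == pytest.approx(dense_loglik(params, data), abs=1e-8)

    def test_exact_fit_identity_covariance(self):
        """y = X beta exactly, V = I: loglik is -(n/2) log(2 pi)."""
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        beta = np.array([2.0, 0.5])
        blocks = [
            lmm.SubjectBlock("A", X @ beta, X, X, np.arange(4.0)),
            lmm.SubjectBlock("B", X @ beta, X, X, np.arange(4.0)),
        ]
        data = lmm.MixedModelData(blocks, ["int", "t"], ["int", "t"])
        params = lmm.make_params(beta, np.zeros((2, 2)), sigma=1.0, rho=0.0)
        ll = lmm.marginal_loglik(params, data, criterion="ML")
        assert ll == pytest.approx(-(8 / 2) * np.log(2 * np.pi), abs=1e-10)

    def test_rho_zero_equals_independent_residuals(self):
        rng = np.random.default_rng(3)
        data = random_instance(rng)
        params = lmm.make_params(
            [100.0, 1.0], np.diag([4.0, 0.5]), sigma=2.0, rho=0.0
        )
        ll = lmm.marginal_loglik(params, data, criterion="ML")
        # oracle with R = I explicitly
        total = 0.0
        for b in data.blocks:
            V = b.Z @ params.Sigma_b @ b.Z.T + 4.0 * np.eye(b.y.size)
            total += stats.multivariate_normal.logpdf(
                b.y, b.X @ params.beta.to_numpy(), V
            )
        assert ll == pytest.approx(total, abs=1e-8)

    def test_non_psd_sigma_rejected(self):
        rng = np.random.default_rng(4)
        data = random_instance(rng)
        params = lmm.make_params([100.0, 1.0], np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)
        with pytest.raises(ValueError, match="positive semi-definite"):
            lmm.marginal_loglik(params, data)


class TestFit:
    def test_gls_collapses_to_ols_at_zero_variances(self, rng):
        cfg = cs.default_config(n_subjects=10, Sigma_b=np.zeros((6, 6)), rho=0.0)
        prof, _ = cs.simulate_cohort(cfg, seed=9)
        data = models.build(prof, models.ModelSpec())
        beta_gls, _ = lmm.gls(data, Sigma_b=None, rho=0.0)
        Xall = np.vstack([b.X for b in data.blocks])
        yall = np.concatenate([b.y for b in data.blocks])
        bols = np.linalg.lstsq(Xall, yall, rcond=None)[0]
        np.testing.assert_allclose(beta_gls.to_numpy(), bols, rtol=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        """Cross-implementation oracle: random intercept + slope, no AR(1)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        Sb = np.array([[9.0, 1.2], [1.2, 0.8]])
        blocks, rows = [], []
        for i in range(10):
            t = np.arange(30, dtype=float)
            Z = np.column_stack([np.ones(30), t / 10])
            b = rng.multivariate_normal(np.zeros(2), Sb)
            y = 50 + 2.0 * (t / 10) + Z @ b + rng.normal(scale=1.5, size=30)
            blocks.append(lmm.SubjectBlock(f"S{i}", y, Z.copy(), Z, t))
            rows += [{"sid": i, "t": tj / 10, "y": yj} for tj, yj in zip(t, y)]
        data = lmm.MixedModelData(blocks, ["int", "t"], ["int", "t"])
        ours = lmm.fit(data, criterion="REML", ar1=False)
        ref = sm.MixedLM.from_formula(
            "y ~ t", pd.DataFrame(rows), groups="sid", re_formula="~t"
        ).fit(reml=True)
        np.testing.assert_allclose(ours.beta.to_numpy(), ref.fe_params.to_numpy(), atol=1e-3)
        assert ours.sigma == pytest.approx(np.sqrt(ref.scale), rel=1e-3)
        np.testing.assert_allclose(ours.Sigma_b, ref.cov_re.to_numpy(), rtol=2e-3, atol=1e-3)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_deterministic_given_seed(self):
        prof, _ = cs.simulate_cohort(cs.default_config(n_subjects=6), seed=5)
        data = models.build(prof, models.ModelSpec(random_terms="intercept"))
        f1 = lmm.fit(data, criterion="REML", ar1=False, seed=3)
        f2 = lmm.fit(data, criterion="REML", ar1=False, seed=3)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.beta.to_numpy(), f2.beta.to_numpy())
        assert np.array_equal(f1.Sigma_b, f2.Sigma_b)

    def test_subject_reordering_invariance(self):
        prof, _ = cs.simulate_cohort(cs.default_config(n_subjects=8), seed=6)
        spec = models.ModelSpec(random_terms="intercept", ar1=False)
        f1 = lmm.fit(models.build(prof, spec), criterion="REML", ar1=False)
        f2 = lmm.fit(models.build(prof[::-1], spec), criterion="REML", ar1=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)
        np.testing.assert_allclose(f1.beta.to_numpy(), f2.beta.to_numpy(), atol=1e-5)

    def test_rank_deficient_design_names_columns(self):
        prof, _ = cs.simulate_cohort(cs.default_config(n_subjects=4), seed=7)
        data = models.build(prof, models.ModelSpec())
        for b in data.blocks:
            b.X[:, 2] = 2.0 * b.X[:, 1]  # make s2 collinear with s1
        with pytest.raises(ValueError, match="rank deficient"):
            lmm.fit(data)

    def test_fitted_loglik_not_below_generating_params(self, small_cohort, small_fit):
        """Optimality: the maximized REML criterion beats the truth."""
        cfg = cs.default_config()
        truth = lmm.make_params(
            np.r_[cfg.intercept, cfg.slopes],
            np.asarray(cfg.Sigma_b),
            cfg.sigma,
            cfg.rho,
            x_names=small_fit.fitted.x_names,
        )
        ll_truth = lmm.marginal_loglik(truth, small_fit.data, criterion="REML")
        assert small_fit.fitted.loglik >= ll_truth - 1e-6


class TestEblup:
    def _toy(self):
        X = np.column_stack([np.ones(3), np.array([0.0, 1.0, 2.0])])
        return X

    def test_zero_residual_subject_has_zero_eblup(self):
        X = self._toy()
        beta = np.array([10.0, 1.0])
        blocks = [
            lmm.SubjectBlock("A", X @ beta, X, X, np.arange(3.0)),
            lmm.SubjectBlock("B", X @ beta + 1.0, X, X, np.arange(3.0)),
        ]
        data = lmm.MixedModelData(blocks, ["int", "t"], ["int", "t"])
        params = lmm.make_params(beta, np.diag([2.0, 1.0]), sigma=1.0, rho=0.0)
        bl = lmm.eblup(params, data)
        np.testing.assert_allclose(bl.loc["A"].to_numpy(), 0.0, atol=1e-12)
        assert np.abs(bl.loc["B"].to_numpy()).max() > 0

    def test_matches_henderson_equations(self):
        """Independent oracle: solve Henderson's mixed-model equations."""
        rng = np.random.default_rng(17)
        X = self._toy()
        y = 10 + rng.normal(size=3) * 2
        block = lmm.SubjectBlock("A", y, X, X, np.arange(3.0))
        data = lmm.MixedModelData([block, lmm.SubjectBlock("B", y + 1, X, X, np.arange(3.0))],
                                  ["int", "t"], ["int", "t"])
        Sb = np.array([[3.0, 0.4], [0.4, 0.9]])
        sigma = 1.3
        beta = np.array([9.5, 0.3])
        params = lmm.make_params(beta, Sb, sigma, rho=0.0)
        ours = lmm.eblup(params, data)
        # Henderson: (Z'Z/sig^2 + Sb^-1) b = Z'(y - X beta)/sig^2 per subject
        for b in data.blocks:
            lhs = b.Z.T @ b.Z / sigma**2 + np.linalg.inv(Sb)
            rhs = b.Z.T @ (b.y - b.X @ beta) / sigma**2
            expected = np.linalg.solve(lhs, rhs)
            np.testing.assert_allclose(ours.loc[b.subject_id].to_numpy(), expected, atol=1e-10)

    def test_complete_shrinkage_as_sigma_b_vanishes(self, small_fit):
        params = lmm.make_params(
            small_fit.fitted.beta.to_numpy(),
            np.eye(6) * 1e-12,
            small_fit.fitted.sigma,
            small_fit.fitted.rho,
            x_names=small_fit.fitted.x_names,
            z_names=small_fit.fitted.z_names,
        )
        bl = lmm.eblup(params, small_fit.data)
        assert np.abs(bl.to_numpy()).max() < 1e-8


class TestLRT:
    def _dummy_fit(self, loglik, n_params, criterion="ML", x_names=("a",)):
        f = lmm.make_params(np.zeros(len(x_names)), np.eye(1), 1.0,
                            x_names=list(x_names), criterion=criterion)
        f.loglik = loglik
        f.n_params = n_params
        return f

    def test_identical_models(self):
        a = self._dummy_fit(-100.0, 5)
        b = self._dummy_fit(-100.0, 5)
        res = lmm.lrt(a, b)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_chi_square_reference(self):
        a = self._dummy_fit(-101.92, 5)
        b = self._dummy_fit(-100.0, 6)
        res = lmm.lrt(a, b)
        assert res.statistic == pytest.approx(3.84, abs=1e-9)
        assert res.p == pytest.approx(0.05, abs=2e-4)
        # boundary mixture halves the naive p for df=1
        assert res.p_boundary == pytest.approx(res.p / 2, abs=1e-12)

    def test_criterion_mismatch_raises(self):
        a = self._dummy_fit(-101.0, 5, criterion="REML")
        b = self._dummy_fit(-100.0, 6, criterion="ML")
        with pytest.raises(ValueError, match="criteria"):
            lmm.lrt(a, b)

    def test_reml_with_different_fixed_effects_raises(self):
        a = self._dummy_fit(-101.0, 5, criterion="REML", x_names=("a",))
        b = self._dummy_fit(-100.0, 6, criterion="REML", x_names=("a", "b"))
        with pytest.raises(ValueError, match="REML"):
            lmm.lrt(a, b)


class TestR2:
    def test_zero_when_no_structure(self):
        rng = np.random.default_rng(31)
        data = random_instance(rng, n_subj=5)
        params = lmm.make_params([100.0, 0.0], np.zeros((2, 2)), sigma=2.0, rho=0.0)
        r2m, r2c = lmm.r2(params, data)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c == pytest.approx(0.0, abs=1e-12)

    def test_conditional_tends_to_one_as_sigma_vanishes(self):
        rng = np.random.default_rng(32)
        data = random_instance(rng, n_subj=5)
        params = lmm.make_params([100.0, 1.0], np.diag([4.0, 1.0]), sigma=1e-8)
        _, r2c = lmm.r2(params, data)
        assert r2c == pytest.approx(1.0, abs=1e-10)

    def test_random_intercept_case_matches_original_formula(self):
        """Johnson's extension reduces to the Nakagawa-Schielzeth formula
        for a random-intercept-only model."""
        rng = np.random.default_rng(33)
        blocks = []
        for i in range(6):
            t = np.arange(8.0)
            X = np.column_stack([np.ones(8), t])
            Z = np.ones((8, 1))
            y = 50 + 0.8 * t + rng.normal() * 2 + rng.normal(size=8)
            blocks.append(lmm.SubjectBlock(f"S{i}", y, X, Z, t))
        data = lmm.MixedModelData(blocks, ["int", "t"], ["int"])
        params = lmm.make_params([50.0, 0.8], np.array([[4.0]]), sigma=1.0, rho=0.0,
                                 z_names=["int"])
        r2m, r2c = lmm.r2(params, data)
        fixed = np.concatenate([b.X @ np.array([50.0, 0.8]) for b in data.blocks])
        var_f = np.var(fixed)
        assert r2m == pytest.approx(var_f / (var_f + 4.0 + 1.0), abs=1e-12)
        assert r2c == pytest.approx((var_f + 4.0) / (var_f + 4.0 + 1.0), abs=1e-12)


class TestResidualACF:
    def _white_noise_data(self, rng, n_subj=30):
        blocks = []
        for i in range(n_subj):
            t = np.arange(20.0)
            X = np.ones((20, 1))
            Z = np.ones((20, 1))
            y = 5.0 + rng.normal(size=20)
            blocks.append(lmm.SubjectBlock(f"S{i}", y, X, Z, t))
        return lmm.MixedModelData(blocks, ["int"], ["int"])

    def test_lag_zero_is_one_and_white_noise_inside_band(self, rng):
        data = self._white_noise_data(rng)
        params = lmm.make_params([5.0], np.array([[1e-10]]), sigma=1.0, rho=0.0,
                                 x_names=["int"], z_names=["int"])
        table = lmm.residual_acf(params, data, max_lag=5)
        assert table["acf"].iloc[0] == 1.0
        assert abs(table["acf"].iloc[1]) < 3 / np.sqrt(data.n_obs)

    def test_unmodelled_ar1_shows_at_lag_one(self, rng):
        blocks = []
        for i in range(30):
            t = np.arange(20.0)
            e = np.empty(20)
            e[0] = rng.normal()
            for j in range(1, 20):
                e[j] = 0.6 * e[j - 1] + rng.normal() * np.sqrt(1 - 0.36)
            blocks.append(
                lmm.SubjectBlock(f"S{i}", 5.0 + e, np.ones((20, 1)), np.ones((20, 1)), t)
            )
        data = lmm.MixedModelData(blocks, ["int"], ["int"])
        ignoring = lmm.make_params([5.0], np.array([[1e-10]]), sigma=1.0, rho=0.0,
                                   x_names=["int"], z_names=["int"])
        table = lmm.residual_acf(ignoring, data, max_lag=3)
        assert table["acf"].iloc[1] > 3 / np.sqrt(data.n_obs)

    def test_max_lag_truncated_with_warning(self, rng):
        data = self._white_noise_data(rng, n_subj=3)
        params = lmm.make_params([5.0], np.array([[1e-10]]), sigma=1.0,
                                 x_names=["int"], z_names=["int"])
        with pytest.warns(UserWarning, match="truncating"):
            table = lmm.residual_acf(params, data, max_lag=50)
        assert table["lag"].max() == 19


class TestVPC:
    def test_same_seed_identical(self, small_fit):
        t1 = lmm.vpc(small_fit.fitted, small_fit.data, nsim=20, seed=11)
        t2 = lmm.vpc(small_fit.fitted, small_fit.data, nsim=20, seed=11)
        pd.testing.assert_frame_equal(t1, t2)

    def test_degenerate_model_zero_band(self, rng):
        data = random_instance(rng, n_subj=3)
        params = lmm.make_params([100.0, 1.0], np.zeros((2, 2)), sigma=0.0, rho=0.0)
        table = lmm.vpc(params, data, nsim=50, seed=1)
        np.testing.assert_allclose(table["sim_hi"] - table["sim_lo"], 0.0, atol=1e-12)

    def test_nsim_validation(self, small_fit):
        with pytest.raises(ValueError):
            lmm.vpc(small_fit.fitted, small_fit.data, nsim=0)
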