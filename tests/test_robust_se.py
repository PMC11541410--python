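import numpy as np
import pandas as pd
import pytest
from scipy.linalg import sqrtm

from mlmcorr import ClusteredDataset
from mlmcorr.lmm_core import DesignError, ModelSpec, fit_lmm, fit_ols
from mlmcorr.robust_se import (
    coef_table,
    cr0_cov,
    cr1_cov,
    cr2_cov,
    robust_inference,
    satterthwaite_df,
)

from conftest import make_clustered


def _dense_cr0(fit):
    """Literal dense transcription of the GLS sandwich."""
    M = fit.cov_gls
    meat = np.zeros((fit.p, fit.p))
    for Xj, Vj, rj in zip(fit.X_blocks, fit.V_blocks(),
                          fit.residual_blocks()):
        Vi = np.linalg.inv(Vj)
        meat += Xj.T @ Vi @ np.outer(rj, rj) @ Vi @ Xj
    return M @ meat @ M


def _dense_cr2(fit, Phi_blocks):
    """Independent dense BRL oracle: explicit adjustment matrices."""
    M = fit.cov_gls
    meat = np.zeros((fit.p, fit.p))
    for Xj, Pj, rj in zip(fit.X_blocks, Phi_blocks, fit.residual_blocks()):
        ihalf = np.real(np.linalg.inv(sqrtm(Pj)))
        half = np.real(sqrtm(Pj))
        G = ihalf @ (Pj - Xj @ M @ Xj.T) @ ihalf
        A = half @ np.real(np.linalg.inv(sqrtm(G))) @ ihalf
        g = Xj.T @ np.linalg.inv(Pj) @ A @ rj
        meat += np.outer(g, g)
    return M @ meat @ M


class TestCr0:
    def test_zero_residuals_zero_matrix(self):
        df = pd.DataFrame({"cluster_id": [0, 0, 1, 1],
                           "y": [0.0, 1.0, 1.0, 2.0],
                           "x": [0.0, 1.0, 0.0, 1.0]})
        fit = fit_ols(ClusteredDataset(df), ModelSpec(kind="ols",
                                                      fixed=("1", "x")))
        # this design has nonzero residuals; force them to zero instead
        fit.y_blocks = [Xj @ fit.gamma for Xj in fit.X_blocks]
        assert np.allclose(cr0_cov(fit), 0.0)

    def test_singleton_clusters_hc0_of_mean(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(20)
        df = pd.DataFrame({"cluster_id": np.arange(20), "y": y})
        fit = fit_ols(ClusteredDataset(df), ModelSpec(kind="ols", fixed=("1",)))
        e = y - y.mean()
        assert cr0_cov(fit)[0, 0] == pytest.approx(np.sum(e ** 2) / 400)

    def test_matches_dense_oracle(self, rs_fit, ri_fit, ols_fit):
        for fit in (rs_fit, ri_fit, ols_fit):
            assert cr0_cov(fit) == pytest.approx(_dense_cr0(fit), abs=1e-12)


class TestCr1:
    def test_scaling(self, ols_fit):
        J = ols_fit.J
        assert cr1_cov(ols_fit) == pytest.approx(
            J / (J - 1) * cr0_cov(ols_fit), abs=1e-14)
        assert cr1_cov(ols_fit, factor="sqrt") == pytest.approx(
            np.sqrt(J / (J - 1)) * cr0_cov(ols_fit), abs=1e-14)

    def test_dominates_cr0_on_diagonal(self, rs_fit):
        d1 = np.diag(cr1_cov(rs_fit))
        d0 = np.diag(cr0_cov(rs_fit))
        assert np.all(d1 >= d0)

    def test_two_clusters_doubles(self):
        data = make_clustered(J=2, n=6, seed=3)
        fit = fit_ols(data, ModelSpec(kind="ols", fixed=("1", "x")))
        assert cr1_cov(fit) == pytest.approx(2.0 * cr0_cov(fit))

    def test_single_cluster_rejected(self):
        df = pd.DataFrame({"cluster_id": [0, 0, 0], "y": [1.0, 2.0, 3.0]})
        fit = fit_ols(ClusteredDataset(df), ModelSpec(kind="ols", fixed=("1",)))
        with pytest.raises(DesignError):
            cr1_cov(fit)


class TestCr2:
    def test_singleton_clusters_equal_hc2(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = rng.standard_normal(15)
        y = 1.0 + x + rng.standard_normal(15)
        df = pd.DataFrame({"cluster_id": np.arange(15), "y": y, "x": x})
        fit = fit_ols(ClusteredDataset(df), ModelSpec(kind="ols",
                                                      fixed=("1", "x")))
        hc2 = sm.OLS(y, sm.add_constant(x)).fit().cov_HC2
        assert cr2_cov(fit) == pytest.approx(hc2, abs=1e-12)

    def test_hand_algebra_four_points(self):
        # singleton clusters: adjusted residual e_i / sqrt(1 - h_i)
        df = pd.DataFrame({"cluster_id": np.arange(4),
                           "y": [0.0, 1.0, 1.0, 3.0],
                           "x": [0.0, 1.0, 2.0, 3.0]})
        fit = fit_ols(ClusteredDataset(df), ModelSpec(kind="ols",
                                                      fixed=("1", "x")))
        X = np.column_stack([np.ones(4), df["x"]])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        e = df["y"].to_numpy() - X @ fit.gamma
        tilde = e / np.sqrt(1.0 - np.diag(H))
        M = np.linalg.inv(X.T @ X)
        expect = M @ X.T @ np.diag(tilde ** 2) @ X @ M
        assert cr2_cov(fit) == pytest.approx(expect, abs=1e-12)

    def test_matches_dense_brl_oracle(self, rs_fit, ri_fit, ols_fit):
        for fit in (rs_fit, ri_fit):
            assert cr2_cov(fit) == pytest.approx(
                _dense_cr2(fit, fit.V_blocks()), abs=1e-10)
        Phi = [ols_fit.sigma2 * np.eye(len(y)) for y in ols_fit.y_blocks]
        assert cr2_cov(ols_fit) == pytest.approx(
            _dense_cr2(ols_fit, Phi), abs=1e-10)

    def test_unbiasedness_under_working_model(self):
        # defining BRL property: E[CR2] = true Var(mean) for iid errors
        J, n, R = 8, 4, 10_000
        rng = np.random.default_rng(7)
        ids = np.repeat(np.arange(J), n)
        spec = ModelSpec(kind="ols", fixed=("1",))
        est = np.empty(R)
        for r in range(R):
            y = rng.standard_normal(J * n)
            fit = fit_ols(ClusteredDataset(
                pd.DataFrame({"cluster_id": ids, "y": y}),
                validate=False), spec)
            est[r] = cr2_cov(fit)[0, 0]
        true_var = 1.0 / (J * n)
        assert est.mean() == pytest.approx(true_var, rel=0.02)

    def test_cluster_order_invariance(self, small_dataset):
        df = small_dataset.df
        perm = df.iloc[::-1].reset_index(drop=True)
        f1 = fit_lmm(small_dataset, ModelSpec(kind="ri"))
        f2 = fit_lmm(ClusteredDataset(perm), ModelSpec(kind="ri"))
        assert np.diag(cr2_cov(f1)) == pytest.approx(
            np.diag(cr2_cov(f2)), rel=1e-5)


class TestSatterthwaiteDf:
    def test_intercept_only_equal_clusters(self):
        J, n = 9, 5
        df = pd.DataFrame({"cluster_id": np.repeat(np.arange(J), n),
                           "y": np.random.default_rng(0).standard_normal(J * n)})
        fit = fit_ols(ClusteredDataset(df), ModelSpec(kind="ols", fixed=("1",)))
        assert satterthwaite_df(fit, 0) == pytest.approx(J - 1, abs=1e-8)

    def test_balanced_two_group_cluster_covariate(self):
        J, n = 10, 4
        g = np.repeat(np.repeat([0.0, 1.0], J // 2), n)
        df = pd.DataFrame({"cluster_id": np.repeat(np.arange(J), n),
                           "y": np.random.default_rng(1).standard_normal(J * n),
                           "g": g})
        fit = fit_ols(ClusteredDataset(df, validate=False),
                      ModelSpec(kind="ols", fixed=("1", "g")))
        assert satterthwaite_df(fit, 1) == pytest.approx(J - 2, abs=1e-8)

    def test_unbalanced_groups_lower_df(self):
        J, n = 10, 4
        rng = np.random.default_rng(2)
        y = rng.standard_normal(J * n)

        def df_for(split):
            g = np.repeat(np.concatenate([np.zeros(split),
                                          np.ones(J - split)]), n)
            df = pd.DataFrame({"cluster_id": np.repeat(np.arange(J), n),
                               "y": y, "g": g})
            fit = fit_ols(ClusteredDataset(df, validate=False),
                          ModelSpec(kind="ols", fixed=("1", "g")))
            return satterthwaite_df(fit, 1)

        assert df_for(2) < df_for(5)

    def test_df_is_outcome_free(self, rs_fit, small_dataset):
        base = [satterthwaite_df(rs_fit, i) for i in range(rs_fit.p)]
        permuted = rs_fit
        rng = np.random.default_rng(3)
        # replace outcomes, keep design and V-hat: df must not change
        permuted = fit_lmm(small_dataset, ModelSpec(kind="rs"))
        permuted.y_blocks = [rng.standard_normal(len(y))
                             for y in permuted.y_blocks]
        permuted._cr2_cache = None
        after = [satterthwaite_df(permuted, i) for i in range(permuted.p)]
        assert base == pytest.approx(after, abs=1e-10)

    def test_positive_on_simulation_fits(self, rs_fit, ri_fit, ols_fit):
        for fit in (rs_fit, ri_fit, ols_fit):
            for i in range(fit.p):
                df = satterthwaite_df(fit, i)
                assert np.isfinite(df) and 0 < df < fit.J


class TestLargeJCalibration:
    def test_cr2_type1_near_nominal_j200(self):
        # CR2 + Satterthwaite t test approaches the nominal level
        from mlmcorr import ConditionSpec, generate_dataset
        from mlmcorr.evaluation import rejection_rate
        from mlmcorr.robust_se import robust_inference

        cond = ConditionSpec(J=200, n_bar=5, icc=0.3, gamma01=0.0,
                             gamma10=0.0, balanced=False, vp_l1="VP1",
                             vp_l2="VP1")
        spec = ModelSpec(kind="ols")
        pvals = []
        for r in range(1500):
            fit = fit_ols(generate_dataset(cond, seed=(31, r)), spec)
            pvals.append(robust_inference(fit, "CR2", terms=[1])[0].p)
        assert rejection_rate(pvals) == pytest.approx(0.05, abs=0.0101)


class TestRobustInference:
    def test_table_shape_and_columns(self, rs_fit):
        table = coef_table(robust_inference(rs_fit, "CR2"))
        assert list(table.columns) == ["term", "estimate", "se", "df", "t",
                                       "p", "correction"]
        assert len(table) == 4
        assert (table["correction"] == "CR2").all()
        assert (table["se"] > 0).all()
        assert table["p"].between(0, 1).all()

    def test_t_is_estimate_over_se(self, ols_fit):
        for ci in robust_inference(ols_fit, "CR0"):
            assert ci.t == pytest.approx(ci.estimate / ci.se)

    def test_unknown_correction(self, ols_fit):
        with pytest.raises(ValueError):
            robust_inference(ols_fit, "CR9")
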