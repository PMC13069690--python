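import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichegrad import (
    ExpressionMatrix,
    InsufficientDataError,
    ValidationError,
    bh_adjust,
    build_spatial_design,
    fit_linear_models,
    natural_spline_basis,
    run_group_de,
    run_marker_de,
    run_spatial_de,
    squeeze_variances,
)


def expr_from_array(Y):
    Y = np.atleast_2d(np.asarray(Y, float))
    return ExpressionMatrix([f"g{i}" for i in range(Y.shape[0])],
                            [f"c{j}" for j in range(Y.shape[1])], np.clip(Y, 0, None))


class TestSplineBasis:
    def test_shape_and_natural_boundary_conditions(self):
        t = np.linspace(0, 1, 100)
        X = natural_spline_basis(t, 3)
        assert X.shape == (100, 3)
        h = t[1] - t[0]
        for col in X.T[1:]:  # cubic pieces; column 0 is t itself
            d2 = np.diff(col, 2) / h ** 2
            peak = np.abs(d2).max()
            # natural condition: curvature vanishes at both boundary knots
            assert abs(d2[0]) < 0.1 * peak
            assert abs(d2[-1]) < 0.1 * peak

    def test_df1_is_monotone_in_t(self, rng):
        t = np.sort(rng.uniform(0, 10, 50))
        X = natural_spline_basis(t, 1)
        assert X.shape == (50, 1)
        assert (np.diff(X[:, 0]) >= 0).all()

    def test_constant_covariate_error(self):
        with pytest.raises(InsufficientDataError):
            natural_spline_basis(np.ones(30), 3)


class TestSpatialDesign:
    @pytest.mark.parametrize("seed", range(5))
    def test_orthonormal_centered_aligned(self, seed):
        t = np.random.default_rng(seed).uniform(0, 1, 80)
        d = build_spatial_design(t, 3)
        Z = d.Z
        assert np.abs(Z.T @ Z - np.eye(3)).max() < 1e-8
        assert np.abs(Z.sum(axis=0)).max() < 1e-8
        assert np.corrcoef(Z[:, 0], t)[0, 1] > 0

    def test_span_matches_independent_orthogonalization(self, rng):
        t = np.linspace(0, 1, 50)
        d = build_spatial_design(t, 3)
        block = np.column_stack([t, natural_spline_basis(t, 3)])
        centered = block - block.mean(axis=0)
        U, s, _ = np.linalg.svd(centered, full_matrices=False)
        U = U[:, s > 1e-10 * s[0]]
        P1, P2 = d.Z @ d.Z.T, U @ U.T
        assert np.abs(P1 - P2).max() < 1e-8

    def test_rank_deficiency_error(self):
        # 4 distinct values repeated: enough distinct points for df=2 knots but
        # too few for a full-rank df=3 centered block after degeneracy
        t = np.repeat([0.0, 1.0, 2.0, 3.0, 4.0], 10)
        d = build_spatial_design(t, 3)  # still fine: 5 distinct values
        assert d.Z.shape == (50, 3)
        with pytest.raises(InsufficientDataError):
            build_spatial_design(np.repeat([0.0, 1.0], 25), 3)


class TestLinearFit:
    def test_exact_gene_recovered(self, rng):
        t = rng.uniform(0, 1, 60)
        d = build_spatial_design(t, 3)
        D = np.column_stack([np.ones(60), d.Z])
        y = 3.0 * d.Z[:, 0]
        fit = fit_linear_models(y[None, :], D)
        assert fit.coef[0, 1] == pytest.approx(3.0, abs=1e-10)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-18)
        assert fit.df_resid == 60 - 4

    def test_noise_gene_estimates(self, rng):
        n = 2000
        D = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(0, 2.0, size=(1, n))
        fit = fit_linear_models(y, D)
        assert abs(fit.coef[0, 1]) < 3 * 2.0 / np.sqrt(n)
        assert fit.sigma2[0] == pytest.approx(4.0, rel=0.2)

    def test_duplicate_column_rank_error(self):
        D = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValidationError, match="rank"):
            fit_linear_models(np.zeros((1, 10)), D)


class TestSqueeze:
    def test_identical_variances_pool_completely(self):
        s2 = np.full(50, 2.5)
        mod = squeeze_variances(s2, 10)
        assert np.isinf(mod.prior_df)
        np.testing.assert_allclose(mod.post_var, 2.5, rtol=1e-6)

    def test_prior_df_zero_is_classical(self, rng):
        s2 = rng.chisquare(5, 100)
        mod = squeeze_variances(s2, 10, prior_df=0)
        np.testing.assert_array_equal(mod.post_var, s2)
        assert mod.df_total == 10

    def test_posterior_between_prior_and_sample(self, rng):
        s2 = rng.chisquare(3, 500) / 3
        mod = squeeze_variances(s2, 8)
        if np.isfinite(mod.prior_df):
            lo = np.minimum(s2, mod.prior_var)
            hi = np.maximum(s2, mod.prior_var)
            assert ((mod.post_var >= lo - 1e-12) & (mod.post_var <= hi + 1e-12)).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_prior_parameter_recovery(self, seed):
        # true variances from a scaled inverse-chi2 with d0=4, s0^2=1; d=20
        rng = np.random.default_rng(seed)
        d0, s0, d, n_genes = 4.0, 1.0, 20, 1000
        sigma2 = d0 * s0 / rng.chisquare(d0, n_genes)
        s2 = sigma2 * rng.chisquare(d, n_genes) / d
        mod = squeeze_variances(s2, d)
        assert np.isfinite(mod.prior_df)
        assert abs(mod.prior_df - d0) <= 0.5 * d0
        assert abs(mod.prior_var - s0) <= 0.2 * s0

    def test_all_zero_variances_flagged(self):
        mod = squeeze_variances(np.zeros(10), 5)
        assert mod.degenerate and np.isinf(mod.prior_df) and mod.prior_var == 0


class TestBH:
    def brute_force_bh(self, p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, int(rng.integers(5, 200)))
            np.testing.assert_allclose(bh_adjust(p), self.brute_force_bh(p), rtol=1e-12)

    def test_adjusted_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()


class TestGroupDE:
    def test_moderated_t_with_zero_prior_equals_classical(self, rng):
        # two-group moderated t at d0=0 must equal the pooled two-sample t
        n = 40
        Y = np.clip(rng.normal(1.5, 0.5, size=(100, n)), 0, None)
        expr = expr_from_array(Y)
        cells = list(expr.cells)
        out = run_group_de(expr, cells[:20], cells[20:], prior_df=0).set_index("gene")
        t_ref, _ = stats.ttest_ind(Y[:, :20], Y[:, 20:], axis=1, equal_var=True)
        got = out.loc[[f"g{i}" for i in range(100)], "statistic"].to_numpy()
        np.testing.assert_allclose(got, t_ref, atol=1e-8)

    def test_planted_mean_shift_recovered(self, rng):
        n = 60
        Y = np.clip(rng.normal(1.0, 0.01, size=(20, n)), 0, None)
        Y[0, :30] += 2.0
        expr = expr_from_array(Y)
        cells = list(expr.cells)
        out = run_group_de(expr, cells[:30], cells[30:]).set_index("gene")
        assert out.loc["g0", "effect"] == pytest.approx(2.0, abs=0.02)
        assert out.loc["g0", "adj_p"] < 1e-10
        assert out.index[0] == "g0"

    def test_identical_groups_zero_effect(self, rng):
        half = np.clip(rng.normal(1, 0.3, size=(10, 25)), 0, None)
        Y = np.hstack([half, half])
        expr = expr_from_array(Y)
        cells = list(expr.cells)
        out = run_group_de(expr, cells[:25], cells[25:])
        np.testing.assert_allclose(out["effect"], 0.0, atol=1e-12)

    def test_null_simulation_fdr(self):
        rng = np.random.default_rng(1)
        Y = np.clip(rng.normal(1.0, 0.5, size=(1000, 200)), 0, None)
        expr = expr_from_array(Y)
        cells = list(expr.cells)
        out = run_group_de(expr, cells[:100], cells[100:])
        assert (out["adj_p"] < 0.05).mean() <= 0.05

    def test_min_pct_flags_undetected_genes(self, rng):
        Y = np.clip(rng.normal(1, 0.2, size=(5, 20)), 0, None)
        Y[2] = 0.0
        expr = expr_from_array(Y)
        cells = list(expr.cells)
        out = run_group_de(expr, cells[:10], cells[10:], min_pct=0.1).set_index("gene")
        assert not out.loc["g2", "tested"]
        assert np.isnan(out.loc["g2", "p"])

    def test_input_errors(self, rng):
        expr = expr_from_array(np.clip(rng.normal(1, 1, (3, 10)), 0, None))
        cells = list(expr.cells)
        with pytest.raises(ValidationError):
            run_group_de(expr, cells[:5], cells[4:])
        with pytest.raises(InsufficientDataError):
            run_group_de(expr, cells[:1], cells[5:])


class TestMarkerDE:
    def test_two_cluster_symmetry(self, rng):
        Y = np.clip(rng.normal(1, 0.4, size=(15, 40)), 0, None)
        expr = expr_from_array(Y)
        cells = pd.DataFrame({"x": np.arange(40.0), "y": 0.0,
                              "cell": list(expr.cells),
                              "cluster": ["a"] * 20 + ["b"] * 20})
        res = run_marker_de(expr, cells)
        a = res["a"].set_index("gene")["effect"]
        b = res["b"].set_index("gene")["effect"]
        np.testing.assert_allclose(a, -b[a.index], atol=1e-12)

    def test_planted_markers_rank_top(self):
        # three zones with five planted markers each: every marker must land
        # in its own cluster's top 10 by adjusted p
        from nichegrad import SyntheticTissueConfig, generate_tissue

        cfg = SyntheticTissueConfig(
            n_cells=450, layout="zones_1d", n_marker_genes=15,
            n_gradient_genes=0, n_null_genes=30, seed=21,
        )
        cells, expr, truth = generate_tissue(cfg)
        res = run_marker_de(expr, cells)
        markers = truth.gene_info.query("category == 'marker'")
        for _, row in markers.iterrows():
            top10 = list(res[row["target"]].head(10)["gene"])
            assert row["gene"] in top10

    def test_single_cluster_error(self, rng):
        expr = expr_from_array(np.clip(rng.normal(1, 1, (3, 10)), 0, None))
        cells = pd.DataFrame({"x": np.arange(10.0), "y": 0.0,
                              "cell": list(expr.cells), "cluster": "a"})
        with pytest.raises(InsufficientDataError):
            run_marker_de(expr, cells)


class TestSpatialDE:
    def _tissue(self, slope, seed=1, n=300):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, n)
        y = 2.0 + slope * t + rng.normal(0, 0.1, n)
        return expr_from_array(y), t

    def test_increasing_gene_positive_trend(self):
        expr, t = self._tissue(+2.0)
        out = run_spatial_de(expr, t)
        assert out.loc[0, "trend_sign"] == 1
        assert out.loc[0, "adj_p"] < 0.05

    def test_decreasing_gene_negative_trend(self):
        expr, t = self._tissue(-2.0)
        out = run_spatial_de(expr, t)
        assert out.loc[0, "trend_sign"] == -1
        assert out.loc[0, "adj_p"] < 0.05

    def test_flat_gene_small_effect(self, rng):
        t = rng.uniform(0, 1, 400)
        y = np.full(400, 2.0) + rng.normal(0, 0.3, 400)
        out = run_spatial_de(expr_from_array(y), t)
        assert abs(out.loc[0, "effect"]) < 3 * 0.3  # no systematic trend

    def test_affine_covariate_invariance(self, rng):
        Y = np.clip(rng.normal(1, 0.5, size=(30, 120)), 0, None)
        t = rng.uniform(0, 1, 120)
        expr = expr_from_array(Y)
        out1 = run_spatial_de(expr, t)
        out2 = run_spatial_de(expr, 7.5 * t + 3.0)
        for col in ("effect", "statistic", "p", "trend_sign"):
            np.testing.assert_allclose(out1[col], out2[col], rtol=1e-8, atol=1e-10)

    def test_weight_vector_alignment(self, small_tissue):
        from nichegrad import compute_centroid_weights

        cells, expr, _ = small_tissue
        shuffled = cells.sample(frac=1, random_state=0).reset_index(drop=True)
        w = compute_centroid_weights(shuffled, shuffled)
        out = run_spatial_de(expr, w)
        assert len(out) == expr.shape[0]
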