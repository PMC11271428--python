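import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from metstab.anova import joint_anova, variance_components
from metstab.blup import (
    blups_from_components,
    composite_score,
    fit_blups,
    hmgv,
    performance_stability_quadrants,
    waasb,
)
from metstab.data import cell_means, met_table_from_frame, validate_balance
from metstab.errors import DesignError, ValidationError
from metstab.simulate import SyntheticConfig, generate_met


def design_matrices(met, trait):
    """Plot-level fixed (env + block-within-env) and random (G, GxE) design."""
    df = met.subset_trait(trait)
    gens = pd.Categorical(df["genotype"], categories=sorted(df["genotype"].unique()))
    envs = pd.Categorical(df["environment"], categories=sorted(df["environment"].unique()))
    blocks = df["environment"].astype(str) + ":" + df["block"].astype(str)
    x = pd.get_dummies(blocks).to_numpy(dtype=float)  # cell means of env:block absorb env
    zg = pd.get_dummies(gens).to_numpy(dtype=float)
    ge = df["genotype"].astype(str) + ":" + df["environment"].astype(str)
    zge = pd.get_dummies(ge).to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    ge_labels = list(pd.get_dummies(ge).columns)
    g_labels = list(gens.categories)
    return y, x, zg, zge, g_labels, ge_labels


def reml_neg_loglik(params, y, x, zg, zge):
    sg, sge, se = np.exp(params)
    n = len(y)
    v = sg * zg @ zg.T + sge * zge @ zge.T + se * np.eye(n)
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.lstsq(xvx, x.T @ vi @ y, rcond=None)[0]
    r = y - x @ beta
    sign, logdet_v = np.linalg.slogdet(v)
    sign2, logdet_x = np.linalg.slogdet(xvx)
    return 0.5 * (logdet_v + logdet_x + r @ vi @ r)


def gls_blups(y, x, zg, zge, sg, sge, se):
    """Mixed-model BLUPs u = G Z' V^-1 (y - X beta_gls) — the matrix oracle."""
    n = len(y)
    v = sg * zg @ zg.T + sge * zge @ zge.T + se * np.eye(n)
    vi = np.linalg.inv(v)
    beta = np.linalg.lstsq(x.T @ vi @ x, x.T @ vi @ y, rcond=None)[0]
    r = y - x @ beta
    ug = sg * zg.T @ vi @ r
    uge = sge * zge.T @ vi @ r
    return ug, uge


@pytest.fixture(scope="module")
def small_trial():
    cfg = SyntheticConfig(
        n_genotypes=6, n_environments=4, n_blocks=2, grand_mean=30.0,
        var_g=8.0, var_ge=4.0, var_error=2.0, env_effect_sd=3.0,
        block_effect_sd=1.0, seed=17,
    )
    return generate_met(cfg)


class TestFitBlups:
    def test_no_noise_limit_recovers_cell_deviations(self, small_trial):
        cells = cell_means(small_trial, "FRY")
        anova = joint_anova(small_trial, "FRY")
        vc = variance_components(anova, 2, 4)
        vc_clean = type(vc)(vc.var_g, vc.var_ge, 1e-12, vc.var_g + vc.var_ge, "component_sum")
        res = blups_from_components(cells, vc_clean, 2)
        assert res.shrinkage_ge == pytest.approx(1.0, abs=1e-9)
        # without noise the prediction reproduces each cell's deviation from
        # its environment mean, on top of the grand mean
        np.testing.assert_allclose(
            res.genotypic_values,
            cells.grand_mean + cells.means - cells.environment_means[None, :],
            atol=1e-6,
        )

    def test_zero_genetic_variance_zero_blups(self, small_trial):
        cells = cell_means(small_trial, "FRY")
        anova = joint_anova(small_trial, "FRY")
        vc = variance_components(anova, 2, 4)
        vc0 = type(vc)(0.0, vc.var_ge, vc.var_e, vc.var_ge + vc.var_e, "component_sum")
        res = blups_from_components(cells, vc0, 2)
        np.testing.assert_allclose(res.genotype_blups, 0.0)

    def test_genotype_blups_sum_to_zero(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        assert res.genotype_blups.sum() == pytest.approx(0.0, abs=1e-9)

    def test_blups_shrink_toward_zero(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        cells = cell_means(small_trial, "FRY")
        fixed_g = cells.genotype_means - cells.grand_mean
        assert (np.abs(res.genotype_blups) <= np.abs(fixed_g) + 1e-12).all()
        assert 0 < res.shrinkage_g < 1 and 0 < res.shrinkage_ge < 1

    def test_closed_form_matches_gls_matrix_oracle(self, small_trial):
        """Closed-form shrinkage equals u = GZ'V^-1(y - X beta) at the same
        variance components."""
        res = fit_blups(small_trial, "FRY")
        y, x, zg, zge, g_labels, ge_labels = design_matrices(small_trial, "FRY")
        vc = res.components
        ug, uge = gls_blups(y, x, zg, zge, vc.var_g, vc.var_ge, vc.var_e)
        got_g = pd.Series(res.genotype_blups, index=list(res.genotypes)).loc[g_labels]
        np.testing.assert_allclose(got_g, ug, atol=1e-6)
        ge_frame = pd.DataFrame(res.ge_blups, index=list(res.genotypes), columns=list(res.environments))
        got_ge = np.array([ge_frame.loc[lab.split(":")[0], lab.split(":")[1]] for lab in ge_labels])
        np.testing.assert_allclose(got_ge, uge, atol=1e-6)

    def test_ems_components_agree_with_reml_optimum(self, small_trial):
        """On balanced data the EMS solution sits at the REML optimum."""
        anova = joint_anova(small_trial, "FRY")
        vc = variance_components(anova, 2, 4)
        y, x, zg, zge, *_ = design_matrices(small_trial, "FRY")
        x0 = np.log([vc.var_g, vc.var_ge, vc.var_e])
        opt = minimize(reml_neg_loglik, x0 + 0.3, args=(y, x, zg, zge), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        np.testing.assert_allclose(np.exp(opt.x), [vc.var_g, vc.var_ge, vc.var_e], rtol=1e-3)

    def test_unbalanced_rejected(self, small_trial):
        df = small_trial.frame.drop(index=0).reset_index(drop=True)
        with pytest.raises(DesignError):
            fit_blups(met_table_from_frame(df), "FRY")


class TestHMGV:
    def test_constant_genotypic_values(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        gv = np.full_like(res.genotypic_values, 25.0)
        res2 = type(res)(res.grand_mean, res.genotype_blups, res.ge_blups, gv,
                         res.components, res.shrinkage_g, res.shrinkage_ge,
                         res.genotypes, res.environments)
        out = hmgv(res2)
        np.testing.assert_allclose(out["hmgv"], 25.0)

    def test_hand_harmonic_mean(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        gv = res.genotypic_values.copy()
        gv[0, :] = 25.0
        gv[0, :2] = [20.0, 30.0]
        # 4 environments: harmonic mean of (20, 30, 25, 25)
        res2 = type(res)(res.grand_mean, res.genotype_blups, res.ge_blups, gv,
                         res.components, res.shrinkage_g, res.shrinkage_ge,
                         res.genotypes, res.environments)
        expected = 4 / (1 / 20 + 1 / 30 + 2 / 25)
        assert hmgv(res2)["hmgv"].iloc[0] == pytest.approx(expected)

    def test_am_hm_inequality(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        out = hmgv(res)
        row_means = res.genotypic_values.mean(axis=1)
        assert (out["hmgv"].to_numpy() <= row_means + 1e-10).all()

    def test_rank_one_is_largest(self, small_trial):
        out = hmgv(fit_blups(small_trial, "FRY"))
        assert out.loc[out["hmgv"].idxmax(), "rank"] == 1

    def test_nonpositive_value_rejected(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        gv = res.genotypic_values.copy()
        gv[1, 2] = -1.0
        res2 = type(res)(res.grand_mean, res.genotype_blups, res.ge_blups, gv,
                         res.components, res.shrinkage_g, res.shrinkage_ge,
                         res.genotypes, res.environments)
        with pytest.raises(ValidationError, match=res.environments[2]):
            hmgv(res2)

    def test_ordering_matches_means_without_interaction(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        ge0 = np.zeros_like(res.ge_blups)
        gv = res.grand_mean + res.genotype_blups[:, None] + ge0
        res2 = type(res)(res.grand_mean, res.genotype_blups, ge0, gv,
                         res.components, res.shrinkage_g, res.shrinkage_ge,
                         res.genotypes, res.environments)
        out = hmgv(res2)
        order_hmgv = out["hmgv"].rank(ascending=False)
        order_mean = pd.Series(res.genotype_blups, index=out.index).rank(ascending=False)
        pd.testing.assert_series_equal(order_hmgv, order_mean, check_names=False)


class TestWAASB:
    def test_rank1_interaction_reduces_to_first_axis(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        u = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        v = np.array([1.0, -1.0, 0.5, -0.5])
        ge1 = np.outer(u - u.mean(), v - v.mean())
        res2 = type(res)(res.grand_mean, res.genotype_blups, ge1,
                         res.genotypic_values, res.components,
                         res.shrinkage_g, res.shrinkage_ge, res.genotypes, res.environments)
        out = waasb(res2)
        uu, ss, _ = np.linalg.svd(ge1)
        expected = np.abs(uu[:, 0] * np.sqrt(ss[0]))
        np.testing.assert_allclose(out["waasb"], expected, atol=1e-10)

    def test_matches_direct_formula_from_independent_svd(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        out = waasb(res)
        u, s, _ = np.linalg.svd(res.ge_blups, full_matrices=False)
        k = min(res.ge_blups.shape) - 1
        ep = s[:k] ** 2 / (s[:k] ** 2).sum()
        scores = np.abs(u[:, :k] * np.sqrt(s[:k]))
        np.testing.assert_allclose(out["waasb"], scores @ ep, atol=1e-10)

    def test_invariant_to_environment_order_and_sign(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        out = waasb(res)
        perm = np.random.default_rng(0).permutation(res.ge_blups.shape[1])
        res_perm = type(res)(res.grand_mean, res.genotype_blups, res.ge_blups[:, perm],
                             res.genotypic_values, res.components, res.shrinkage_g,
                             res.shrinkage_ge, res.genotypes,
                             tuple(res.environments[j] for j in perm))
        np.testing.assert_allclose(waasb(res_perm)["waasb"], out["waasb"], atol=1e-10)

    def test_zero_interaction_warns(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        res0 = type(res)(res.grand_mean, res.genotype_blups, np.zeros_like(res.ge_blups),
                         res.genotypic_values, res.components, res.shrinkage_g,
                         res.shrinkage_ge, res.genotypes, res.environments)
        with pytest.warns(UserWarning, match="zero"):
            out = waasb(res0)
        np.testing.assert_allclose(out["waasb"], 0.0)


class TestQuadrants:
    def test_partition_property(self, small_trial):
        res = fit_blups(small_trial, "FRY")
        cells = cell_means(small_trial, "FRY")
        means = pd.Series(cells.genotype_means, index=list(cells.genotypes))
        groups = performance_stability_quadrants(waasb(res), means)
        assert set(groups.unique()) <= {1, 2, 3, 4}
        assert len(groups) == len(means)

    def test_group4_semantics(self):
        means = pd.Series({"A": 40.0, "B": 20.0, "C": 40.0, "D": 20.0})
        w = pd.DataFrame({"waasb": [0.1, 0.1, 5.0, 5.0]}, index=list("ABCD"))
        groups = performance_stability_quadrants(w, means)
        assert groups["A"] == 4 and groups["B"] == 3 and groups["C"] == 2 and groups["D"] == 1

    def test_composite_score_extremes(self):
        means = pd.Series({"A": 40.0, "B": 30.0, "C": 20.0})
        w = pd.Series({"A": 0.1, "B": 1.0, "C": 2.0})
        score = composite_score(means, w)
        assert score["A"] == 100.0 and score["C"] == 0.0
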