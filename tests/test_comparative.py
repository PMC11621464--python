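"""Comparative inference: tip values, BM rates, bootstrap, PGLS, disparity."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from tempoevo.comparative import (
    bootstrap_rate_comparison,
    disparity_comparison,
    fit_bm,
    pgls,
    sensitivity_pgls,
    species_tip_values,
    standardize_traits,
    sum_of_variances,
)
from tempoevo.phylo import Chronogram
from tempoevo.synth import (
    SyntheticStudyConfig,
    pure_birth_chronogram,
    simulate_bm_traits,
    simulate_metric_tables,
)


def _balanced_metrics(rng, n_species=4, n_colonies=3, n_rec=2,
                      colony_sd=0.0, resid_sd=0.3):
    rows = []
    for s in range(n_species):
        for c in range(n_colonies):
            b = rng.normal(0, colony_sd)
            for _ in range(n_rec):
                rows.append({"species": f"s{s}", "colony_id": f"s{s}c{c}",
                             "trait": 10.0 + 2 * s + b + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestTipValues:
    def test_no_colony_variance_gives_species_means(self):
        df = _balanced_metrics(np.random.default_rng(0), colony_sd=0.0)
        tips = species_tip_values(df, traits=["trait"])
        means = df.groupby("species")["trait"].mean()
        # balanced design: REML estimate equals the species mean
        np.testing.assert_allclose(tips["trait"].to_numpy(),
                                   means.to_numpy(), atol=1e-6)

    def test_single_colony_single_species_is_mean(self):
        df = pd.DataFrame({"species": "sp", "colony_id": "c1",
                           "trait": [1.0, 2.0, 6.0]})
        tips = species_tip_values(df, traits=["trait"])
        assert tips.loc["sp", "trait"] == pytest.approx(3.0)

    def test_matches_statsmodels_reml_oracle(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        rows = []
        for s in range(4):
            for c in range(3):
                b = rng.normal(0, 0.5)
                for _ in range(int(rng.integers(1, 4))):
                    rows.append({"species": f"s{s}", "colony_id": f"s{s}c{c}",
                                 "trait": 1.0 + s + b + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        tips = species_tip_values(df, traits=["trait"])
        fit = smf.mixedlm("trait ~ 0 + C(species)", df,
                          groups=df["colony_id"]).fit(reml=True)
        np.testing.assert_allclose(tips["trait"].to_numpy(),
                                   fit.fe_params.to_numpy(), atol=1e-4)

    def test_missing_species_trait_warns(self):
        df = pd.DataFrame({
            "species": ["a", "a", "b"], "colony_id": ["a1", "a2", "b1"],
            "x": [1.0, 2.0, 3.0], "y": [4.0, 5.0, np.nan]})
        with pytest.warns(UserWarning, match="'y'.*'b'"):
            tips = species_tip_values(df, traits=["x", "y"])
        assert np.isnan(tips.loc["b", "y"])
        assert tips.loc["b", "x"] == 3.0


class TestStandardize:
    def test_divide_by_mean(self):
        t = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        np.testing.assert_allclose(standardize_traits(t)["x"], [0.5, 1.0, 1.5])

    def test_constant_column_and_idempotence(self):
        t = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        out = standardize_traits(t)
        np.testing.assert_allclose(out["x"], 1.0)
        np.testing.assert_allclose(standardize_traits(out)["x"], out["x"])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            standardize_traits(pd.DataFrame({"x": [-1.0, 1.0]}))


class TestFitBM:
    def test_two_tip_closed_form(self):
        tree = Chronogram.from_newick("(A:1.5,B:1.5);")
        fit = fit_bm(tree, {"A": 2.0, "B": 5.0})
        assert fit.sigma2 == pytest.approx((2.0 - 5.0) ** 2 / (4 * 1.5),
                                           abs=1e-12)

    def test_equal_tips_zero_rate(self, six_tip_tree):
        fit = fit_bm(six_tip_tree, {s: 1.7 for s in six_tip_tree.taxa})
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-15)

    def test_branch_scaling_law(self, six_tip_tree):
        tips = simulate_bm_traits(six_tip_tree, 1.0, seed=2)
        s1 = fit_bm(six_tip_tree, tips).sigma2
        s3 = fit_bm(six_tip_tree.scale(3.0), tips).sigma2
        assert s3 == pytest.approx(s1 / 3.0, rel=1e-12)

    def test_affine_equivariance(self, six_tip_tree):
        tips = simulate_bm_traits(six_tip_tree, 1.0, seed=4)
        base = fit_bm(six_tip_tree, tips)
        moved = fit_bm(six_tip_tree, {k: 2.0 * v + 5.0 for k, v in tips.items()})
        assert moved.sigma2 == pytest.approx(4.0 * base.sigma2, rel=1e-10)
        assert moved.root_state == pytest.approx(2.0 * base.root_state + 5.0,
                                                 rel=1e-10)

    def test_duplicate_zero_length_tips_rejected(self):
        tree = Chronogram.from_newick("((A:0.0,B:0.0):1.0,C:1.0);")
        with pytest.raises(ValueError, match="singular"):
            fit_bm(tree, {"A": 1.0, "B": 2.0, "C": 3.0})


class TestPGLS:
    def test_star_tree_equals_ols(self, star_tree):
        rng = np.random.default_rng(0)
        taxa = star_tree.taxa
        x = dict(zip(taxa, rng.normal(size=len(taxa))))
        y = {k: 1.5 * v + rng.normal(0, 0.2) for k, v in x.items()}
        fit = pgls(star_tree, x, y)
        res = st.linregress([x[t] for t in taxa], [y[t] for t in taxa])
        assert fit.slope == pytest.approx(res.slope, abs=1e-8)
        assert fit.intercept == pytest.approx(res.intercept, abs=1e-8)
        assert fit.t_statistic == pytest.approx(res.slope / res.stderr, abs=1e-8)

    def test_exact_linear_relation(self, six_tip_tree):
        x = dict(zip(six_tip_tree.taxa, [0.0, 1, 2, 3, 4, 5.0]))
        y = {k: 2.0 * v + 1.0 for k, v in x.items()}
        fit = pgls(six_tip_tree, x, y)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_matches_statsmodels_gls_oracle(self):
        import statsmodels.api as sm

        tree = pure_birth_chronogram(8, seed=11)
        rng = np.random.default_rng(3)
        taxa = tree.taxa
        xv = rng.normal(size=8)
        yv = 0.5 * xv + rng.normal(size=8)
        fit = pgls(tree, dict(zip(taxa, xv)), dict(zip(taxa, yv)))
        C, _ = tree.vcv(order=taxa)
        gls = sm.GLS(yv, sm.add_constant(xv), sigma=C).fit()
        assert fit.slope == pytest.approx(gls.params[1], abs=1e-10)
        assert fit.t_statistic == pytest.approx(gls.tvalues[1], abs=1e-8)
        assert fit.p_value == pytest.approx(gls.pvalues[1], abs=1e-8)

    def test_t_invariant_to_affine_y(self, six_tip_tree):
        rng = np.random.default_rng(9)
        x = dict(zip(six_tip_tree.taxa, rng.normal(size=6)))
        y = dict(zip(six_tip_tree.taxa, rng.normal(size=6)))
        t1 = pgls(six_tip_tree, x, y).t_statistic
        y2 = {k: 7.0 * v - 3.0 for k, v in y.items()}
        t2 = pgls(six_tip_tree, x, y2).t_statistic
        assert t2 == pytest.approx(t1, rel=1e-9)

    def test_constant_x_rejected(self, six_tip_tree):
        x = {s: 1.0 for s in six_tip_tree.taxa}
        y = dict(zip(six_tip_tree.taxa, np.arange(6.0)))
        with pytest.raises(ValueError, match="singular"):
            pgls(six_tip_tree, x, y)


class TestSensitivityPGLS:
    def test_zero_sd_reproduces_plain_pgls(self, six_tip_tree):
        rng = np.random.default_rng(1)
        x = dict(zip(six_tip_tree.taxa, rng.normal(size=6)))
        y = dict(zip(six_tip_tree.taxa, rng.normal(size=6)))
        zeros = {s: 0.0 for s in six_tip_tree.taxa}
        res = sensitivity_pgls(six_tip_tree, x, y, zeros, zeros,
                               n_iter=50, seed=0)
        base = pgls(six_tip_tree, x, y)
        np.testing.assert_allclose(res.p_values, base.p_value, atol=1e-12)
        np.testing.assert_allclose(res.slopes, base.slope, atol=1e-12)

    def test_null_relationship_median_p_moderate(self):
        tree = pure_birth_chronogram(12, seed=21)
        in_band = 0
        for master in range(10):
            rng = np.random.default_rng(100 + master)
            x = dict(zip(tree.taxa, rng.normal(size=12)))
            y = dict(zip(tree.taxa, rng.normal(size=12)))
            sds = {s: 0.3 for s in tree.taxa}
            res = sensitivity_pgls(tree, x, y, sds, sds, n_iter=200,
                                   seed=master)
            in_band += 0.2 <= res.median_p <= 0.8
        assert in_band >= 7

    def test_strong_slope_detected(self):
        tree = pure_birth_chronogram(12, seed=22)
        hits = 0
        for master in range(20):
            tips_x = simulate_bm_traits(tree, 1.0, seed=500 + master)
            y = {k: 2.0 * v for k, v in tips_x.items()}
            sds = {s: 0.05 for s in tree.taxa}
            res = sensitivity_pgls(tree, tips_x, y, sds, sds, n_iter=200,
                                   seed=master)
            hits += res.median_p < 0.05
        assert hits >= 18


class TestDisparity:
    def test_sum_of_variances_direct_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 2))
        total = 0.0
        for j in range(2):  # hand-rolled per-axis variance
            col = pts[:, j]
            m = sum(col) / 5
            total += sum((v - m) ** 2 for v in col) / 4
        assert sum_of_variances(pts) == pytest.approx(total, abs=1e-12)

    def test_degenerate_cloud_zero_disparity(self):
        same = np.ones((5, 2))
        other = np.random.default_rng(0).normal(size=(5, 2))
        res = disparity_comparison(same, other, n_boot=200, seed=1)
        assert res.sum_of_variances_colony == pytest.approx(0.0, abs=1e-12)

    def test_identical_clouds_symmetric_p(self):
        pts = np.random.default_rng(3).normal(size=(12, 2))
        res = disparity_comparison(pts, pts.copy(), n_boot=2000, seed=4)
        assert 0.4 <= res.p_value <= 0.6

    def test_too_few_species(self):
        pts = np.ones((2, 2))
        with pytest.raises(ValueError, match="3 species"):
            disparity_comparison(pts, pts, n_boot=100, seed=0)


class TestBootstrapRateComparison:
    @staticmethod
    def _tables(seed=0, **kw):
        cfg = SyntheticStudyConfig(
            n_species=10, colonies_per_species=4, recordings_per_colony=1,
            individuals_per_species=4, intraspecific_sd=0.15, seed=seed, **kw)
        return simulate_metric_tables(cfg)

    def test_identical_tables_give_p_one(self):
        colony, _, tree, _ = self._tables()
        indiv = colony.rename(columns={}).copy()
        indiv["individual_id"] = indiv["colony_id"]
        res = bootstrap_rate_comparison(colony, indiv, tree,
                                        "rhythmicity_beta", n_boot=200, seed=1)
        assert res.observed_difference == 0.0
        assert res.p_value == 1.0

    def test_minimum_p_is_floor(self):
        # colony spread vastly exceeds individual spread: no replicate
        # difference can fall at or below zero
        colony, indiv, tree, _ = self._tables(
            interspecific_sd_colony=(2.0, 0.0),
            interspecific_sd_individual=(0.0, 0.0))
        res = bootstrap_rate_comparison(colony, indiv, tree,
                                        "rhythmicity_beta", n_boot=10_000,
                                        seed=2)
        assert res.p_value == pytest.approx(1e-4)

    def test_five_to_one_sd_ratio_detected(self):
        hits = 0
        for seed in range(20):
            colony, indiv, tree, _ = self._tables(
                seed=seed,
                interspecific_sd_colony=(0.75, 0.3),
                interspecific_sd_individual=(0.15, 0.3))
            res = bootstrap_rate_comparison(colony, indiv, tree,
                                            "rhythmicity_beta",
                                            n_boot=500, seed=seed)
            hits += res.p_value < 0.05
        assert hits >= 18

    def test_species_mismatch_rejected(self):
        colony, indiv, tree, _ = self._tables()
        with pytest.raises(ValueError, match="same species"):
            bootstrap_rate_comparison(colony, indiv[indiv["species"] != "sp01"],
                                      tree, "rhythmicity_beta",
                                      n_boot=100, seed=0)

    def test_seed_determinism(self):
        colony, indiv, tree, _ = self._tables()
        a = bootstrap_rate_comparison(colony, indiv, tree,
                                      "dominant_period_min", n_boot=150, seed=9)
        b = bootstrap_rate_comparison(colony, indiv, tree,
                                      "dominant_period_min", n_boot=150, seed=9)
        np.testing.assert_array_equal(a.sigma2_colony_draws,
                                      b.sigma2_colony_draws)
        assert a.p_value == b.p_value
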