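import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from urbanbees.core import CommunityTable, build_community_table, filter_taxa
from urbanbees.synthetic import generate_dataset, scenario
from urbanbees.traits import (
    expand_occurrence,
    fdr_adjust,
    fit_trait_glmm,
    trait_occurrence_curves,
)


@pytest.fixture(scope="module")
def small_fit():
    """One converged GLMM fit on a small synthetic survey (shared)."""
    cfg = scenario(
        "filter_paper_like", seed=5, n_sites=80, pool_size=40,
        interaction_effects={"nesting": 0.8, "diet": 0.0, "sociality": 0.0, "size": 0.0},
    )
    rec, sites, traits = generate_dataset(cfg)
    rec = filter_taxa(rec, traits, drop_honeybee=True, drop_parasitic=True)
    table = build_community_table(rec, sites)
    occ = expand_occurrence(table, traits, sites)
    return fit_trait_glmm(occ, metric="impervious_pct", seed=0), occ


class TestExpandOccurrence:
    def _inputs(self):
        table = CommunityTable(
            ("s1", "s2"), ("sp1", "sp2", "sp3"),
            np.array([[2, 0, 0], [0, 0, 1]]),
        )
        traits = pd.DataFrame(
            {
                "species": ["sp1", "sp2", "sp3"],
                "nesting": ["above", "below", "no_information"],
                "sociality": ["social", "solitary", "no_information"],
                "diet": ["generalist", "specialist", "no_information"],
                "size": ["small", "large", "no_information"],
                "itd_mm": [1.0, 3.0, np.nan],
                "parasitic": [False, False, False],
            }
        )
        sites = pd.DataFrame(
            {
                "site_id": ["s1", "s2"],
                "pop_density": [10.0, 5000.0],
                "impervious_pct": [5.0, 90.0],
                "region": ["Atlantic", "Continental"],
                "sampling_category": ["C0", "C1"],
            }
        )
        return table, traits, sites

    def test_full_cross_documented_order(self):
        table, traits, sites = self._inputs()
        occ = expand_occurrence(table, traits, sites)
        assert len(occ) == 6
        assert occ["occurrence"].tolist() == [1, 0, 0, 0, 0, 1]
        assert occ["site_id"].tolist() == ["s1"] * 3 + ["s2"] * 3
        assert occ["species"].tolist() == ["sp1", "sp2", "sp3"] * 2

    def test_parasitic_and_honeybee_excluded_from_pool(self):
        table, traits, sites = self._inputs()
        table = CommunityTable(
            ("s1", "s2"), ("Apis mellifera", "sp1", "sp2", "sp3"),
            np.array([[5, 2, 0, 0], [1, 0, 0, 1]]),
        )
        traits.loc[1, "parasitic"] = True  # sp2
        occ = expand_occurrence(table, traits, sites)
        assert set(occ["species"]) == {"sp1", "sp3"}
        assert len(occ) == 4

    def test_species_with_all_traits_missing_retained(self):
        table, traits, sites = self._inputs()
        occ = expand_occurrence(table, traits.iloc[:2], sites)  # sp3 has no row
        sp3 = occ[occ["species"] == "sp3"]
        assert len(sp3) == 2
        assert (sp3[["nesting", "sociality", "diet", "size"]] == "no_information").all().all()

    def test_occurrence_conservation(self, tiny_dataset):
        records, sites, traits = tiny_dataset
        rec = filter_taxa(records, traits, drop_honeybee=True, drop_parasitic=True)
        table = build_community_table(rec, sites)
        occ = expand_occurrence(table, traits, sites)
        assert occ["occurrence"].sum() == int((table.incidence >= 1).sum())

    def test_row_count_is_pool_times_sites(self, tiny_dataset):
        records, sites, traits = tiny_dataset
        rec = filter_taxa(records, traits, drop_honeybee=True, drop_parasitic=True)
        table = build_community_table(rec, sites)
        occ = expand_occurrence(table, traits, sites)
        pool = occ["species"].nunique()
        assert len(occ) == pool * table.n_sites


class TestFdrAdjust:
    def test_step_up_worked_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_monotone_order_preserving(self, rng):
        # step-up adjustment never lowers a p-value and preserves order;
        # note it is NOT a fixed point (re-adjusting adjusted values
        # inflates them again), so idempotence is not asserted
        p = rng.random(25)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (fdr_adjust(adj) >= adj - 1e-15).all()

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(fdr_adjust(p), expected, rtol=1e-12)


class TestFitTraitGlmm:
    def test_zero_variances_match_plain_logistic(self, small_fit):
        _, occ = small_fit
        from urbanbees.traits import _trait_design
        from urbanbees._glmm import CrossedLogisticGLMM

        occ = occ.sort_values(["site_id", "species"], kind="mergesort").reset_index(drop=True)
        x_mat, names, _, _ = _trait_design(occ, "impervious_pct")
        n_s = occ["site_id"].nunique()
        n_k = occ["species"].nunique()
        y = occ["occurrence"].to_numpy(float).reshape(n_s, n_k)
        cat = pd.Categorical(occ.groupby("site_id", sort=True)["sampling_category"].first()).codes
        fit0 = CrossedLogisticGLMM(y, x_mat, cat).fit(
            fix_variances={"site": 0.0, "category": 0.0, "species": 0.0}
        )
        glm = sm.GLM(y.ravel(), x_mat, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit0.beta, glm.params, atol=1e-4)

    def test_mixed_loglik_dominates_zero_variance_loglik(self, small_fit):
        fit, occ = small_fit
        from urbanbees.traits import _trait_design
        from urbanbees._glmm import CrossedLogisticGLMM

        occ = occ.sort_values(["site_id", "species"], kind="mergesort").reset_index(drop=True)
        x_mat, _, _, _ = _trait_design(occ, "impervious_pct")
        n_s, n_k = occ["site_id"].nunique(), occ["species"].nunique()
        y = occ["occurrence"].to_numpy(float).reshape(n_s, n_k)
        cat = pd.Categorical(occ.groupby("site_id", sort=True)["sampling_category"].first()).codes
        fit0 = CrossedLogisticGLMM(y, x_mat, cat).fit(
            fix_variances={"site": 0.0, "category": 0.0, "species": 0.0}
        )
        assert fit.loglik >= fit0.loglik - 1e-6

    def test_strong_interaction_recovered(self, small_fit):
        fit, _ = small_fit
        assert fit.converged
        row = fit.coefficient("impervious_pct:nesting[above]")
        assert row["estimate"] > 0
        assert row["p_adj"] < 0.05

    def test_reference_modalities_and_coefficient_scheme(self, small_fit):
        fit, _ = small_fit
        assert fit.reference_modalities == {
            "nesting": "below", "diet": "generalist",
            "sociality": "social", "size": "small",
        }
        terms = set(fit.coef["term"])
        for t, contrast in [("nesting", "above"), ("diet", "specialist"),
                            ("sociality", "solitary"), ("size", "large")]:
            assert f"{t}[{contrast}]" in terms
            assert f"impervious_pct:{t}[{contrast}]" in terms
        # adjusted p exists exactly for the 8 informative trait tests
        assert fit.coef["p_adj"].notna().sum() == 8
        adj = fit.coef.dropna(subset=["p_adj"])
        assert (adj["p_adj"] >= adj["p"] - 1e-15).all()

    def test_region_lrt_present(self, small_fit):
        fit, _ = small_fit
        rec = fit.lrt_for("region")
        assert rec.df == len([t for t in fit.coef["term"] if t.startswith("region[")])
        assert rec.chi2 >= 0

    def test_all_zero_species_still_converges(self, small_fit):
        _, occ = small_fit
        occ = occ.copy()
        sp = occ["species"].iloc[0]
        occ.loc[occ["species"] == sp, "occurrence"] = 0
        # guard against an emptied site is not needed: other species remain
        fit = fit_trait_glmm(occ, metric="impervious_pct", seed=0, region_lrt=False)
        assert fit.converged
        assert np.isfinite(fit.loglik)

    def test_incomplete_cross_rejected(self, small_fit):
        _, occ = small_fit
        with pytest.raises(ValueError, match="complete"):
            fit_trait_glmm(occ.iloc[:-1], metric="impervious_pct")

    def test_unknown_metric_rejected(self, small_fit):
        _, occ = small_fit
        with pytest.raises(ValueError):
            fit_trait_glmm(occ, metric="altitude")


class TestOccurrenceCurves:
    def test_reference_prediction_at_zero_is_inverse_logit_intercept(self, small_fit):
        fit, _ = small_fit
        curves = trait_occurrence_curves(fit, [0.0])
        ref = curves[curves["curve"] == "reference"].iloc[0]
        intercept = fit.coefficient("(Intercept)")["estimate"]
        assert ref["probability"] == pytest.approx(1 / (1 + np.exp(-intercept)))

    def test_zero_coefficient_modality_leaves_curve_unchanged(self, small_fit):
        fit, _ = small_fit
        fit2 = fit.__class__(**{**fit.__dict__})
        coef = fit.coef.copy()
        coef.loc[coef["term"].isin(["size[large]", "impervious_pct:size[large]"]), "estimate"] = 0.0
        fit2.coef = coef
        curves = trait_occurrence_curves(fit2, np.linspace(-2, 2, 5))
        ref = curves[curves["curve"] == "reference"]["probability"].to_numpy()
        switched = curves[curves["curve"] == "size=large"]["probability"].to_numpy()
        np.testing.assert_allclose(ref, switched)

    def test_positive_interaction_gives_increasing_odds_ratio(self, small_fit):
        fit, _ = small_fit
        grid = np.linspace(-2, 2, 9)
        curves = trait_occurrence_curves(fit, grid)
        ref = curves[curves["curve"] == "reference"]["probability"].to_numpy()
        above = curves[curves["curve"] == "nesting=above"]["probability"].to_numpy()
        odds_ratio = (above / (1 - above)) / (ref / (1 - ref))
        assert (np.diff(odds_ratio) > 0).all()

    def test_bands_bracket_point_estimate(self, small_fit):
        fit, _ = small_fit
        curves = trait_occurrence_curves(fit, np.linspace(-1, 1, 3))
        assert (curves["lower"] <= curves["probability"] + 1e-12).all()
        assert (curves["upper"] >= curves["probability"] - 1e-12).all()
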