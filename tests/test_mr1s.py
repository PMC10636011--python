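"""One-sample MR: allele scores, two-stage fits, strata, sex-specific selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fallmr import mr1s, synthdata
from fallmr.synthdata import SimConfig


class TestAlleleScore:
    def test_unit_weights_sum_dosages(self):
        dos = np.array([[0, 1, 2], [2, 2, 2], [1, 0, 0]], dtype=float)
        score = mr1s.build_allele_score(dos, np.ones(3))
        assert np.array_equal(score, [3, 6, 1])

    def test_zero_weights_zero_scores(self):
        dos = np.random.default_rng(0).integers(0, 3, (10, 4)).astype(float)
        assert np.array_equal(mr1s.build_allele_score(dos, np.zeros(4)), np.zeros(10))

    def test_recoding_with_negated_weight_preserves_centred_score(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (50, 5)).astype(float)
        w = rng.normal(size=5)
        a = mr1s.build_allele_score(dos, w)
        dos2 = dos.copy()
        dos2[:, 2] = 2 - dos2[:, 2]
        w2 = w.copy()
        w2[2] = -w2[2]
        b = mr1s.build_allele_score(dos2, w2)
        assert np.allclose(a - a.mean(), b - b.mean())

    def test_missing_dosages_imputed_to_twice_eaf(self):
        dos = np.array([[0.0, np.nan], [2.0, 1.0]])
        score = mr1s.build_allele_score(dos, np.ones(2), eaf=np.array([0.5, 0.25]))
        assert score[0] == pytest.approx(0.0 + 0.5)

    def test_empty_weights_rejected(self):
        with pytest.raises(ValueError):
            mr1s.build_allele_score(np.zeros((5, 0)), np.array([]))


class TestTSLS:
    def test_perfect_instrument_equals_ols(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = 0.4 * x + rng.standard_normal(500)
        iv = mr1s.tsls(x, x, y, second_stage_family="linear")
        import statsmodels.api as sm

        ols = sm.OLS(y, np.column_stack([np.ones(500), x])).fit()
        assert iv.beta == pytest.approx(ols.params.iloc[1] if hasattr(ols.params, 'iloc') else ols.params[1], abs=1e-10)

    def test_equals_wald_ratio_single_instrument(self):
        rng = np.random.default_rng(3)
        n = 2000
        g = rng.integers(0, 3, n).astype(float)
        u = rng.standard_normal(n)
        x = 0.3 * g + 0.5 * u + rng.standard_normal(n)
        y = 0.25 * x + 0.5 * u + rng.standard_normal(n)
        iv = mr1s.tsls(g, x, y, second_stage_family="linear")
        import statsmodels.api as sm

        X = np.column_stack([np.ones(n), g])
        wald = sm.OLS(y, X).fit().params[1] / sm.OLS(x, X).fit().params[1]
        assert iv.beta == pytest.approx(wald, abs=1e-8)

    def test_defeats_confounding_where_ols_fails(self):
        cfg = SimConfig(n_individuals=12_000, n_variants=80, exposure_h2=0.25, seed=4,
                        confounder_effect_x=0.6, confounder_effect_y=0.8,
                        true_causal_effect=0.3)
        cohort = synthdata.simulate_traits(synthdata.simulate_genotypes(cfg), cfg)
        rng = np.random.default_rng(5)
        x = cohort.data["exposure"].to_numpy()
        y = 0.3 * x + 0.8 * cohort.data["confounder"].to_numpy() + rng.standard_normal(len(x))
        score = mr1s.build_allele_score(cohort.dosages, cohort.truth["variant_effects"])
        iv = mr1s.tsls(score, x, y, second_stage_family="linear")
        import statsmodels.api as sm

        ols = sm.OLS(y, np.column_stack([np.ones(len(x)), x])).fit()
        assert abs(iv.beta - 0.3) < 3 * iv.se
        assert abs(ols.params.iloc[1] if hasattr(ols.params, 'iloc') else ols.params[1] - 0.3) > 3 * ols.bse[1]
        assert iv.first_stage_F > 30

    def test_poisson_second_stage_more_precise_than_logistic(self):
        # the count outcome retains information the dichotomy discards; the
        # two families estimate on different scales (log-OR vs log-rate), so
        # precision is compared as CI width relative to the point estimate
        ratios = []
        for rep in range(5):
            cfg = SimConfig(n_individuals=5000, n_variants=50, exposure_h2=0.3,
                            true_causal_effect=0.4, count_mean_extra=1.5, seed=600 + rep)
            cohort = synthdata.simulate_traits(synthdata.simulate_genotypes(cfg), cfg)
            score = mr1s.build_allele_score(cohort.dosages, cohort.truth["variant_effects"])
            x = cohort.data["exposure"].to_numpy()
            logi = mr1s.tsls(score, x, (cohort.data["fall_status"] == "case").astype(int).to_numpy(),
                             second_stage_family="logistic")
            pois = mr1s.tsls(score, x, cohort.data["fall_count"].to_numpy(),
                             second_stage_family="poisson")
            ratios.append((pois.se / abs(pois.beta)) / (logi.se / abs(logi.beta)))
        assert np.mean(ratios) < 1.0

    def test_weak_instrument_flagged(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(300)
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        res = mr1s.tsls(z, x, y, second_stage_family="linear")
        assert res.flag == "weak_instrument" or res.first_stage_F >= 1

    def test_orthogonal_covariate_barely_moves_estimate(self):
        rng = np.random.default_rng(7)
        n = 20_000
        g = rng.integers(0, 3, n).astype(float)
        x = 0.4 * g + rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n)
        noise_cov = pd.DataFrame({"c": rng.standard_normal(n)})
        a = mr1s.tsls(g, x, y, second_stage_family="linear")
        b = mr1s.tsls(g, x, y, covariates=noise_cov, second_stage_family="linear")
        assert a.beta == pytest.approx(b.beta, abs=5 * a.se / np.sqrt(n) * 10)

    def test_family_outcome_mismatch_rejected(self):
        x = np.random.default_rng(8).standard_normal(50)
        with pytest.raises(ValueError):
            mr1s.tsls(x, x, x, second_stage_family="logistic")


@pytest.fixture(scope="module")
def stratified_fit():
    cfg = SimConfig(n_individuals=10_000, n_variants=80, exposure_h2=0.3, seed=9,
                    true_causal_effect=0.4, exposure_active_stratum="ever")
    cohort = synthdata.simulate_traits(synthdata.simulate_genotypes(cfg), cfg)
    rng = np.random.default_rng(10)
    df = cohort.data.copy()
    df["score"] = mr1s.build_allele_score(cohort.dosages, cohort.truth["variant_effects"])
    df["y"] = 0.4 * df["exposure"] + rng.standard_normal(len(df))
    return mr1s.stratified_mr(df, "drinker", "score", "exposure", "y",
                              second_stage_family="linear")


class TestStratifiedMR:

    def test_never_stratum_is_null(self, stratified_fit):
        never = stratified_fit["strata"]["never"]
        assert abs(never.beta) < 3 * max(never.se, 0.05) or never.flag == "weak_instrument"

    def test_ever_stratum_recovers_design_effect(self, stratified_fit):
        ever = stratified_fit["strata"]["ever"]
        assert abs(ever.beta - 0.4) < 3 * ever.se
        assert ever.first_stage_F > 30

    def test_stratum_sizes_partition_cohort(self, stratified_fit):
        assert sum(r.n for r in stratified_fit["strata"].values()) == 10_000

    def test_single_stratum_rejected(self):
        df = pd.DataFrame({"s": ["a"] * 100, "z": np.ones(100), "x": np.ones(100), "y": np.ones(100)})
        with pytest.raises(ValueError):
            mr1s.stratified_mr(df, "s", "z", "x", "y")


class TestSexSpecificSelection:
    def sex_tables(self, m, seed, beta_m=None, beta_f=None, se=0.01):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 0.05, m)
        bm = base if beta_m is None else beta_m
        bf = base if beta_f is None else beta_f
        ids = [f"rs{i}" for i in range(m)]
        male = pd.DataFrame({"variant_id": ids, "beta": bm + rng.normal(0, se, m), "se": se})
        female = pd.DataFrame({"variant_id": ids, "beta": bf + rng.normal(0, se, m), "se": se})
        return male, female

    def test_null_interaction_selects_alpha_fraction(self):
        male, female = self.sex_tables(2000, seed=11)
        sel = mr1s.select_sex_specific_instruments(male, female, interaction_alpha=0.05)
        z = (male["beta"] - female["beta"]) / (np.sqrt(2) * 0.01)
        frac = (sel.interaction_p < 0.05).mean()
        assert abs(frac - 0.05) < 0.02
        assert 0.9 < z.std() < 1.1  # interaction z is standard normal under the null

    def test_planted_interactions_found_with_high_sensitivity(self):
        m = 400
        rng = np.random.default_rng(12)
        base = rng.normal(0, 0.05, m)
        bm, bf = base.copy(), base.copy()
        planted = np.arange(40)
        bm[planted] = 0.20
        bf[planted] = 0.10
        male, female = self.sex_tables(m, seed=13, beta_m=bm, beta_f=bf, se=0.01)
        sel = mr1s.select_sex_specific_instruments(male, female, interaction_alpha=1e-5)
        chosen = set(sel.male_set["variant_id"]) | set(sel.female_set["variant_id"])
        expected = {f"rs{i}" for i in planted}
        sensitivity = len(chosen & expected) / len(expected)
        specificity = 1 - len(chosen - expected) / (m - len(expected))
        assert sensitivity > 0.95 and specificity > 0.95
        assert set(sel.male_set["variant_id"]) <= expected  # stronger in males

    def test_f_threshold_boundary_strict(self):
        male = pd.DataFrame({"variant_id": ["v1"], "beta": [np.sqrt(14.9) * 0.01], "se": [0.01]})
        female = pd.DataFrame({"variant_id": ["v1"], "beta": [0.0], "se": [0.01]})
        with pytest.warns(UserWarning, match="no variant passed"):
            sel = mr1s.select_sex_specific_instruments(male, female, interaction_alpha=0.5, f_min=15)
        assert sel.male_set.empty and sel.female_set.empty
        above = male.assign(beta=[np.sqrt(15.1) * 0.01])
        sel2 = mr1s.select_sex_specific_instruments(above, female, interaction_alpha=0.5, f_min=15)
        assert list(sel2.male_set["variant_id"]) == ["v1"]


class TestSexStratifiedMR:
    def _instruments(self, ids, beta, se):
        return pd.DataFrame({"variant_id": ids, "beta": beta, "se": se})

    def test_identical_sexes_combine_with_root2_se(self):
        ids = ["a", "b", "c"]
        ins = mr1s.SexSpecificInstruments(
            male_set=self._instruments(ids, [0.2, 0.3, 0.25], [0.02] * 3),
            female_set=self._instruments(ids, [0.2, 0.3, 0.25], [0.02] * 3),
            interaction_p=pd.Series(dtype=float),
            f_threshold_used=15,
        )
        outcome = self._instruments(ids, [0.06, 0.09, 0.075], [0.01] * 3)
        res = mr1s.sex_stratified_mr(ins, outcome, outcome)
        male = res["per_sex"]["male"]
        assert res["combined"].beta == pytest.approx(male.beta, abs=1e-12)
        assert res["combined"].se == pytest.approx(male.se / np.sqrt(2), abs=1e-12)

    def test_empty_sex_skipped_and_combined_equals_other(self):
        ids = ["a", "b", "c"]
        ins = mr1s.SexSpecificInstruments(
            male_set=self._instruments(ids, [0.2, 0.3, 0.25], [0.02] * 3),
            female_set=pd.DataFrame(columns=["variant_id", "beta", "se"]),
            interaction_p=pd.Series(dtype=float),
            f_threshold_used=15,
        )
        outcome = self._instruments(ids, [0.06, 0.09, 0.075], [0.01] * 3)
        res = mr1s.sex_stratified_mr(ins, outcome, outcome)
        assert "female" not in res["per_sex"]
        assert res["combined"].beta == pytest.approx(res["per_sex"]["male"].beta)

    def test_common_effect_recovered_from_sex_specific_instruments(self):
        cfg = SimConfig(n_individuals=12_000, n_variants=200, exposure_h2=0.3, seed=14)
        sim = synthdata.simulate_sex_specific(cfg, male_effect=2.0, female_effect=0.2)
        sel = mr1s.select_sex_specific_instruments(
            sim["male_stats"].assign(variant_id=sim["variants"]["variant_id"]),
            sim["female_stats"].assign(variant_id=sim["variants"]["variant_id"]),
            interaction_alpha=1e-3,
        )
        if sel.male_set.empty and sel.female_set.empty:
            pytest.skip("no instruments passed selection at this simulated strength")
        theta = 0.3
        rng = np.random.default_rng(15)

        def outcome_stats(table):
            return pd.DataFrame({
                "variant_id": table["variant_id"],
                "beta": theta * table["beta"] + rng.normal(0, 1e-4, len(table)),
                "se": 1e-4,
            })

        res = mr1s.sex_stratified_mr(sel, outcome_stats(sel.male_set), outcome_stats(sel.female_set))
        assert res["combined"].beta == pytest.approx(theta, abs=0.05)
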