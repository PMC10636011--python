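"""Two-sample MR estimators vs closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fallmr import mr2s, synthdata
from fallmr.synthdata import SimConfig

from conftest import make_instruments


def sumstats_row(vid, ea, oa, eaf, beta, se=0.05, n=10_000):
    return {
        "variant_id": vid, "chrom": 1, "pos": 100, "effect_allele": ea,
        "other_allele": oa, "eaf": eaf, "beta": beta, "se": se,
        "pvalue": 2 * stats.norm.sf(abs(beta / se)), "n": n,
    }


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = pd.DataFrame([sumstats_row("v1", "A", "G", 0.3, 0.5)])
        out = pd.DataFrame([sumstats_row("v1", "G", "A", 0.7, 0.2)])
        ins = mr2s.harmonize(exp, out)
        assert ins["harmonization_action"].iloc[0] == "flipped"
        assert ins["beta_y"].iloc[0] == pytest.approx(-0.2)

    def test_ambiguous_palindromic_dropped(self):
        exp = pd.DataFrame([sumstats_row("v1", "A", "T", 0.50, 0.5)])
        out = pd.DataFrame([sumstats_row("v1", "A", "T", 0.50, 0.2)])
        ins = mr2s.harmonize(exp, out)
        assert ins["harmonization_action"].iloc[0] == "dropped_palindromic"

    def test_aligned_variant_kept_unchanged(self):
        exp = pd.DataFrame([sumstats_row("v1", "A", "G", 0.3, 0.5)])
        out = pd.DataFrame([sumstats_row("v1", "A", "G", 0.3, 0.2)])
        ins = mr2s.harmonize(exp, out)
        assert ins["harmonization_action"].iloc[0] == "kept"
        assert ins["beta_y"].iloc[0] == pytest.approx(0.2)

    def test_complement_strand_recognised(self):
        exp = pd.DataFrame([sumstats_row("v1", "A", "G", 0.3, 0.5)])
        out = pd.DataFrame([sumstats_row("v1", "T", "C", 0.3, 0.2)])
        ins = mr2s.harmonize(exp, out)
        assert ins["harmonization_action"].iloc[0] == "kept"

    def test_no_shared_variants_rejected(self):
        exp = pd.DataFrame([sumstats_row("v1", "A", "G", 0.3, 0.5)])
        out = pd.DataFrame([sumstats_row("v2", "A", "G", 0.3, 0.2)])
        with pytest.raises(ValueError, match="shared"):
            mr2s.harmonize(exp, out)


def ivw_oracle(bx, by, sy):
    """Closed-form weighted through-origin regression."""
    w = 1.0 / np.asarray(sy) ** 2
    bx, by = np.asarray(bx), np.asarray(by)
    beta = (w * bx * by).sum() / (w * bx**2).sum()
    se = np.sqrt(1.0 / (w * bx**2).sum())
    return beta, se


def egger_oracle(bx, by, sy):
    """Weighted regression with intercept via the normal equations."""
    sign = np.where(np.asarray(bx) < 0, -1.0, 1.0)
    bx, by = np.asarray(bx) * sign, np.asarray(by) * sign
    w = 1.0 / np.asarray(sy) ** 2
    W = np.diag(w)
    X = np.column_stack([np.ones_like(bx), bx])
    coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
    return coef[1], coef[0]


def wm_oracle(ratios, weights):
    """Brute-force cumulative-weight interpolation at 50%."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    cum = np.cumsum(w) - w / 2
    for i in range(1, len(r)):
        if cum[i] >= 0.5:
            return r[i - 1] + (r[i] - r[i - 1]) * (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
    return r[-1]


@pytest.fixture(scope="module")
def fixed_instruments():
    rng = np.random.default_rng(42)
    k = 10
    bx = rng.uniform(0.05, 0.3, k)
    sy = rng.uniform(0.02, 0.08, k)
    by = 0.3 * bx + rng.normal(0, 0.02, k)
    return make_instruments(bx, np.full(k, 0.01), by, sy)


class TestIVW:
    def test_single_instrument_is_ratio(self):
        ins = make_instruments([0.5], [0.02], [0.2], [0.1])
        est = mr2s.ivw(ins)
        assert est.method == "ratio"
        assert est.beta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.2)

    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.4])
        ins = make_instruments(bx, bx * 0 + 0.01, 0.7 * bx, [0.05, 0.04, 0.06])
        est = mr2s.ivw(ins)
        assert est.beta == pytest.approx(0.7, abs=1e-12)
        assert est.heterogeneity["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_closed_form_oracle(self, fixed_instruments):
        est = mr2s.ivw(fixed_instruments, effects="fixed")
        beta, se = ivw_oracle(
            fixed_instruments["beta_x"], fixed_instruments["beta_y"], fixed_instruments["se_y"]
        )
        assert est.beta == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_random_effects_never_shrink_se(self, fixed_instruments):
        fx = mr2s.ivw(fixed_instruments, effects="fixed")
        re = mr2s.ivw(fixed_instruments, effects="multiplicative_random")
        assert re.se >= fx.se

    def test_zero_exposure_effect_single_instrument_rejected(self):
        ins = make_instruments([0.0], [0.02], [0.2], [0.1])
        with pytest.raises(ValueError):
            mr2s.ivw(ins)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.3 * bx
        ins = make_instruments(bx, bx * 0 + 0.01, by, [0.05] * 4)
        slope, intercept = mr2s.mr_egger(ins)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.beta == pytest.approx(0.1, abs=1e-10)

    def test_matches_weighted_regression_oracle(self, fixed_instruments):
        slope, intercept = mr2s.mr_egger(fixed_instruments)
        s, i = egger_oracle(
            fixed_instruments["beta_x"], fixed_instruments["beta_y"], fixed_instruments["se_y"]
        )
        assert slope.beta == pytest.approx(s, abs=1e-10)
        assert intercept.beta == pytest.approx(i, abs=1e-10)

    def test_too_few_instruments_rejected(self):
        ins = make_instruments([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.05] * 2)
        with pytest.raises(ValueError, match="3"):
            mr2s.mr_egger(ins)

    def test_directional_pleiotropy_biases_ivw_not_egger(self):
        rng = np.random.default_rng(8)
        k, theta, pleio = 50, 0.2, 0.08
        bx = rng.uniform(0.1, 0.5, k)
        sy = np.full(k, 0.01)
        by = theta * bx + pleio + rng.normal(0, 0.01, k)
        ins = make_instruments(bx, np.full(k, 0.005), by, sy)
        ivw_est = mr2s.ivw(ins)
        slope, intercept = mr2s.mr_egger(ins)
        assert abs(ivw_est.beta - theta) > 3 * ivw_est.se  # IVW biased
        assert abs(slope.beta - theta) < 3 * slope.se      # Egger recovers
        assert abs(intercept.beta - pleio) < 3 * intercept.se


class TestWeightedMedian:
    def test_equal_ratios_reproduced_exactly(self):
        bx = np.array([0.1, 0.25, 0.4])
        ins = make_instruments(bx, bx * 0 + 0.01, 0.6 * bx, [0.03, 0.08, 0.02])
        est = mr2s.weighted_median(ins, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.6, abs=1e-12)

    def test_matches_interpolation_oracle(self, fixed_instruments):
        est = mr2s.weighted_median(fixed_instruments, n_boot=10, seed=0)
        ratios = fixed_instruments["beta_y"] / fixed_instruments["beta_x"]
        weights = fixed_instruments["beta_x"] ** 2 / fixed_instruments["se_y"] ** 2
        assert est.beta == pytest.approx(wm_oracle(ratios, weights), abs=1e-10)

    def test_equal_weights_odd_k_matches_hand_interpolation(self):
        bx = np.ones(5)
        by = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        ins = make_instruments(bx, bx * 0.01, by, np.ones(5))
        est = mr2s.weighted_median(ins, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.3, abs=1e-12)  # middle ratio at 50%

    def test_robust_to_minority_invalid_instruments(self):
        rng = np.random.default_rng(9)
        k, theta = 10, 0.2
        bx = rng.uniform(0.2, 0.5, k)
        sy = np.full(k, 0.008)
        by = theta * bx + rng.normal(0, 0.008, k)
        by[:3] += 0.15  # 3 of 10 instruments grossly pleiotropic
        ins = make_instruments(bx, np.full(k, 0.004), by, sy)
        wm = mr2s.weighted_median(ins, n_boot=500, seed=1)
        ivw_est = mr2s.ivw(ins, effects="fixed")
        assert abs(wm.beta - theta) < 3 * wm.se
        assert abs(ivw_est.beta - theta) > 3 * ivw_est.se


class TestPenalisedWeightedMedian:
    def test_no_outliers_equals_wm(self, fixed_instruments):
        wm = mr2s.weighted_median(fixed_instruments, n_boot=10, seed=0)
        pwm = mr2s.penalised_weighted_median(fixed_instruments, n_boot=10, seed=0)
        assert pwm.beta == pytest.approx(wm.beta, abs=1e-10)

    def test_gross_outlier_downweighted(self):
        bx = np.array([0.2, 0.25, 0.3, 0.35, 0.4])
        by = 0.3 * bx
        by[4] += 0.5  # one wildly pleiotropic instrument
        ins = make_instruments(bx, bx * 0 + 0.005, by, np.full(5, 0.01))
        factors = mr2s.penalisation_factors(ins)
        assert factors[4] < 0.01
        assert (factors[:4] > 0.5).all()
        pwm = mr2s.penalised_weighted_median(ins, n_boot=200, seed=2)
        assert abs(pwm.beta - 0.3) < 0.02

    def test_vanishing_penalty_alpha_recovers_wm(self):
        rng = np.random.default_rng(10)
        bx = rng.uniform(0.1, 0.4, 8)
        by = 0.3 * bx + rng.normal(0, 0.05, 8)
        ins = make_instruments(bx, np.full(8, 0.01), by, np.full(8, 0.03))
        wm = mr2s.weighted_median(ins, n_boot=10, seed=0)
        pwm = mr2s.penalised_weighted_median(ins, penalty_alpha=1e-300, n_boot=10, seed=0)
        assert pwm.beta == pytest.approx(wm.beta, abs=1e-10)


class TestMeanF:
    def test_single_instrument_f_is_squared_z(self):
        ins = make_instruments([0.5], [0.1], [0.1], [0.1])
        assert mr2s.mean_f_statistic(ins).mean_f == pytest.approx(25.0)

    def test_null_instruments_give_mean_f_near_one(self):
        rng = np.random.default_rng(11)
        k = 4000
        sx = np.full(k, 0.02)
        ins = make_instruments(rng.normal(0, 0.02, k), sx, np.zeros(k), np.full(k, 0.02))
        assert mr2s.mean_f_statistic(ins).mean_f == pytest.approx(1.0, abs=0.1)

    def test_design_strength_recovered(self):
        rng = np.random.default_rng(12)
        k, target_f = 200, 10.0
        sx = np.full(k, 0.01)
        bx_true = np.full(k, np.sqrt((target_f - 1)) * 0.01)
        bx_hat = bx_true + rng.normal(0, 0.01, k)
        ins = make_instruments(bx_hat, sx, np.zeros(k), np.full(k, 0.02))
        assert mr2s.mean_f_statistic(ins).mean_f == pytest.approx(target_f, rel=0.15)


class TestScalePerDoubling:
    def test_ln2_constant(self):
        est = mr2s.MREstimate("IVW", 1.0, 0.1, 0.01, 5, exposure_binary=True)
        scaled = mr2s.scale_per_doubling(est)
        assert scaled.beta == pytest.approx(0.693, abs=5e-4)
        assert scaled.scale_note == "per_doubling_log_odds"

    def test_zero_maps_to_zero(self):
        est = mr2s.MREstimate("IVW", 0.0, 0.1, 1.0, 5, exposure_binary=True)
        assert mr2s.scale_per_doubling(est).beta == 0.0

    def test_full_precision_arithmetic(self):
        est = mr2s.MREstimate("IVW", 0.2, 0.05, 0.01, 5, exposure_binary=True)
        scaled = mr2s.scale_per_doubling(est)
        assert scaled.beta == pytest.approx(0.2 * np.log(2), abs=1e-12)
        assert scaled.se == pytest.approx(0.05 * np.log(2), abs=1e-12)
        assert scaled.odds_ratio == pytest.approx(np.exp(0.2 * np.log(2)), abs=1e-12)

    def test_continuous_exposure_rejected(self):
        est = mr2s.MREstimate("IVW", 0.2, 0.05, 0.01, 5, exposure_binary=False)
        with pytest.raises(ValueError, match="binary"):
            mr2s.scale_per_doubling(est)

    def test_double_scaling_rejected(self):
        est = mr2s.MREstimate("IVW", 0.2, 0.05, 0.01, 5, exposure_binary=True)
        once = mr2s.scale_per_doubling(est)
        with pytest.raises(ValueError, match="already"):
            mr2s.scale_per_doubling(once)


@pytest.fixture(scope="module")
def clean_sim():
    cfg = SimConfig(n_variants=30, exposure_h2=0.1, true_causal_effect=0.3, seed=77,
                    n_exposure_gwas=200_000, n_outcome_gwas=200_000)
    pair = synthdata.simulate_sumstats_pair(cfg)
    return mr2s.harmonize(pair.exposure_stats, pair.outcome_stats)


class TestEstimatorProperties:

    def test_sign_equivariance(self, clean_sim):
        flipped = clean_sim.assign(beta_y=-clean_sim["beta_y"])
        for fn in (lambda i: mr2s.ivw(i), lambda i: mr2s.mr_egger(i)[0],
                   lambda i: mr2s.weighted_median(i, n_boot=10, seed=0)):
            assert fn(flipped).beta == pytest.approx(-fn(clean_sim).beta, abs=1e-10)

    def test_exposure_rescaling_divides_estimate(self, clean_sim):
        c = 3.0
        scaled = clean_sim.assign(beta_x=c * clean_sim["beta_x"], se_x=c * clean_sim["se_x"])
        assert mr2s.ivw(scaled).beta == pytest.approx(mr2s.ivw(clean_sim).beta / c, abs=1e-10)

    def test_methods_agree_on_clean_data(self, clean_sim):
        ests = [
            mr2s.ivw(clean_sim),
            mr2s.mr_egger(clean_sim)[0],
            mr2s.weighted_median(clean_sim, n_boot=300, seed=3),
            mr2s.penalised_weighted_median(clean_sim, n_boot=300, seed=3),
        ]
        for est in ests:
            assert abs(est.beta - 0.3) < 3 * est.se
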