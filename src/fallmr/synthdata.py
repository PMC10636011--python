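"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes — genotype dosages, continuous exposures,
a ~10%-prevalence binary fall phenotype with an over-dispersed per-case
fall count, coded clinical event logs, and exposure/outcome GWAS
summary-statistic pairs — can be generated here with the parameters that
produced it returned alongside, so that downstream estimators can be
checked for bias, coverage and calibration without any external data.

The binary outcome lives on the logistic (log-odds) scale, matching the
estimators applied to it; the per-case fall count is ``1 + Poisson`` so
that *case* and *count >= 1* coincide by construction.  Sample overlap
between the exposure and outcome GWAS is induced at the estimation-error
level (correlated noise between the two summary tables) rather than by
resampling shared individuals, which is the abstraction the overlap
correction itself works at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SimConfig",
    "Cohort",
    "SumStatsPair",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_sumstats_pair",
    "simulate_event_log",
    "simulate_correlated_gwas",
    "simulate_sex_specific",
]

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"),
    ("G", "A"), ("C", "A"), ("C", "T"), ("G", "T"),
    ("A", "T"), ("C", "G"),  # palindromic pairs, kept rare below
]


@dataclass
class SimConfig:
    """Knobs of the data-generating process.

    The defaults describe the study conditions the pipeline is validated
    under: a ~10% case-prevalence binary fall outcome, polygenic exposures
    with configurable confounding, and optional pleiotropy / sample-overlap
    / winner's-curse structure in the summary-statistic generator.
    """

    n_individuals: int = 10_000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    within_block_r: float = 0.0
    case_prevalence: float = 0.10
    exposure_h2: float = 0.2
    confounder_effect_x: float = 0.0
    confounder_effect_y: float = 0.0
    true_causal_effect: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    overlap_fraction: float = 0.0
    selection_pvalue: float = 1.0  # 1.0 = no instrument selection
    seed: int = 0
    # secondary knobs
    n_causal: int | None = None            # None = all variants causal
    n_exposure_gwas: int = 100_000         # GWAS sample size behind beta_x
    n_outcome_gwas: int = 200_000          # GWAS sample size behind beta_y
    count_mean_extra: float = 0.37         # mean Poisson rate of falls beyond the first
    count_dispersion: float = 0.0          # gamma-frailty over-dispersion (0 = Poisson)
    age_effect: float = 0.03               # log-odds of falling per year of age
    sex_effect: float = -0.3               # log-odds for males relative to females
    exposure_active_stratum: str | None = None  # restrict genetic effect on the
    # exposure to one 'drinker' stratum (negative-control designs)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("n_individuals and n_variants must be >= 1")
        if not (0 < self.case_prevalence < 1):
            raise ValueError(f"case_prevalence must lie in (0, 1), got {self.case_prevalence}")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError(f"overlap_fraction must lie in [0, 1], got {self.overlap_fraction}")
        if not (0 <= self.within_block_r < 1):
            raise ValueError(f"within_block_r must lie in [0, 1), got {self.within_block_r}")
        if not (0 <= self.exposure_h2 < 1):
            raise ValueError(f"exposure_h2 must lie in [0, 1), got {self.exposure_h2}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")


@dataclass
class Cohort:
    """Individual-level cohort: dosages, covariates, exposure and outcome."""

    data: pd.DataFrame           # person_id, sex, age, confounder, exposure, fall_status, fall_count, drinker
    dosages: np.ndarray          # n_individuals x n_variants, values {0,1,2}
    variants: pd.DataFrame       # variant_id, chrom, pos, alleles, eaf, info
    truth: dict = field(default_factory=dict)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.data["fall_status"] == "case").to_numpy()


@dataclass
class SumStatsPair:
    """Exposure/outcome summary-statistic tables with their ground truth."""

    exposure_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    truth: dict


def simulate_genotypes(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw block-LD dosages in {0,1,2} plus variant metadata.

    The latent haplotype Gaussian within a block follows an AR(1)
    correlation structure whose adjacent-variant correlation cycles over
    {1, 2/3, 1/3, 0} x ``within_block_r`` from block to block (decaying
    as r^|i-j| with variant distance within a block).  Both choices exist
    to spread the LD scores out: a genome whose variants all tag the same
    amount of variation leaves the LD-score-regression slope and
    intercept unidentifiable.  Each of the two haplotypes per person is
    thresholded at the allele-frequency quantile, so empirical MAFs track
    the requested range.  INFO values are drawn in (0, 1] (mostly near 1,
    with a minority low) so imputation-quality filters have something to
    remove.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    bsize = config.ld_block_size
    idx = np.arange(bsize)
    dist = np.abs(idx[:, None] - idx[None, :])
    block_r_fracs = (1.0, 2.0 / 3.0, 1.0 / 3.0, 0.0)
    chols = {}
    for frac in block_r_fracs:
        r_b = config.within_block_r * frac
        chols[frac] = np.linalg.cholesky(r_b**dist) if r_b > 0 else np.eye(bsize)

    dosages = np.zeros((n, m), dtype=np.int8)
    for bi, start in enumerate(range(0, m, bsize)):
        stop = min(start + bsize, m)
        width = stop - start
        frac = block_r_fracs[bi % len(block_r_fracs)]
        L = chols[frac][:width, :width]
        for _hap in range(2):
            z = rng.standard_normal((n, width))
            if frac > 0 and config.within_block_r > 0:
                z = z @ L.T
            dosages[:, start:stop] += (z < thresholds[start:stop]).astype(np.int8)

    pair_idx = rng.integers(0, 8, size=m)           # non-palindromic pairs
    palindromic = rng.random(m) < 0.08
    pair_idx[palindromic] = rng.integers(8, 10, size=int(palindromic.sum()))
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    info = np.where(rng.random(m) < 0.9, rng.beta(20, 1, size=m), rng.random(m))
    info = np.clip(info, 1e-3, 1.0)

    block_of = np.arange(m) // config.ld_block_size
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{100000 + i}" for i in range(m)],
            "chrom": (block_of % 22 + 1).astype(int),
            "pos": 10_000 + 5_000 * np.arange(m),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": mafs,
            "info": info,
        }
    )
    return dosages, variants


def _draw_variant_effects(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-variant effects on the standardized exposure: normal polygenic model."""
    m = config.n_variants
    n_causal = m if config.n_causal is None else min(config.n_causal, m)
    betas = np.zeros(m)
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    betas[causal_idx] = rng.normal(0.0, np.sqrt(config.exposure_h2 / n_causal), size=n_causal)
    return betas


def _tune_intercept(linear_predictor: np.ndarray, prevalence: float) -> float:
    """Find the logistic intercept that hits the target case fraction."""

    def gap(c: float) -> float:
        return float(np.mean(stats.logistic.cdf(c + linear_predictor))) - prevalence

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        achievable = (float(np.mean(stats.logistic.cdf(lo + linear_predictor))),
                      float(np.mean(stats.logistic.cdf(hi + linear_predictor))))
        raise ValueError(
            f"cannot reach case_prevalence={prevalence}; achievable range "
            f"is approximately [{achievable[0]:.4g}, {achievable[1]:.4g}]"
        )
    return optimize.brentq(gap, lo, hi, xtol=1e-10)


def simulate_traits(
    genotypes: tuple[np.ndarray, pd.DataFrame] | np.ndarray,
    config: SimConfig,
    variants: pd.DataFrame | None = None,
) -> Cohort:
    """Build a cohort on top of a dosage matrix.

    exposure = standardized(genetic score + confounder effect + noise);
    binary fall via a logistic model whose intercept is tuned numerically
    to the requested prevalence; per-case fall count = 1 + Poisson (with
    optional gamma-frailty over-dispersion) sharing the same linear
    predictor.
    """
    if isinstance(genotypes, tuple):
        dosages, variants = genotypes
    else:
        dosages = genotypes
        if variants is None:
            raise ValueError("variant metadata required when passing a bare dosage matrix")

    rng = np.random.default_rng(config.seed + 1)
    n = dosages.shape[0]

    sex = np.where(rng.random(n) < 0.45, "male", "female")
    age = rng.uniform(40.0, 70.0, size=n)
    confounder = rng.standard_normal(n)
    drinker = np.where(rng.random(n) < 0.55, "ever", "never")

    betas = _draw_variant_effects(config, rng)
    g_std = (dosages - dosages.mean(axis=0)) / np.maximum(dosages.std(axis=0), 1e-12)
    genetic = g_std @ betas
    if config.exposure_active_stratum is not None:
        genetic = np.where(drinker == config.exposure_active_stratum, genetic, 0.0)

    noise_var = max(1.0 - config.exposure_h2 - config.confounder_effect_x**2, 0.05)
    exposure_raw = (
        genetic
        + config.confounder_effect_x * confounder
        + rng.normal(0.0, np.sqrt(noise_var), size=n)
    )
    exposure = (exposure_raw - exposure_raw.mean()) / exposure_raw.std()

    lp = (
        config.true_causal_effect * exposure
        + config.confounder_effect_y * confounder
        + config.age_effect * (age - age.mean())
        + config.sex_effect * (sex == "male")
    )
    intercept = _tune_intercept(lp, config.case_prevalence)
    p_case = stats.logistic.cdf(intercept + lp)
    is_case = rng.random(n) < p_case

    # count of falls beyond the first, sharing the causal linear predictor
    count_lp = config.true_causal_effect * exposure + config.confounder_effect_y * confounder
    lam = config.count_mean_extra * np.exp(count_lp - count_lp.mean())
    if config.count_dispersion > 0:
        shape = 1.0 / config.count_dispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=n)
    fall_count = np.where(is_case, 1 + rng.poisson(lam), 0)

    data = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "confounder": confounder,
            "drinker": drinker,
            "exposure": exposure,
            "fall_status": np.where(is_case, "case", "control"),
            "fall_count": fall_count.astype(int),
        }
    )
    truth = {
        "true_causal_effect": config.true_causal_effect,
        "variant_effects": betas,
        "intercept": intercept,
        "confounder_effect_x": config.confounder_effect_x,
        "confounder_effect_y": config.confounder_effect_y,
        "case_prevalence": config.case_prevalence,
    }
    return Cohort(data=data, dosages=dosages, variants=variants, truth=truth)


def simulate_sumstats_pair(config: SimConfig, n_instruments: int | None = None) -> SumStatsPair:
    """Exposure/outcome summary-statistic pair with known causal structure.

    outcome beta = true_causal_effect * exposure beta + pleiotropy + noise;
    the two tables' estimation errors are correlated in proportion to
    ``overlap_fraction`` (scaled by the phenotypic correlation the
    confounding and causal effect would induce), and an optional
    winner's-curse step retains only variants whose *estimated* exposure
    p-value clears ``selection_pvalue``.
    """
    m = n_instruments if n_instruments is not None else config.n_variants
    if m < 1:
        raise ValueError("need at least one candidate instrument")
    rng = np.random.default_rng(config.seed + 2)

    # per-variant LD scores l_j: the marginal (tagged) effect variance is
    # h2 * l_j / m, matching the LDSC regression model E[chi2] = 1 + n h2 l/m
    ld_scores = rng.uniform(1.0, 4.0, size=m)
    beta_x = rng.normal(0.0, 1.0, size=m) * np.sqrt(config.exposure_h2 * ld_scores / m)
    if config.pleiotropy_mode == "none":
        alpha = np.zeros(m)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, size=m)
    else:  # directional
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m)
    beta_y = config.true_causal_effect * beta_x + alpha

    se_x = np.full(m, 1.0 / np.sqrt(config.n_exposure_gwas)) * rng.uniform(0.9, 1.1, size=m)
    se_y = np.full(m, 1.0 / np.sqrt(config.n_outcome_gwas)) * rng.uniform(0.9, 1.1, size=m)

    pheno_corr = config.confounder_effect_x * config.confounder_effect_y + config.true_causal_effect
    rho = float(np.clip(config.overlap_fraction * pheno_corr, -0.95, 0.95))
    zx = rng.standard_normal(m)
    zy = rho * zx + np.sqrt(1.0 - rho**2) * rng.standard_normal(m)
    bx_hat = beta_x + zx * se_x
    by_hat = beta_y + zy * se_y

    p_x = 2.0 * stats.norm.sf(np.abs(bx_hat / se_x))
    keep = np.ones(m, dtype=bool) if config.selection_pvalue >= 1.0 else p_x < config.selection_pvalue
    if not keep.any():
        raise ValueError(
            f"instrument selection at p < {config.selection_pvalue} retained zero of "
            f"{m} candidate variants; weaken the threshold or strengthen the effects"
        )

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    pair_idx = rng.integers(0, 8, size=m)
    meta = {
        "variant_id": [f"rs{200000 + i}" for i in range(m)],
        "chrom": np.ones(m, dtype=int),
        "pos": 10_000 + 5_000 * np.arange(m),
        "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "eaf": mafs,
        "info": np.ones(m),
    }

    def _table(beta_hat: np.ndarray, se: np.ndarray, n_gwas: int) -> pd.DataFrame:
        z = beta_hat / se
        return pd.DataFrame(
            {
                **meta,
                "beta": beta_hat,
                "se": se,
                "pvalue": 2.0 * stats.norm.sf(np.abs(z)),
                "n": np.full(m, n_gwas, dtype=int),
            }
        ).loc[keep].reset_index(drop=True)

    truth = {
        "true_causal_effect": config.true_causal_effect,
        "beta_x_true": beta_x[keep],
        "beta_x_true_all": beta_x,
        "pleiotropy": alpha[keep],
        "error_correlation": rho,
        "ld_scores": ld_scores,
        "ld_scores_retained": ld_scores[keep],
        "n_candidates": m,
        "n_retained": int(keep.sum()),
        "selection_pvalue": config.selection_pvalue,
    }
    return SumStatsPair(
        exposure_stats=_table(bx_hat, se_x, config.n_exposure_gwas),
        outcome_stats=_table(by_hat, se_y, config.n_outcome_gwas),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# coded clinical event logs

_HES_WINDOW = (np.datetime64("1995-01-01"), np.datetime64("2021-12-31"))
_GP_WINDOW = (np.datetime64("1955-01-01"), np.datetime64("2017-12-31"))


def _random_dates(rng: np.random.Generator, window, size: int, distinct: bool) -> np.ndarray:
    lo, hi = window
    span = int((hi - lo) / np.timedelta64(1, "D"))
    if distinct:
        offsets = rng.choice(span, size=size, replace=False)
    else:
        offsets = rng.integers(0, span, size=size)
    return lo + offsets.astype("timedelta64[D]")


def simulate_event_log(
    cohort: Cohort,
    code_list,
    seed: int = 0,
    frac_no_records: float = 0.01,
    max_codes_per_date: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Emit a coded HES/GP event log consistent with the cohort's phenotype.

    Each case receives ``fall_count`` *distinct* event dates, each carrying
    1..max_codes_per_date distinct balance-fall codes (so the same-date
    deduplication rule is exercised); everyone also receives unrelated
    non-fall records, except a small fraction of controls flagged
    "no-records" who receive no rows at all (exercising the exclusion
    rule).  Returns the log and the list of no-records person ids.
    """
    entries = code_list.entries if hasattr(code_list, "entries") else code_list
    include = entries[entries["category"] == "balance_fall"]
    nonfall = entries[entries["category"] == "non_fall"]
    if include.empty:
        raise ValueError("code list contains no balance_fall codes")
    if nonfall.empty:
        raise ValueError("code list contains no non_fall codes")

    rng = np.random.default_rng(seed)
    pools = {
        ("HES", "fall"): include[include["vocabulary"] == "ICD10"],
        ("GP", "fall"): include[include["vocabulary"].isin(["READ2", "READ3"])],
        ("HES", "non"): nonfall[nonfall["vocabulary"] == "ICD10"],
        ("GP", "non"): nonfall[nonfall["vocabulary"].isin(["READ2", "READ3"])],
    }
    for key, pool in pools.items():
        if pool.empty:
            raise ValueError(f"code list has no codes for {key[0]} ({key[1]}-fall)")

    data = cohort.data
    controls = data.loc[data["fall_status"] == "control", "person_id"].tolist()
    n_skip = int(round(frac_no_records * len(controls)))
    no_records = sorted(rng.choice(controls, size=n_skip, replace=False).tolist()) if n_skip else []
    skip = set(no_records)

    rows: list[tuple] = []
    for pid, status, count in zip(data["person_id"], data["fall_status"], data["fall_count"]):
        if pid in skip:
            continue
        if status == "case":
            source = "HES" if rng.random() < 0.5 else "GP"
            window = _HES_WINDOW if source == "HES" else _GP_WINDOW
            pool = pools[(source, "fall")]
            dates = _random_dates(rng, window, int(count), distinct=True)
            for date in dates:
                k = int(rng.integers(1, min(max_codes_per_date, len(pool)) + 1))
                picks = pool.iloc[rng.choice(len(pool), size=k, replace=False)]
                for _, code_row in picks.iterrows():
                    rows.append((pid, source, code_row["vocabulary"], code_row["code"], date))
        n_other = int(rng.integers(1, 4))
        for _ in range(n_other):
            source = "HES" if rng.random() < 0.5 else "GP"
            window = _HES_WINDOW if source == "HES" else _GP_WINDOW
            pool = pools[(source, "non")]
            code_row = pool.iloc[int(rng.integers(0, len(pool)))]
            date = _random_dates(rng, window, 1, distinct=False)[0]
            rows.append((pid, source, code_row["vocabulary"], code_row["code"], date))

    events = pd.DataFrame(rows, columns=["person_id", "source", "vocabulary", "code", "event_date"])
    events["event_date"] = pd.to_datetime(events["event_date"])
    return events, no_records


def simulate_correlated_gwas(
    config: SimConfig,
    rg_true: float,
    h2_b: float | None = None,
) -> dict:
    """Two individual-level traits with genetically correlated effects.

    Per-variant standardized causal effects for the two traits are drawn
    from a bivariate normal with correlation ``rg_true`` and per-trait
    variances h2/m; marginal association scans on the shared genotypes
    give the two summary tables whose LD score regression should recover
    the h2 values and rg.  The two traits' environmental noise is
    independent (no phenotypic overlap term beyond genetics).
    """
    from fallmr.assoc import linear_assoc_scan

    if not (-1.0 <= rg_true <= 1.0):
        raise ValueError("rg_true must lie in [-1, 1]")
    dosages, variants = simulate_genotypes(config)
    rng = np.random.default_rng(config.seed + 4)
    n, m = dosages.shape
    h2a = config.exposure_h2
    h2b = h2_b if h2_b is not None else h2a

    za = rng.standard_normal(m)
    zb = rg_true * za + np.sqrt(1.0 - rg_true**2) * rng.standard_normal(m)
    b1 = za * np.sqrt(h2a / m)
    b2 = zb * np.sqrt(h2b / m)

    g_std = (dosages - dosages.mean(axis=0)) / np.maximum(dosages.std(axis=0), 1e-12)
    y1 = g_std @ b1 + rng.normal(0.0, np.sqrt(max(1 - h2a, 0.02)), size=n)
    y2 = g_std @ b2 + rng.normal(0.0, np.sqrt(max(1 - h2b, 0.02)), size=n)

    out = {}
    for label, y in (("a", y1), ("b", y2)):
        scan = linear_assoc_scan(dosages, y)
        scan.insert(0, "variant_id", variants["variant_id"].to_numpy())
        out[f"stats_{label}"] = scan
    out.update(
        dosages=dosages,
        variants=variants,
        truth={"rg": rg_true, "h2_a": h2a, "h2_b": h2b, "beta_a": b1, "beta_b": b2},
    )
    return out


def simulate_sex_specific(
    config: SimConfig,
    male_effect: float,
    female_effect: float,
    frac_interaction: float = 0.1,
) -> dict:
    """Cohort with sex-specific genetic effects plus per-sex GWAS tables.

    The first ``ceil(frac_interaction * n_variants)`` variants carry a
    sex-by-genotype interaction: their shared base effect is multiplied by
    ``male_effect`` in males and ``female_effect`` in females.  Per-sex
    marginal association tables are computed on the respective subsets.
    """
    from fallmr.assoc import linear_assoc_scan

    dosages, variants = simulate_genotypes(config)
    rng = np.random.default_rng(config.seed + 3)
    n, m = dosages.shape

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    if len(set(sex)) < 2:
        raise ValueError("cohort must contain both sexes")

    base = rng.normal(0.0, np.sqrt(config.exposure_h2 / m), size=m)
    n_int = max(1, int(np.ceil(frac_interaction * m)))
    beta_m, beta_f = base.copy(), base.copy()
    beta_m[:n_int] = male_effect * base[:n_int]
    beta_f[:n_int] = female_effect * base[:n_int]

    g_std = (dosages - dosages.mean(axis=0)) / np.maximum(dosages.std(axis=0), 1e-12)
    noise = rng.normal(0.0, np.sqrt(max(1.0 - config.exposure_h2, 0.05)), size=n)
    exposure = np.where(sex == "male", g_std @ beta_m, g_std @ beta_f) + noise

    out = {}
    for label, mask in (("male", sex == "male"), ("female", sex == "female")):
        scan = linear_assoc_scan(dosages[mask], exposure[mask])
        scan.insert(0, "variant_id", variants["variant_id"].to_numpy())
        out[f"{label}_stats"] = scan
    out.update(
        dosages=dosages,
        variants=variants,
        sex=sex,
        exposure=exposure,
        truth={
            "beta_male": beta_m,
            "beta_female": beta_f,
            "interaction_variants": variants["variant_id"].iloc[:n_int].tolist(),
        },
    )
    return out
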