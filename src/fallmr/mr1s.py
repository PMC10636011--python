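"""One-sample Mendelian randomisation: allele scores, two-stage estimation,
stratified negative controls, and sex-stratified instrument selection.

The two-stage estimator regresses the exposure on the genetic instrument
(plus covariates) in a first linear stage, then regresses the outcome on
the first-stage fitted values (plus covariates) under a linear, logistic
or Poisson second stage.  Second-stage standard errors are robust
(sandwich) with the first-stage fit treated as fixed — the usual
2SLS-for-binary-outcomes practice; the neglected generated-regressor
uncertainty is small at the strong instrument strengths these analyses
require, and a bootstrap alternative is available.

Sex-stratified instrument selection identifies variants with a
gene-by-sex interaction, assigns each to the sex where it is stronger,
and retains it only if its per-sex F statistic ((beta/se)^2) strictly
exceeds the threshold (default 15).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from fallmr.mr2s import MREstimate

__all__ = [
    "build_allele_score",
    "tsls",
    "stratified_mr",
    "select_sex_specific_instruments",
    "sex_stratified_mr",
    "TSLSResult",
    "SexSpecificInstruments",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class TSLSResult:
    second_stage_family: str
    beta: float
    se: float
    ci95: tuple[float, float]
    p: float
    first_stage_F: float
    n: int
    flag: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if np.isfinite(self.beta) and not (lo <= self.beta <= hi):
            raise ValueError("confidence interval does not bracket the estimate")


@dataclass
class SexSpecificInstruments:
    male_set: pd.DataFrame
    female_set: pd.DataFrame
    interaction_p: pd.Series
    f_threshold_used: float


def build_allele_score(
    dosages: np.ndarray,
    weights: np.ndarray,
    standardize: bool = False,
    eaf: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted dosage sum per person; missing dosages imputed to 2*EAF.

    Mean imputation preserves the score's expectation; when EAF is not
    supplied the observed column mean stands in for 2*EAF.
    """
    D = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("weight vector is empty")
    if D.shape[1] != w.size:
        raise ValueError(f"{D.shape[1]} variants but {w.size} weights")
    if np.isnan(D).any():
        fill = 2.0 * np.asarray(eaf, dtype=float) if eaf is not None else np.nanmean(D, axis=0)
        idx = np.where(np.isnan(D))
        D = D.copy()
        D[idx] = np.take(fill, idx[1])
    score = D @ w
    if standardize:
        sd = score.std()
        if sd == 0:
            raise ValueError("allele score is constant; cannot standardize")
        score = (score - score.mean()) / sd
    return score


def _design(main: np.ndarray, covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones(n), np.asarray(main, dtype=float)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    return np.column_stack(cols)


def tsls(
    score: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    second_stage_family: str = "linear",
) -> TSLSResult:
    """Two-stage estimate of the exposure's causal effect on the outcome.

    First stage: OLS of exposure on the allele score (plus covariates);
    the score's F statistic is its squared t.  Second stage: GLM of the
    outcome on the fitted exposure (plus covariates) with HC0 robust SEs.
    """
    score = np.asarray(score, dtype=float)
    x = np.asarray(exposure, dtype=float)
    yv = np.asarray(outcome)
    if yv.dtype == object or yv.dtype.kind in "US":
        yv = (yv == "case").astype(float)
    yv = yv.astype(float)
    n = len(score)

    X1 = _design(score, covariates, n)
    first = sm.OLS(x, X1).fit()
    f_stat = float(first.tvalues[1] ** 2)
    fitted = X1 @ first.params

    families = {
        "linear": sm.families.Gaussian(),
        "logistic": sm.families.Binomial(),
        "poisson": sm.families.Poisson(),
    }
    if second_stage_family not in families:
        raise ValueError(f"unknown second-stage family {second_stage_family!r}")
    if second_stage_family == "logistic" and not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValueError("logistic second stage requires a binary outcome")
    if second_stage_family == "poisson" and (np.any(yv < 0) or np.any(yv != np.round(yv))):
        raise ValueError("poisson second stage requires a non-negative integer outcome")

    X2 = _design(fitted, covariates, n)
    fit = sm.GLM(yv, X2, family=families[second_stage_family]).fit(cov_type="HC0")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    flag = "weak_instrument" if f_stat < 1.0 else ""
    return TSLSResult(
        second_stage_family=second_stage_family,
        beta=beta,
        se=se,
        ci95=(beta - _Z95 * se, beta + _Z95 * se),
        p=p,
        first_stage_F=f_stat,
        n=n,
        flag=flag,
    )


def stratified_mr(
    cohort: pd.DataFrame,
    stratum_variable: str,
    instrument: str,
    exposure: str,
    outcome: str,
    covariates: list[str] | None = None,
    second_stage_family: str = "linear",
    min_n: int = 50,
) -> dict:
    """Independent two-stage fits per stratum plus a between-stratum contrast.

    The first stage is refit within each stratum (the instrument-exposure
    relation is exactly what the negative-control design expects to differ
    across strata).  Strata below ``min_n`` are skipped with a warning.
    Returns {"strata": {label: TSLSResult}, "contrast": {z, p, pair}}.
    """
    levels = [lv for lv in pd.unique(cohort[stratum_variable]) if pd.notna(lv)]
    if len(levels) < 2:
        raise ValueError(f"need >= 2 strata in {stratum_variable!r}, found {levels}")
    results: dict = {}
    for lv in levels:
        sub = cohort[cohort[stratum_variable] == lv]
        if len(sub) < min_n:
            warnings.warn(f"stratum {lv!r} has n={len(sub)} < {min_n}; skipped", stacklevel=2)
            continue
        cov = sub[covariates] if covariates else None
        results[lv] = tsls(
            sub[instrument].to_numpy(),
            sub[exposure].to_numpy(),
            sub[outcome].to_numpy(),
            covariates=cov,
            second_stage_family=second_stage_family,
        )
    contrast = None
    if len(results) >= 2:
        (la, ra), (lb, rb) = list(results.items())[:2]
        z = (ra.beta - rb.beta) / np.sqrt(ra.se**2 + rb.se**2)
        contrast = {"pair": (la, lb), "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}
    return {"strata": results, "contrast": contrast}


def select_sex_specific_instruments(
    male_stats: pd.DataFrame,
    female_stats: pd.DataFrame,
    interaction_alpha: float = 1e-5,
    f_min: float = 15.0,
) -> SexSpecificInstruments:
    """Variants with a gene-by-sex interaction, assigned to their stronger sex.

    Interaction z = (beta_m - beta_f) / sqrt(se_m^2 + se_f^2); variants
    with interaction p < interaction_alpha go to the sex with the larger
    |beta|/se and are retained only if (beta/se)^2 strictly exceeds
    ``f_min`` there.  An empty selection is returned with a warning, not
    an error.
    """
    m = male_stats.set_index("variant_id")
    f = female_stats.set_index("variant_id")
    shared = m.index.intersection(f.index)
    if len(shared) == 0:
        raise ValueError("no shared variants between male and female tables")
    m, f = m.loc[shared], f.loc[shared]

    z_int = (m["beta"] - f["beta"]) / np.sqrt(m["se"] ** 2 + f["se"] ** 2)
    p_int = pd.Series(2 * stats.norm.sf(np.abs(z_int)), index=shared, name="interaction_p")

    zm, zf = (m["beta"] / m["se"]).abs(), (f["beta"] / f["se"]).abs()
    hits = p_int.index[p_int < interaction_alpha]
    male_ids = [v for v in hits if zm[v] >= zf[v] and zm[v] ** 2 > f_min]
    female_ids = [v for v in hits if zf[v] > zm[v] and zf[v] ** 2 > f_min]
    if not male_ids and not female_ids:
        warnings.warn("no variant passed the interaction and F-statistic criteria", stacklevel=2)

    def _set(ids, table):
        out = table.loc[ids, ["beta", "se"]].copy()
        out.insert(0, "variant_id", ids)
        return out.reset_index(drop=True)

    return SexSpecificInstruments(
        male_set=_set(male_ids, m),
        female_set=_set(female_ids, f),
        interaction_p=p_int,
        f_threshold_used=f_min,
    )


def sex_stratified_mr(
    instruments: SexSpecificInstruments,
    male_outcome_stats: pd.DataFrame,
    female_outcome_stats: pd.DataFrame,
) -> dict:
    """Per-sex IVW on sex-specific instruments plus a fixed-effect combination.

    Each sex's IVW uses its own exposure weights (from the instrument
    sets) against its own outcome statistics; the combined estimate is the
    inverse-variance-weighted average of the per-sex estimates.  An empty
    sex is skipped and the combination equals the other sex's estimate.
    """
    from fallmr.mr2s import ivw

    per_sex: dict[str, MREstimate] = {}
    for label, ins, out_stats in (
        ("male", instruments.male_set, male_outcome_stats),
        ("female", instruments.female_set, female_outcome_stats),
    ):
        if ins.empty:
            continue
        merged = ins.merge(
            out_stats[["variant_id", "beta", "se"]],
            on="variant_id",
            suffixes=("_exp", "_out"),
        )
        if merged.empty:
            continue
        table = pd.DataFrame(
            {
                "beta_x": merged["beta_exp"],
                "se_x": merged["se_exp"],
                "beta_y": merged["beta_out"],
                "se_y": merged["se_out"],
            }
        )
        per_sex[label] = ivw(table)
    if not per_sex:
        raise ValueError("both per-sex instrument sets are empty or unmatched")

    betas = np.array([e.beta for e in per_sex.values()])
    ws = np.array([1.0 / e.se**2 for e in per_sex.values()])
    beta_c = float((ws * betas).sum() / ws.sum())
    se_c = float(np.sqrt(1.0 / ws.sum()))
    p_c = float(2 * stats.norm.sf(abs(beta_c) / se_c))
    combined = MREstimate(
        "IVW_sex_combined", beta_c, se_c, p_c,
        k_instruments=sum(e.k_instruments for e in per_sex.values()),
    )
    return {"per_sex": per_sex, "combined": combined}
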