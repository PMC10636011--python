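"""Two-sample Mendelian randomisation estimators on harmonized summary data.

The suite mirrors standard practice: inverse-variance weighting (IVW) as
the primary estimator, with MR-Egger, the weighted median (WM) and the
penalised weighted median (PWM) as pleiotropy-robust sensitivity analyses,
plus instrument-strength diagnostics (mean F) and the ln 2 "per doubling"
rescaling for binary exposures reported on the log-odds scale.

* IVW: beta = sum(w b_x b_y) / sum(w b_x^2) with w = 1/se_y^2, i.e. a
  weighted regression of outcome effects on exposure effects through the
  origin; under multiplicative random effects the SE is inflated by
  sqrt(Q / (k - 1)) when Cochran's Q exceeds its degrees of freedom.
* MR-Egger: the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and carries its own test.
  Instruments are re-oriented so every exposure effect is non-negative
  before fitting (the intercept is orientation-dependent).
* WM: the 50% point of the inverse-variance-weighted empirical
  distribution of per-variant ratio estimates, by linear interpolation of
  the standardized cumulative weights; SE by seeded parametric bootstrap.
* PWM: WM after multiplying each weight by min(1, q_j / penalty_alpha),
  where q_j is the upper-tail chi-square(1) probability of the variant's
  contribution to heterogeneity about the WM estimate — outlying
  instruments are smoothly down-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "harmonize",
    "ivw",
    "mr_egger",
    "weighted_median",
    "penalised_weighted_median",
    "mean_f_statistic",
    "scale_per_doubling",
    "MeanFResult",
]

_Z95 = stats.norm.ppf(0.975)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and scale metadata."""

    method: str
    beta: float
    se: float
    p: float
    k_instruments: int
    ci95: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    heterogeneity: dict = field(default_factory=dict)  # Q, df, p
    scale_note: str = "per_unit"   # per_SD | per_unit | per_doubling_log_odds
    exposure_binary: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.ci95 is None:
            self.ci95 = (self.beta - _Z95 * self.se, self.beta + _Z95 * self.se)
        lo, hi = self.ci95
        if np.isfinite(self.beta) and not (lo <= self.beta <= hi):
            raise ValueError("confidence interval does not bracket the estimate")
        if self.k_instruments < 1:
            raise ValueError("need at least one instrument")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    Swapped alleles flip the outcome beta's sign (and complement-strand
    matches are recognised); palindromic variants (A/T, C/G) whose
    exposure EAF falls inside the ambiguity window are dropped, since
    strand cannot be resolved there.  Every variant's action is logged in
    ``harmonization_action``.
    """
    lo, hi = palindromic_eaf_window
    exp = exposure_stats.set_index("variant_id")
    out = outcome_stats.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise ValueError("no shared variants between exposure and outcome tables")

    rows = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        yea, yoa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        cea, coa = _COMPLEMENT.get(yea), _COMPLEMENT.get(yoa)
        palin = _is_palindromic(ea, oa)

        if palin and lo <= float(e["eaf"]) <= hi:
            action, flip = "dropped_palindromic", None
        elif (yea, yoa) == (ea, oa):
            action, flip = "kept", False
        elif (yea, yoa) == (oa, ea):
            action, flip = "flipped", True
        elif not palin and (cea, coa) == (ea, oa):
            action, flip = "kept", False
        elif not palin and (cea, coa) == (oa, ea):
            action, flip = "flipped", True
        else:
            action, flip = "dropped_missing", None

        row = {
            "variant_id": vid,
            "effect_allele": ea,
            "other_allele": oa,
            "beta_x": float(e["beta"]),
            "se_x": float(e["se"]),
            "eaf": float(e["eaf"]),
            "harmonization_action": action,
        }
        if flip is None:
            row.update(beta_y=np.nan, se_y=np.nan)
        else:
            row.update(
                beta_y=-float(o["beta"]) if flip else float(o["beta"]),
                se_y=float(o["se"]),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _retained(instruments: pd.DataFrame) -> pd.DataFrame:
    if "harmonization_action" in instruments.columns:
        instruments = instruments[
            instruments["harmonization_action"].isin(["kept", "flipped"])
        ]
    return instruments.dropna(subset=["beta_x", "beta_y", "se_y"])


def _arrays(instruments: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ins = _retained(instruments)
    return (
        ins["beta_x"].to_numpy(float),
        ins["se_x"].to_numpy(float) if "se_x" in ins else np.full(len(ins), np.nan),
        ins["beta_y"].to_numpy(float),
        ins["se_y"].to_numpy(float),
    )


def ivw(instruments: pd.DataFrame, effects: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (weighted through-origin regression).

    With one instrument this degrades to the ratio estimate (noted as
    such); under ``multiplicative_random`` the SE is inflated by
    max(1, sqrt(Q/(k-1))).
    """
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k == 0:
        raise ValueError("no usable instruments")
    if k == 1:
        if bx[0] == 0:
            raise ValueError("single instrument with zero exposure effect: ratio undefined")
        beta = by[0] / bx[0]
        se = sy[0] / abs(bx[0])
        p = float(2 * stats.norm.sf(abs(beta) / se))
        return MREstimate("ratio", float(beta), float(se), p, 1, note="k=1: ratio estimate")

    w = 1.0 / sy**2
    beta = float((w * bx * by).sum() / (w * bx**2).sum())
    se_fixed = float(np.sqrt(1.0 / (w * bx**2).sum()))
    q = float((w * (by - beta * bx) ** 2).sum())
    q_p = float(stats.chi2.sf(q, df=k - 1))
    se = se_fixed
    if effects == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    elif effects != "fixed":
        raise ValueError(f"unknown effects model {effects!r}")
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate(
        "IVW", beta, se, p, k,
        heterogeneity={"Q": q, "df": k - 1, "p": q_p},
    )


def mr_egger(instruments: pd.DataFrame) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Weighted regression of outcome on exposure effects with a free
    intercept (weights 1/se_y^2), after re-orienting instruments so all
    exposure effects are non-negative.  SEs carry the estimated residual
    scale sqrt(Q/(k-2)) (untruncated, so the intercept test is exactly
    t(k-2)-calibrated under the no-pleiotropy null) with t(k-2) p-values.
    """
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError(f"MR-Egger needs at least 3 instruments, got {k}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1.0 / sy**2
    sw = w.sum()
    xm, ym = (w * bx).sum() / sw, (w * by).sum() / sw
    sxx = (w * (bx - xm) ** 2).sum()
    slope = float((w * (bx - xm) * (by - ym)).sum() / sxx)
    intercept = float(ym - slope * xm)

    resid = by - intercept - slope * bx
    q = float((w * resid**2).sum())
    disp = np.sqrt(q / (k - 2))
    se_slope = float(np.sqrt(1.0 / sxx)) * disp
    se_int = float(np.sqrt(1.0 / sw + xm**2 / sxx)) * disp
    p_slope = float(2 * stats.t.sf(abs(slope) / se_slope, df=k - 2))
    p_int = float(2 * stats.t.sf(abs(intercept) / se_int, df=k - 2))
    het = {"Q": q, "df": k - 2, "p": float(stats.chi2.sf(q, df=k - 2))}
    tcrit = stats.t.ppf(0.975, df=k - 2)
    slope_est = MREstimate(
        "Egger_slope", slope, se_slope, p_slope, k,
        ci95=(slope - tcrit * se_slope, slope + tcrit * se_slope),
        heterogeneity=het,
    )
    int_est = MREstimate(
        "Egger_intercept", intercept, se_int, p_int, k,
        ci95=(intercept - tcrit * se_int, intercept + tcrit * se_int),
        heterogeneity=het,
        note="pleiotropy test",
    )
    return slope_est, int_est


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50% point of the weighted empirical ratio distribution (interpolated)."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / w.sum()
    return float(np.interp(0.5, cum, r))


def _ratio_weights(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ratios = by / bx
    weights = bx**2 / sy**2   # inverse variance of the ratio (leading order)
    return ratios, weights


def weighted_median(
    instruments: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    _weights: np.ndarray | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError(f"weighted median needs at least 3 instruments, got {k}")
    ratios, weights = _ratio_weights(bx, by, sy)
    if _weights is not None:
        weights = _weights
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    sx_eff = np.where(np.isfinite(sx), sx, 0.0)
    for b in range(n_boot):
        bxb = bx + rng.standard_normal(k) * sx_eff
        byb = by + rng.standard_normal(k) * sy
        rb, wb = _ratio_weights(bxb, byb, sy)
        if _weights is not None:
            wb = _weights
        boots[b] = _weighted_median_point(rb, wb)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan
    return MREstimate("WM", beta, se, p, k)


def penalisation_factors(
    instruments: pd.DataFrame, penalty_alpha: float = 0.05
) -> np.ndarray:
    """Per-instrument penalty factors min(1, q_j / penalty_alpha).

    q_j is the upper-tail chi-square(1) probability of instrument j's
    weighted squared deviation from the (unpenalised) weighted-median
    estimate; instruments consistent with it keep factor 1.
    """
    bx, _, by, sy = _arrays(instruments)
    ratios, weights = _ratio_weights(bx, by, sy)
    beta_wm = _weighted_median_point(ratios, weights)
    q_contrib = weights * (ratios - beta_wm) ** 2
    q_prob = stats.chi2.sf(q_contrib, df=1)
    return np.minimum(1.0, q_prob / penalty_alpha)


def penalised_weighted_median(
    instruments: pd.DataFrame,
    penalty_alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median with heterogeneity-penalised weights."""
    bx, _, by, sy = _arrays(instruments)
    if len(bx) < 3:
        raise ValueError(f"penalised weighted median needs at least 3 instruments, got {len(bx)}")
    _, weights = _ratio_weights(bx, by, sy)
    penal = weights * penalisation_factors(instruments, penalty_alpha)
    est = weighted_median(instruments, n_boot=n_boot, seed=seed, _weights=penal)
    return replace(est, method="PWM")


@dataclass
class MeanFResult:
    mean_f: float
    cragg_donald: float | None = None

    def __float__(self) -> float:
        return self.mean_f


def mean_f_statistic(instruments: pd.DataFrame, n_exposure: int | None = None) -> MeanFResult:
    """Mean per-instrument F = mean (beta_x / se_x)^2.

    When the exposure GWAS sample size and EAFs are available, also
    reports the Cragg-Donald-style approximation from the summed variance
    explained.
    """
    ins = _retained(instruments)
    bx = ins["beta_x"].to_numpy(float)
    sx = ins["se_x"].to_numpy(float)
    if np.any(sx <= 0):
        raise ValueError("se_x must be positive")
    mean_f = float(np.mean((bx / sx) ** 2))
    cd = None
    if n_exposure is not None and "eaf" in ins.columns:
        eaf = ins["eaf"].to_numpy(float)
        r2 = float(np.sum(2.0 * eaf * (1.0 - eaf) * bx**2))
        r2 = min(r2, 0.99)
        k = len(bx)
        cd = float(r2 / k * (n_exposure - k - 1) / (1.0 - r2))
    return MeanFResult(mean_f=mean_f, cragg_donald=cd)


LN2 = float(np.log(2.0))


def scale_per_doubling(estimate: MREstimate) -> MREstimate:
    """Rescale a binary-exposure log-odds estimate to the per-doubling scale.

    Multiplies beta, SE and CI by ln 2 = 0.693...; the z statistic and p
    are unchanged.  Refuses continuous-exposure estimates and estimates
    already on the per-doubling scale (guards against double-scaling).
    """
    if not estimate.exposure_binary:
        raise ValueError("per-doubling scaling applies only to binary exposures on the log-odds scale")
    if estimate.scale_note == "per_doubling_log_odds":
        raise ValueError("estimate is already on the per-doubling scale")
    lo, hi = estimate.ci95
    return replace(
        estimate,
        beta=estimate.beta * LN2,
        se=estimate.se * LN2,
        ci95=(lo * LN2, hi * LN2),
        scale_note="per_doubling_log_odds",
    )
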