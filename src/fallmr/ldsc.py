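"""LD score regression: SNP heritability and cross-trait genetic correlation.

For heritability, the expected GWAS chi-square of variant j is
``1 + n h2 l_j / m`` (plus an intercept term absorbing confounding), where
``l_j`` is the variant's LD score — the sum of adjusted squared
correlations with variants in a window around it, including itself.  A
weighted regression of chi-square on ``n l / m`` therefore estimates h2
from its slope; the cross-trait analogue regresses the z-score product of
two traits and yields the genetic covariance, whose normalised version is
the genetic correlation rg.  Uncertainty comes from a leave-one-block-out
jackknife over contiguous variant blocks.

LD scores are computed from the analysis genotypes themselves (no external
reference panel), with the small-sample adjustment
``r2_adj = r2 - (1 - r2) / (n - 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_ld_scores",
    "estimate_h2",
    "estimate_rg",
    "bonferroni_report",
    "h2_observed_to_liability",
    "HeritabilityResult",
    "GeneticCorrelationResult",
]


@dataclass
class HeritabilityResult:
    h2_observed: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_blocks: int

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("jackknife needs at least 2 blocks")


@dataclass
class GeneticCorrelationResult:
    rg: float
    gencov: float
    se: float
    p: float
    h2_a: float
    h2_b: float
    cross_intercept: float
    n_blocks: int
    se_cross_intercept: float = np.nan
    significant_bonferroni: bool | None = None
    flag: str = ""


def compute_ld_scores(dosages: np.ndarray, window: int = 50) -> pd.DataFrame:
    """Windowed adjusted-r2 LD scores from a dosage matrix.

    score_j = sum over |k - j| <= window of r2_adj(j, k), including the
    self term (which the adjustment leaves at exactly 1).
    """
    G = np.asarray(dosages, dtype=float)
    n, m = G.shape
    if n <= 2:
        raise ValueError("need more than 2 individuals to adjust r2")
    sd = G.std(axis=0)
    sd[sd == 0] = np.nan
    Z = (G - G.mean(axis=0)) / sd

    scores = np.full(m, 1.0)  # self term: r2=1 -> adjusted 1
    adj = lambda r2: r2 - (1.0 - r2) / (n - 2)
    for lag in range(1, min(window, m - 1) + 1):
        r = np.einsum("ij,ij->j", Z[:, :-lag], Z[:, lag:]) / n
        r2a = adj(r**2)
        scores[: m - lag] += r2a
        scores[lag:] += r2a
    return pd.DataFrame({"ld_score": scores})


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(slope), float(ym - slope * xm)


def _jackknife(values: np.ndarray) -> float:
    b = len(values)
    return float(np.sqrt((b - 1) / b * ((values - values.mean()) ** 2).sum()))


def _block_bounds(m: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _h2_weights(x: np.ndarray, ld: np.ndarray, h2: float) -> np.ndarray:
    # heteroskedasticity weights 1/(l * (1 + n h2 l/m)^2), one two-step update
    return 1.0 / (np.maximum(ld, 1.0) * (1.0 + np.maximum(h2, 0.0) * x) ** 2)


def estimate_h2(
    sumstats: pd.DataFrame,
    ldscores: pd.DataFrame | np.ndarray,
    n: int,
    m_variants: int | None = None,
    n_blocks: int = 20,
) -> HeritabilityResult:
    """SNP heritability from the slope of chi-square on n*l/m.

    ``sumstats`` must carry beta and se on aligned variants; ``m_variants``
    defaults to the number of regression variants.  Two-step
    heteroskedasticity weighting, block-jackknife SEs.
    """
    ld = np.asarray(ldscores["ld_score"] if isinstance(ldscores, pd.DataFrame) else ldscores, dtype=float)
    chi2 = (np.asarray(sumstats["beta"], dtype=float) / np.asarray(sumstats["se"], dtype=float)) ** 2
    m = len(chi2)
    if len(ld) != m:
        raise ValueError("summary statistics and LD scores are not aligned")
    if m < n_blocks:
        raise ValueError(f"fewer variants ({m}) than jackknife blocks ({n_blocks})")
    M = m_variants if m_variants is not None else m
    x = n * ld / M

    w = _h2_weights(x, ld, 0.0)
    slope, _ = _wls(x, chi2, w)
    w = _h2_weights(x, ld, slope)
    slope, intercept = _wls(x, chi2, w)

    bounds = _block_bounds(m, n_blocks)
    jk = np.empty((n_blocks, 2))
    for b, (lo, hi) in enumerate(bounds):
        mask = np.ones(m, dtype=bool)
        mask[lo:hi] = False
        jk[b] = _wls(x[mask], chi2[mask], w[mask])
    return HeritabilityResult(
        h2_observed=slope,
        intercept=intercept,
        se_h2=_jackknife(jk[:, 0]),
        se_intercept=_jackknife(jk[:, 1]),
        n_blocks=n_blocks,
    )


def estimate_rg(
    sumstats_a: pd.DataFrame,
    sumstats_b: pd.DataFrame,
    ldscores: pd.DataFrame | np.ndarray,
    n_a: int,
    n_b: int,
    m_variants: int | None = None,
    n_blocks: int = 20,
) -> GeneticCorrelationResult:
    """Cross-trait LD score regression: rg = gencov / sqrt(h2_a * h2_b).

    The z-score product is regressed on sqrt(n_a n_b) l / m; its slope is
    the genetic covariance and its intercept absorbs sample overlap.  The
    weights are the geometric combination of the two traits' h2 weights so
    that rg(a, a) is exactly 1.  The jackknife re-estimates all three
    regressions per left-out block; p is a normal-theory test of rg = 0.
    """
    ld = np.asarray(ldscores["ld_score"] if isinstance(ldscores, pd.DataFrame) else ldscores, dtype=float)
    za = np.asarray(sumstats_a["beta"], dtype=float) / np.asarray(sumstats_a["se"], dtype=float)
    zb = np.asarray(sumstats_b["beta"], dtype=float) / np.asarray(sumstats_b["se"], dtype=float)
    m = len(za)
    if not (len(zb) == m == len(ld)):
        raise ValueError("summary statistics and LD scores are not aligned")
    if m < n_blocks:
        raise ValueError(f"fewer variants ({m}) than jackknife blocks ({n_blocks})")
    M = m_variants if m_variants is not None else m

    xa, xb = n_a * ld / M, n_b * ld / M
    xab = np.sqrt(n_a * n_b) * ld / M

    def _fit(mask: np.ndarray) -> tuple[float, float, float, float]:
        wa = _h2_weights(xa[mask], ld[mask], 0.0)
        h2a0, _ = _wls(xa[mask], za[mask] ** 2, wa)
        wb = _h2_weights(xb[mask], ld[mask], 0.0)
        h2b0, _ = _wls(xb[mask], zb[mask] ** 2, wb)
        wa = _h2_weights(xa[mask], ld[mask], h2a0)
        wb = _h2_weights(xb[mask], ld[mask], h2b0)
        h2a, _ = _wls(xa[mask], za[mask] ** 2, wa)
        h2b, _ = _wls(xb[mask], zb[mask] ** 2, wb)
        wab = np.sqrt(wa * wb)
        gencov, icpt = _wls(xab[mask], (za * zb)[mask], wab)
        return h2a, h2b, gencov, icpt

    full = np.ones(m, dtype=bool)
    h2a, h2b, gencov, cross_icpt = _fit(full)
    if h2a <= 0 or h2b <= 0:
        return GeneticCorrelationResult(
            rg=np.nan, gencov=gencov, se=np.nan, p=np.nan,
            h2_a=h2a, h2_b=h2b, cross_intercept=cross_icpt,
            n_blocks=n_blocks, flag="h2_nonpositive",
        )
    rg = gencov / np.sqrt(h2a * h2b)

    bounds = _block_bounds(m, n_blocks)
    jk = np.empty(n_blocks)
    jk_icpt = np.empty(n_blocks)
    for b, (lo, hi) in enumerate(bounds):
        mask = np.ones(m, dtype=bool)
        mask[lo:hi] = False
        ja, jb_, jcov, jicpt = _fit(mask)
        jk[b] = jcov / np.sqrt(max(ja, 1e-12) * max(jb_, 1e-12))
        jk_icpt[b] = jicpt
    se = _jackknife(jk)
    p = float(2.0 * stats.norm.sf(abs(rg) / se)) if se > 0 else np.nan
    return GeneticCorrelationResult(
        rg=float(rg), gencov=float(gencov), se=se, p=p,
        h2_a=float(h2a), h2_b=float(h2b), cross_intercept=float(cross_icpt),
        n_blocks=n_blocks, se_cross_intercept=_jackknife(jk_icpt),
    )


def bonferroni_report(
    results,
    n_tests: int = 12,
    alpha: float = 0.05,
):
    """Flag results significant at the Bonferroni threshold alpha / n_tests.

    With the default 12 tests the threshold is 0.05/12 ≈ 0.0042; strict
    inequality.  Accepts a DataFrame with a ``p`` column (returns it
    annotated plus the threshold) or a list of GeneticCorrelationResult.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    if isinstance(results, pd.DataFrame):
        out = results.copy()
        out["significant_bonferroni"] = out["p"] < threshold
        out.attrs["bonferroni_threshold"] = threshold
        return out, threshold
    for r in results:
        r.significant_bonferroni = bool(r.p < threshold) if np.isfinite(r.p) else False
    return results, threshold


def h2_observed_to_liability(h2_obs: float, pop_prevalence: float, sample_prevalence: float) -> float:
    """Observed-scale to liability-scale heritability (case-control design)."""
    k, p = pop_prevalence, sample_prevalence
    if not (0 < k < 1 and 0 < p < 1):
        raise ValueError("prevalences must lie in (0, 1)")
    t = stats.norm.isf(k)
    z = stats.norm.pdf(t)
    return float(h2_obs * k**2 * (1 - k) ** 2 / (z**2 * p * (1 - p)))
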