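"""Variant QC, Firth-penalised per-variant association, observational models.

The per-variant scan applies Firth's Jeffreys-prior penalty to the logistic
likelihood, which keeps estimates finite under separation and reduces
small-sample bias in heavily unbalanced case/control designs such as a
~10%-prevalence fall phenotype.  P-values come from the penalised
likelihood-ratio test, which is better calibrated than the Wald statistic
in exactly the unbalanced settings the penalty targets.

QC follows the strict-inequality rule: a variant is excluded iff
INFO < 0.3 or MAF < 0.1% (boundary values are retained).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "variant_qc",
    "firth_fit",
    "firth_logistic_assoc",
    "linear_assoc_scan",
    "observational_model",
    "flag_gws",
    "RegressionResult",
    "GWS_ALPHA",
]

GWS_ALPHA = 5e-8


# ---------------------------------------------------------------------------
# variant QC


def variant_qc(
    variants: pd.DataFrame,
    info_min: float = 0.3,
    maf_min: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply INFO / MAF exclusion filters; returns (retained, exclusion_log).

    MAF is ``min(eaf, 1 - eaf)``.  Exclusion uses strict inequality, so a
    variant sitting exactly on a threshold is retained.  Variants with
    missing INFO or EAF are excluded with reason "missing".
    """
    info = pd.to_numeric(variants.get("info", pd.Series(np.nan, index=variants.index)), errors="coerce")
    eaf = pd.to_numeric(variants.get("eaf", pd.Series(np.nan, index=variants.index)), errors="coerce")
    maf = np.minimum(eaf, 1.0 - eaf)

    missing = info.isna() | eaf.isna()
    fail_info = (~missing) & (info < info_min)
    fail_maf = (~missing) & (maf < maf_min)

    reasons = np.select(
        [missing, fail_info & fail_maf, fail_info, fail_maf],
        ["missing", "info;maf", "info", "maf"],
        default="",
    )
    excluded_mask = reasons != ""
    exclusion_log = pd.DataFrame(
        {"variant_id": variants.loc[excluded_mask, "variant_id"], "reason": reasons[excluded_mask]}
    ).reset_index(drop=True)
    retained = variants.loc[~excluded_mask].reset_index(drop=True)
    return retained, exclusion_log


# ---------------------------------------------------------------------------
# Firth logistic regression


def _firth_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Penalised log-likelihood: l(beta) + 0.5 * log det X'WX (Jeffreys prior)."""
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    _, logdet = np.linalg.slogdet(X.T * w @ X)
    return ll + 0.5 * logdet


def firth_fit(
    X: np.ndarray,
    y: np.ndarray,
    free: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton solver for the Jeffreys-penalised logistic likelihood.

    Returns (beta, covariance, penalised log-likelihood, converged).  The
    modified score is ``X'(y - p + h (1/2 - p))`` with h the hat-diagonal
    of the weighted design; covariance is the inverse penalised
    information.  Step-halving protects against likelihood decreases.

    ``free`` (boolean mask over columns) restricts the maximisation to a
    subset of coefficients with the rest fixed at zero while the Jeffreys
    penalty still uses the full design — the constrained fit needed by
    the penalised likelihood-ratio test.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if free is None:
        free = np.ones(k, dtype=bool)
    beta = np.zeros(k)
    pll = _firth_loglik(beta, X, y)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = X.T * w @ X
        info_inv = np.linalg.inv(info)
        # hat diagonal: h_i = w_i * x_i' (X'WX)^-1 x_i
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = (X.T @ (y - p + h * (0.5 - p)))[free]
        if np.linalg.norm(score) < tol:
            converged = True
            break
        step = np.zeros(k)
        step[free] = np.linalg.solve(info[np.ix_(free, free)], score)
        for _half in range(25):
            cand = beta + step
            cand_pll = _firth_loglik(cand, X, y)
            if cand_pll >= pll - 1e-12:
                break
            step = step / 2.0
        beta, pll = cand, cand_pll
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T * w @ X)
    return beta, cov, pll, converged


def firth_logistic_assoc(
    dosages: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variant_ids=None,
) -> pd.DataFrame:
    """Per-variant Firth association scan with penalised-LRT p-values.

    ``status`` is 0/1 (or "case"/"control").  The covariate-only penalised
    fit is shared across variants as the LRT null.  Monomorphic variants
    are flagged and carry no estimate.
    """
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    y = np.asarray(status)
    if y.dtype == object or y.dtype.kind in "US":
        y = (y == "case").astype(float)
    y = y.astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")

    n, m = dosages.shape
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if not np.any(C.std(axis=0) == 0):  # ensure an intercept column
            C = np.column_stack([np.ones(n), C])

    ids = variant_ids if variant_ids is not None else [f"v{j}" for j in range(m)]
    rows = []
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    for j in range(m):
        g = dosages[:, j]
        if np.ptp(g) == 0:
            rows.append({"variant_id": ids[j], "beta": np.nan, "se": np.nan, "p": np.nan,
                         "n_cases": n_cases, "n_controls": n_controls, "flag": "monomorphic"})
            continue
        X = np.column_stack([g, C])
        beta, cov, pll, converged = firth_fit(X, y)
        free_null = np.ones(X.shape[1], dtype=bool)
        free_null[0] = False
        _, _, pll_null, _ = firth_fit(X, y, free=free_null)
        lrt = max(2.0 * (pll - pll_null), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        rows.append({"variant_id": ids[j], "beta": float(beta[0]), "se": float(np.sqrt(cov[0, 0])),
                     "p": p, "n_cases": n_cases, "n_controls": n_controls,
                     "flag": "" if converged else "not_converged"})
    out = pd.DataFrame(rows)
    return flag_gws(out)


def linear_assoc_scan(dosages: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Vectorised marginal simple-regression scan (beta, se, p, n per variant)."""
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    gv = G.var(axis=0)
    yc = y - y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G - G.mean(axis=0)).T @ yc / (n * gv)
        resid_var = (yc @ yc / n - beta**2 * gv) * n / (n - 2)
        se = np.sqrt(resid_var / (n * gv))
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"beta": beta, "se": se, "pvalue": p, "n": n})
    out.loc[gv == 0, ["beta", "se", "pvalue"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# observational regressions


@dataclass
class RegressionResult:
    """Exposure-outcome regression on the ratio scale (OR or rate ratio)."""

    exposure: str
    scale: str                      # per_SD | per_unit | per_category
    ratio: float                    # exp(coefficient)
    ci95: tuple[float, float]
    p: float
    model: str                      # logistic | poisson | linear
    beta: float
    se: float
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.ratio <= hi):
            raise ValueError("confidence interval does not bracket the estimate")


def observational_model(
    exposure: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    family: str = "logistic",
    standardize: bool = True,
    exposure_name: str = "exposure",
) -> RegressionResult:
    """Fit the observational exposure-outcome regression with covariate adjustment.

    ``family`` is "logistic" for a binary outcome, "poisson" for counts, or
    "linear".  With ``standardize`` the exposure is z-scored first and the
    effect is per SD.  The ratio is exp(coefficient) with a Wald 95% CI
    (for the linear family the coefficient itself is reported as ``beta``
    and ``ratio`` is exp(beta) for table uniformity).
    """
    import statsmodels.api as sm

    x = np.asarray(exposure, dtype=float)
    yv = np.asarray(outcome, dtype=float)
    if family == "logistic":
        fam = sm.families.Binomial()
        if not set(np.unique(yv)) <= {0.0, 1.0}:
            raise ValueError("logistic family requires a binary outcome")
    elif family == "poisson":
        fam = sm.families.Poisson()
        if np.any(yv < 0) or np.any(yv != np.round(yv)):
            raise ValueError("poisson family requires a non-negative integer outcome")
    elif family == "linear":
        fam = sm.families.Gaussian()
    else:
        raise ValueError(f"unknown family {family!r}")

    if standardize:
        x = (x - x.mean()) / x.std()
        scale = "per_SD"
    else:
        scale = "per_unit"

    design = pd.DataFrame({"const": np.ones(len(x)), "exposure": x})
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        cov = covariates.copy()
        for c in cov.columns:
            if cov[c].dtype == object or cov[c].dtype.name == "category":
                cov[c] = cov[c].astype("category").cat.codes
        design = pd.concat([design.reset_index(drop=True), cov.reset_index(drop=True).astype(float)], axis=1)
        cov_names = tuple(covariates.columns)

    fit = sm.GLM(yv, design, family=fam).fit()
    beta = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return RegressionResult(
        exposure=exposure_name,
        scale=scale,
        ratio=float(np.exp(beta)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p=float(fit.pvalues["exposure"]),
        model=family,
        beta=beta,
        se=se,
        covariates=cov_names,
    )


def flag_gws(results: pd.DataFrame, alpha: float = GWS_ALPHA) -> pd.DataFrame:
    """Annotate genome-wide significance by strict inequality p < alpha."""
    results = results.copy()
    pcol = "p" if "p" in results.columns else "pvalue"
    if results.empty:
        results["gws_flag"] = pd.Series(dtype=bool)
        return results
    results["gws_flag"] = results[pcol] < alpha
    results.loc[results[pcol].isna(), "gws_flag"] = False
    return results
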