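"""Configuration-driven orchestration of the full analysis pipeline.

Stages run in dependency order on synthetic inputs with known truth:
synthdata -> phenotyping -> assoc -> ldsc -> mr2s / mr1s / mroverlap ->
report.  Every stage's parameters and seed are logged; report tables are
TSV with the field's usual formatting (integer percentages in the
demographics table, odds ratios to 3 decimals in the MR forest table,
Bonferroni significance flags on the genetic-correlation table).
Bidirectional MR (falls as the exposure) is the same estimator code with
the roles of the two summary tables swapped, driven by a config flag.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fallmr import assoc, io, ldsc, mr1s, mr2s, mroverlap, phenotyping, synthdata

logger = logging.getLogger("fallmr")

ALL_STAGES = ("synthdata", "phenotyping", "assoc", "ldsc", "mr2s", "mr1s", "mroverlap", "report")


@dataclass
class RunConfig:
    """One YAML-loadable object governing a full pipeline run."""

    seed: int = 0
    outdir: str = "fallmr_run"
    stages: tuple[str, ...] = ALL_STAGES
    n_individuals: int = 4000
    n_variants: int = 400
    ld_block_size: int = 10
    within_block_r: float = 0.6
    case_prevalence: float = 0.10
    exposure_h2: float = 0.2
    confounder_effect_x: float = 0.3
    confounder_effect_y: float = 0.3
    true_causal_effect: float = 0.2
    overlap_fraction: float = 0.0
    selection_pvalue: float = 1e-3
    n_firth_variants: int = 20
    bidirectional: bool = True
    bonferroni_n_tests: int = 12

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if "mr2s" in self.stages and "synthdata" not in self.stages:
            raise ValueError("mr2s requires the synthdata stage to supply summary statistics")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"{path}: unknown config key(s) {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def format_ratio(x: float) -> str:
    """Report an odds/rate ratio to 3 decimals (1.2615 -> '1.262')."""
    return f"{x:.3f}"


def _mr_row(analysis: str, exposure: str, outcome: str, est: mr2s.MREstimate) -> dict:
    lo, hi = est.ci95
    return {
        "analysis": analysis,
        "exposure": exposure,
        "outcome": outcome,
        "method": est.method,
        "estimate_or": format_ratio(float(np.exp(est.beta))),
        "beta": est.beta,
        "se": est.se,
        "ci_low": lo,
        "ci_high": hi,
        "p": est.p,
        "k": est.k_instruments,
        "Q": est.heterogeneity.get("Q", np.nan),
        "Q_p": est.heterogeneity.get("p", np.nan),
        "scale_note": est.scale_note,
        "notes": est.note,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; writes TSV report tables under outdir.

    Returns the in-memory result bundle keyed by stage.  Failure of one
    exposure's MR analysis is logged and does not abort the others.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    logger.info("pipeline start: seed=%d stages=%s", config.seed, config.stages)

    sim = synthdata.SimConfig(
        n_individuals=config.n_individuals,
        n_variants=config.n_variants,
        ld_block_size=config.ld_block_size,
        within_block_r=config.within_block_r,
        case_prevalence=config.case_prevalence,
        exposure_h2=config.exposure_h2,
        confounder_effect_x=config.confounder_effect_x,
        confounder_effect_y=config.confounder_effect_y,
        true_causal_effect=config.true_causal_effect,
        overlap_fraction=config.overlap_fraction,
        selection_pvalue=1.0,
        seed=config.seed,
    )

    if "synthdata" in config.stages:
        cohort = synthdata.simulate_traits(synthdata.simulate_genotypes(sim), sim)
        codes = phenotyping.default_code_list()
        events, no_records = synthdata.simulate_event_log(cohort, codes, seed=config.seed + 10)
        pair = synthdata.simulate_sumstats_pair(sim)
        results["synthdata"] = {
            "cohort": cohort, "codes": codes, "events": events,
            "no_records": no_records, "pair": pair,
        }
        io.write_cohort_csv(cohort.data, out / "cohort.csv")
        events.to_csv(out / "events.csv", index=False)
        codes.entries.to_csv(out / "code_list.csv", index=False)
        io.write_sumstats(pair.exposure_stats, out / "exposure_sumstats.tsv")
        io.write_sumstats(pair.outcome_stats, out / "outcome_sumstats.tsv")
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in pair.truth.items()}
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump({"sumstats_pair": truth, "seed": config.seed}, fh)
        logger.info("synthdata: n=%d cases=%d", config.n_individuals, int(cohort.case_mask.sum()))

    if "phenotyping" in config.stages:
        sd = results["synthdata"]
        pheno = phenotyping.derive_fall_status(
            sd["events"], sd["codes"],
            all_persons=sd["cohort"].data["person_id"],
        )
        rng = np.random.default_rng(config.seed + 20)
        status = pheno.set_index("person_id")["status"]
        selfreport = pd.Series(
            np.where(status == "case", rng.random(len(status)) < 0.31, rng.random(len(status)) < 0.001),
            index=status.index,
        )
        xtab = phenotyping.cross_tabulate(pheno, selfreport)
        cov = sd["cohort"].data.set_index("person_id")[["age", "sex", "exposure"]]
        demo = phenotyping.summarize_cohort(pheno, cov)
        results["phenotyping"] = {"phenotype": pheno, "cross_tab": xtab, "demographics": demo}
        pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
        demo.to_csv(out / "table_demographics.tsv", sep="\t", index=False)

    if "assoc" in config.stages:
        sd = results["synthdata"]
        cohort = sd["cohort"]
        retained, excl = assoc.variant_qc(cohort.variants)
        covs = pd.DataFrame({
            "age": cohort.data["age"].to_numpy(),
            "sex": (cohort.data["sex"] == "male").astype(float).to_numpy(),
        })
        idx = retained.index[: config.n_firth_variants]
        scan = assoc.firth_logistic_assoc(
            cohort.dosages[:, idx],
            cohort.data["fall_status"].to_numpy(),
            covariates=covs,
            variant_ids=retained.loc[idx, "variant_id"].tolist(),
        )
        obs_logistic = assoc.observational_model(
            cohort.data["exposure"], (cohort.data["fall_status"] == "case").astype(int),
            covariates=covs, family="logistic", exposure_name="exposure",
        )
        cases = cohort.data[cohort.data["fall_status"] == "case"]
        obs_poisson = assoc.observational_model(
            cases["exposure"], cases["fall_count"].astype(int),
            covariates=covs.loc[cases.index], family="poisson", exposure_name="exposure",
        )
        results["assoc"] = {
            "qc_retained": retained, "qc_excluded": excl, "firth": scan,
            "observational": [obs_logistic, obs_poisson],
        }
        excl.to_csv(out / "variant_exclusions.tsv", sep="\t", index=False)
        scan.to_csv(out / "table_gws_hits.tsv", sep="\t", index=False)

    if "ldsc" in config.stages:
        corr = synthdata.simulate_correlated_gwas(sim, rg_true=0.7)
        scores = ldsc.compute_ld_scores(corr["dosages"], window=2 * config.ld_block_size)
        h2 = ldsc.estimate_h2(corr["stats_a"], scores, n=config.n_individuals)
        rg = ldsc.estimate_rg(corr["stats_a"], corr["stats_b"], scores,
                              n_a=config.n_individuals, n_b=config.n_individuals)
        [rg], threshold = ldsc.bonferroni_report([rg], n_tests=config.bonferroni_n_tests)
        results["ldsc"] = {"ld_scores": scores, "h2": h2, "rg": rg, "bonferroni_threshold": threshold}
        pd.DataFrame([{
            "trait_1": "exposure", "trait_2": "falls", "rg": rg.rg, "se": rg.se, "p": rg.p,
            "h2_1": rg.h2_a, "h2_2": rg.h2_b,
            "significant_bonferroni": rg.significant_bonferroni,
            "bonferroni_threshold": threshold,
        }]).to_csv(out / "table_genetic_correlations.tsv", sep="\t", index=False)

    if "mr2s" in config.stages:
        pair = results["synthdata"]["pair"]
        rows = []
        directions = [("exposure", "falls", pair.exposure_stats, pair.outcome_stats)]
        if config.bidirectional:
            directions.append(("falls", "exposure", pair.outcome_stats, pair.exposure_stats))
        for exp_name, out_name, exp_ss, out_ss in directions:
            try:
                exp_sel = exp_ss[exp_ss["pvalue"] < config.selection_pvalue]
                ins = mr2s.harmonize(exp_sel, out_ss)
                ests = [mr2s.ivw(ins)]
                if len(ins) >= 3:
                    slope, icpt = mr2s.mr_egger(ins)
                    ests += [slope, icpt,
                             mr2s.weighted_median(ins, seed=config.seed + 30),
                             mr2s.penalised_weighted_median(ins, seed=config.seed + 31)]
                fstat = mr2s.mean_f_statistic(ins)
                for est in ests:
                    row = _mr_row("two_sample", exp_name, out_name, est)
                    row["mean_F"] = fstat.mean_f
                    rows.append(row)
            except Exception:  # one direction failing must not abort the other
                logger.exception("mr2s failed for %s -> %s", exp_name, out_name)
        table = pd.DataFrame(rows)
        results["mr2s"] = {"table": table}
        table.to_csv(out / "table_mr_forest.tsv", sep="\t", index=False)

    if "mr1s" in config.stages:
        cohort = results["synthdata"]["cohort"]
        weights = cohort.truth["variant_effects"]
        score = mr1s.build_allele_score(cohort.dosages, weights, standardize=True)
        covs = pd.DataFrame({
            "age": cohort.data["age"].to_numpy(),
            "sex": (cohort.data["sex"] == "male").astype(float).to_numpy(),
        })
        binary = (cohort.data["fall_status"] == "case").astype(int).to_numpy()
        fits = {
            "logistic": mr1s.tsls(score, cohort.data["exposure"].to_numpy(), binary,
                                  covariates=covs, second_stage_family="logistic"),
            "poisson": mr1s.tsls(score, cohort.data["exposure"].to_numpy(),
                                 cohort.data["fall_count"].to_numpy(),
                                 covariates=covs, second_stage_family="poisson"),
        }
        results["mr1s"] = {"tsls": fits}
        pd.DataFrame([
            {"method": "TSLS", "family": fam, "beta": r.beta, "or": format_ratio(float(np.exp(r.beta))),
             "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p": r.p, "F": r.first_stage_F, "n": r.n}
            for fam, r in fits.items()
        ]).to_csv(out / "table_mr_one_sample.tsv", sep="\t", index=False)

    if "mroverlap" in config.stages:
        pair = results["synthdata"]["pair"]
        scores = pd.DataFrame({"ld_score": pair.truth["ld_scores"]})
        res = mroverlap.corrected_ivw(
            pair.exposure_stats, pair.outcome_stats, scores,
            n_x=sim.n_exposure_gwas, n_y=sim.n_outcome_gwas,
            selection_threshold=config.selection_pvalue,
        )
        results["mroverlap"] = res
        rows = [_mr_row("mr_overlap_corrected", "exposure", "falls", res.observed)]
        if res.corrected is not None:
            row = _mr_row("mr_overlap_corrected", "exposure", "falls", res.corrected)
            row["difference_p"] = res.difference_p
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "table_mr_overlap.tsv", sep="\t", index=False)

    if "report" in config.stages:
        written = sorted(p.name for p in out.glob("table_*.tsv"))
        results["report"] = {"tables": written}
        logger.info("report tables: %s", written)

    return results
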