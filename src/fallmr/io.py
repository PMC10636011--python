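"""Standard-format I/O: summary-statistics TSV, cohort/event CSV, YAML truth.

Column contracts
----------------
summary statistics (TSV): variant_id, chrom, pos, effect_allele,
    other_allele, eaf, beta, se, pvalue, n [, info]
event log (CSV): person_id, source, vocabulary, code, event_date (ISO 8601)
code list (CSV): vocabulary, code, category, description
phenotype (TSV): one row per person
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("fallmr")

SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

__all__ = ["read_sumstats", "write_sumstats", "read_cohort_csv", "write_cohort_csv",
           "SUMSTATS_COLUMNS"]


def read_sumstats(path) -> pd.DataFrame:
    """Read and validate a summary-statistics TSV.

    Missing required columns raise a named error; malformed rows
    (non-positive SE, EAF outside (0,1), unparsable numbers) are rejected
    with their line numbers logged.  Alleles are uppercased and positions
    kept 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    numeric = ["pos", "eaf", "beta", "se", "pvalue", "n"] + (["info"] if "info" in df.columns else [])
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    bad = df[numeric].isna().any(axis=1)
    bad |= df["se"] <= 0
    bad |= ~df["eaf"].between(0, 1, inclusive="neither")
    bad |= df["pos"] < 1
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s", path, int(bad.sum()), lines[:20])
        df = df[~bad]

    df = df.copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return df.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistics table in the canonical TSV column order."""
    cols = SUMSTATS_COLUMNS + [c for c in ("info",) if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
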