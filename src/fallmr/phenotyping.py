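"""EHR code-list phenotyping: fall case/control status and fall counts.

Case/control derivation from coded hospital (HES, ICD-10) and primary-care
(GP, Read v2/v3) event logs against include/exclude code lists:

* **case** — at least one balance-related fall code in the selected sources;
* **control** — at least one record of any kind in the selected sources and
  *no* fall code of any category (any fall code, balance-related or not,
  disqualifies a control);
* **excluded** — no records in the selected sources, or fall codes only of
  the non-balance category (such a person is neither case nor control).

The per-person fall count is the number of *distinct event dates* carrying
at least one balance-fall code: multiple distinct codes recorded on the
same date count as one fall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CodeList",
    "VOCABULARIES",
    "CATEGORIES",
    "parse_code_list",
    "default_code_list",
    "validate_event_log",
    "derive_fall_status",
    "count_falls",
    "cross_tabulate",
    "summarize_cohort",
]

VOCABULARIES = ("ICD10", "READ2", "READ3")
CATEGORIES = ("balance_fall", "other_fall", "non_fall")
SOURCE_VOCABULARY = {"HES": ("ICD10",), "GP": ("READ2", "READ3")}


@dataclass(frozen=True)
class CodeList:
    """Validated set of (vocabulary, code, category, description) entries."""

    entries: pd.DataFrame

    def __len__(self) -> int:
        return len(self.entries)

    def codes(self, *categories: str) -> pd.DataFrame:
        return self.entries[self.entries["category"].isin(categories)]


def _validate_code_frame(df: pd.DataFrame, origin: str = "code list") -> pd.DataFrame:
    required = {"vocabulary", "code", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{origin}: missing required column(s) {sorted(missing)}")
    if "description" not in df.columns:
        df = df.assign(description="")
    df = df.astype({"vocabulary": str, "code": str, "category": str})
    for i, row in df.iterrows():
        if row["vocabulary"] not in VOCABULARIES:
            raise ValueError(f"{origin} row {i}: unknown vocabulary {row['vocabulary']!r}")
        if row["category"] not in CATEGORIES:
            raise ValueError(f"{origin} row {i}: unknown category {row['category']!r}")
    dupes = df.duplicated(subset=["vocabulary", "code"])
    if dupes.any():
        bad = df.loc[dupes, ["vocabulary", "code"]].to_records(index=False).tolist()
        raise ValueError(f"{origin}: duplicate (vocabulary, code) entries: {bad}")
    return df.reset_index(drop=True)


def parse_code_list(path) -> CodeList:
    """Read and validate a code-list CSV (vocabulary, code, category, description)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    df = _validate_code_frame(df, origin=str(path))
    if df.empty:
        warnings.warn(f"{path}: code list is empty", stacklevel=2)
    return CodeList(entries=df)


def default_code_list() -> CodeList:
    """A small synthetic code list covering every vocabulary and category.

    The codes follow the shape of real ICD-10 W-chapter fall codes and
    Read-style primary-care codes but are a stand-in set for testing, not
    a clinically reviewed list.
    """
    rows = [
        # balance-related falls
        ("ICD10", "W00", "balance_fall", "fall on same level involving ice and snow"),
        ("ICD10", "W01", "balance_fall", "fall on same level from slipping or tripping"),
        ("ICD10", "W05", "balance_fall", "fall involving wheelchair"),
        ("ICD10", "W10", "balance_fall", "fall on and from stairs and steps"),
        ("ICD10", "W18", "balance_fall", "other fall on same level"),
        ("ICD10", "W19", "balance_fall", "unspecified fall"),
        ("READ2", "TC00.", "balance_fall", "accidental fall on same level"),
        ("READ2", "TC10.", "balance_fall", "fall from stairs"),
        ("READ3", "XaFall", "balance_fall", "had a fall"),
        ("READ3", "XaTrip", "balance_fall", "fall due to trip"),
        # falls unlikely to reflect balance problems
        ("ICD10", "W16", "other_fall", "diving or jumping into water causing injury"),
        ("ICD10", "W13", "other_fall", "fall from, out of or through building"),
        ("READ2", "TC60.", "other_fall", "fall into water"),
        # unrelated records
        ("ICD10", "I10", "non_fall", "essential hypertension"),
        ("ICD10", "J45", "non_fall", "asthma"),
        ("ICD10", "K21", "non_fall", "gastro-oesophageal reflux"),
        ("READ2", "H33..", "non_fall", "asthma"),
        ("READ2", "G20..", "non_fall", "essential hypertension"),
        ("READ3", "XE0Uc", "non_fall", "hypertension monitoring"),
    ]
    df = pd.DataFrame(rows, columns=["vocabulary", "code", "category", "description"])
    return CodeList(entries=_validate_code_frame(df))


def validate_event_log(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-log contract and drop vocabulary/source mismatches.

    Rows whose vocabulary is inconsistent with their source (ICD-10 must
    come from HES, Read codes from GP) are rejected with a warning rather
    than silently coerced.
    """
    required = {"person_id", "source", "vocabulary", "code", "event_date"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event log: missing required column(s) {sorted(missing)}")
    events = events.copy()
    events["event_date"] = pd.to_datetime(events["event_date"])
    ok = np.zeros(len(events), dtype=bool)
    for source, vocabs in SOURCE_VOCABULARY.items():
        ok |= (events["source"] == source) & events["vocabulary"].isin(vocabs)
    if (~ok).any():
        warnings.warn(
            f"dropping {int((~ok).sum())} event rows with vocabulary/source mismatch",
            stacklevel=2,
        )
        events = events[ok]
    return events.reset_index(drop=True)


def _annotate(events: pd.DataFrame, codes: CodeList) -> pd.DataFrame:
    """Attach a category to every event row; unlisted codes count as non_fall."""
    merged = events.merge(
        codes.entries[["vocabulary", "code", "category"]],
        on=["vocabulary", "code"],
        how="left",
    )
    merged["category"] = merged["category"].fillna("non_fall")
    return merged


def derive_fall_status(
    events: pd.DataFrame,
    codes: CodeList,
    sources: tuple[str, ...] = ("HES", "GP"),
    all_persons=None,
    birth_year: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-person fall phenotype for the selected record sources.

    Returns one row per person with ``status`` in {case, control, excluded},
    ``fall_count`` (distinct balance-fall dates), ``first_fall_date`` and,
    when ``birth_year`` is supplied, ``age_at_first_fall``.  Persons listed
    in ``all_persons`` but absent from the log are reported as excluded, so
    {case, control, excluded} partitions the requested person set.
    """
    if not sources:
        raise ValueError("sources must be a non-empty subset of {'HES', 'GP'}")
    bad = set(sources) - set(SOURCE_VOCABULARY)
    if bad:
        raise ValueError(f"unknown source(s) {sorted(bad)}")
    if codes.entries.empty:
        raise ValueError("code list is empty")

    events = validate_event_log(events)
    sub = _annotate(events[events["source"].isin(sources)], codes)

    has_record = sub.groupby("person_id").size().rename("n_records")
    is_balance = sub["category"] == "balance_fall"
    is_any_fall = sub["category"].isin(["balance_fall", "other_fall"])
    any_balance = sub[is_balance].groupby("person_id").size().rename("n_balance")
    any_fall = sub[is_any_fall].groupby("person_id").size().rename("n_fall")

    fall_dates = (
        sub.loc[is_balance]
        .assign(day=lambda d: d["event_date"].dt.normalize())
        .groupby("person_id")["day"]
        .agg(fall_count="nunique", first_fall_date="min")
    )

    persons = pd.Index(sorted(set(events["person_id"])), name="person_id")
    if all_persons is not None:
        persons = persons.union(pd.Index(all_persons, name="person_id"))

    out = pd.DataFrame(index=persons)
    out["n_records"] = has_record.reindex(persons).fillna(0).astype(int)
    out["n_balance"] = any_balance.reindex(persons).fillna(0).astype(int)
    out["n_fall"] = any_fall.reindex(persons).fillna(0).astype(int)
    out["fall_count"] = fall_dates["fall_count"].reindex(persons).fillna(0).astype(int)
    out["first_fall_date"] = fall_dates["first_fall_date"].reindex(persons)

    status = np.where(
        out["n_balance"] > 0,
        "case",
        np.where((out["n_records"] > 0) & (out["n_fall"] == 0), "control", "excluded"),
    )
    out["status"] = status
    if birth_year is not None:
        by = pd.Series(birth_year).reindex(persons)
        out["age_at_first_fall"] = out["first_fall_date"].dt.year - by
    return out.drop(columns=["n_records", "n_balance", "n_fall"]).reset_index()


def count_falls(events: pd.DataFrame, codes: CodeList,
                sources: tuple[str, ...] = ("HES", "GP")) -> pd.Series:
    """Distinct balance-fall event dates per person (same-date codes dedup to 1)."""
    events = validate_event_log(events)
    sub = _annotate(events[events["source"].isin(sources)], codes)
    sub = sub[sub["category"] == "balance_fall"]
    counts = sub.assign(day=sub["event_date"].dt.normalize()).groupby("person_id")["day"].nunique()
    return counts.rename("fall_count")


def cross_tabulate(derived: pd.DataFrame, selfreport: pd.Series) -> pd.DataFrame:
    """2x2 table of derived status vs self-reported falls, with row percentages.

    ``derived`` must carry person_id and status; ``selfreport`` is a boolean
    Series indexed by person_id.  Percentages are rounded to the nearest
    integer percent for reporting.
    """
    status = derived.set_index("person_id")["status"]
    orphans = status.index.symmetric_difference(selfreport.index)
    if len(orphans):
        raise ValueError(f"person keys do not align; {len(orphans)} orphans, e.g. {list(orphans[:5])}")
    rows = []
    for group in ("case", "control"):
        mask = status == group
        n = int(mask.sum())
        n_self = int(selfreport[status.index[mask]].sum())
        pct = int(round(100.0 * n_self / n)) if n else 0
        rows.append({"group": group, "n": n, "n_selfreport": n_self, "pct_selfreport": pct})
    return pd.DataFrame(rows)


def percentage(count: int, total: int) -> int:
    """Integer percent as reported in demographic tables: round(100*count/total)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * count / total))


def summarize_cohort(phenotype: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Demographics table: per-trait case/control summaries with adjusted p-values.

    ``covariates`` is indexed by person_id and must include ``age`` and
    ``sex``; every other column is summarised as mean (SD) if numeric or
    count (%) if binary, and its case/control difference tested with a
    logistic regression of case status on the trait adjusted for age and
    sex.  Constant traits get a not-applicable p-value.
    """
    import statsmodels.api as sm

    for needed in ("age", "sex"):
        if needed not in covariates.columns:
            raise ValueError(f"covariates must include {needed!r}")

    status = phenotype.set_index("person_id")["status"]
    keep = status[status.isin(["case", "control"])]
    cov = covariates.loc[keep.index]
    y = (keep == "case").astype(float)
    sex_male = (cov["sex"] == "male").astype(float) if cov["sex"].dtype == object else cov["sex"].astype(float)
    age = cov["age"].astype(float)

    rows = []
    trait_cols = [c for c in cov.columns if c not in ("age", "sex")]
    for trait in ["age", "sex"] + trait_cols:
        if trait == "sex":
            x = sex_male
        else:
            x = cov[trait]
            if x.dtype == object or x.dtype == bool:
                x = x.astype("category").cat.codes.astype(float)
            x = x.astype(float)
        binary = set(np.unique(x.dropna())) <= {0.0, 1.0}
        cells = {}
        for label, mask in (("case", y == 1), ("control", y == 0)):
            xs = x[mask].dropna()
            if binary:
                cells[label] = f"{int(xs.sum())} ({percentage(int(xs.sum()), len(xs))}%)"
            else:
                cells[label] = f"{xs.mean():.3g} ({xs.std():.3g})"
        if x.nunique(dropna=True) < 2:
            p = np.nan
        else:
            design = pd.DataFrame({"const": 1.0, "trait": x})
            if trait != "age":
                design["age"] = age
            if trait != "sex":
                design["sex"] = sex_male
            ok = design.notna().all(axis=1)
            fit = sm.GLM(y[ok], design[ok], family=sm.families.Binomial()).fit()
            p = float(fit.pvalues["trait"])
        rows.append({"trait": trait, "cases": cells["case"], "controls": cells["control"], "p_value": p})
    return pd.DataFrame(rows)
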