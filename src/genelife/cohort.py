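"""Reading, validating and writing per-subject cohort tables.

The cohort table is a delimited text file (comma by default, tab accepted)
with one row per subject and a fixed header vocabulary: demographics and
covariates, the raw lifestyle variables feeding the five-factor lifestyle
score, genotypes at the 13 SNP loci (columns named by rsID), baseline and
follow-up blood pressure, the antihypertensive-medication flag and the
incident-hypertension outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    EDUCATION_LEVELS,
    FOOD_ITEMS,
    FREQ_LEVELS,
    INCOME_LEVELS,
    IPAQ_LEVELS,
    MARITAL_LEVELS,
    SEX_LEVELS,
    SMOKING_LEVELS,
    SNP_IDS,
)

FOOD_COLUMNS = tuple(f"ff_{item}" for item in FOOD_ITEMS)

#: Required columns and their kinds ("num", "bool", "cat:<levels>", "geno").
REQUIRED_COLUMNS: tuple[str, ...] = (
    ("subject_id",)
    + ("age", "sex", "education", "marital", "income")
    + ("family_history_htn", "antihypertensive_med")
    + ("baseline_sbp", "baseline_dbp", "followup_sbp", "followup_dbp")
    + ("hypertension",)
    + FOOD_COLUMNS
    + ("bmi", "smoking", "years_since_quit", "ipaq_level", "drinks_per_year")
    + SNP_IDS
)

_CATEGORICALS = {
    "sex": SEX_LEVELS,
    "education": EDUCATION_LEVELS,
    "marital": MARITAL_LEVELS,
    "income": INCOME_LEVELS,
    "smoking": SMOKING_LEVELS,
    "ipaq_level": IPAQ_LEVELS,
    **{col: FREQ_LEVELS for col in FOOD_COLUMNS},
}

_BOOLEANS = ("family_history_htn", "antihypertensive_med", "hypertension")

_NUMERICS = (
    "age",
    "baseline_sbp",
    "baseline_dbp",
    "followup_sbp",
    "followup_dbp",
    "bmi",
    "drinks_per_year",
)


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class ValidationError(ValueError):
    """Row-level content violates the cohort invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "; ".join(problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"{len(problems)} validation problem(s): {preview}{more}")


def derive_outcome(followup_sbp, followup_dbp, antihypertensive_med):
    """Incident hypertension at follow-up.

    True iff systolic pressure >= 140 mmHg, or diastolic pressure >= 90 mmHg,
    or the subject took antihypertensive medication within the two weeks
    before the follow-up visit. Accepts scalars or arrays.
    """
    sbp = np.asarray(followup_sbp, dtype=float)
    dbp = np.asarray(followup_dbp, dtype=float)
    med = np.asarray(antihypertensive_med, dtype=bool)
    if np.any(sbp <= 0) or np.any(dbp <= 0):
        raise ValueError("blood pressures must be positive")
    out = (sbp >= 140.0) | (dbp >= 90.0) | med
    if out.ndim == 0:
        return bool(out)
    return out


def validate_cohort(table: pd.DataFrame) -> None:
    """Raise :class:`SchemaError`/:class:`ValidationError` on a bad table.

    Every offending row is reported with its index and field name so a data
    file can be fixed in one pass.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if table.empty:
        return

    problems: list[str] = []

    dup = table["subject_id"][table["subject_id"].duplicated()]
    for idx, val in dup.items():
        problems.append(f"row {idx}: duplicate subject_id {val!r}")

    for col in _NUMERICS:
        vals = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[vals.isna()]:
            problems.append(f"row {idx}: field {col} not numeric: {table.at[idx, col]!r}")

    quit_years = pd.to_numeric(table["years_since_quit"], errors="coerce")
    former = table["smoking"] == "former"
    for idx in table.index[former & quit_years.isna()]:
        problems.append(f"row {idx}: field years_since_quit required for former smokers")

    for col, levels in _CATEGORICALS.items():
        bad = ~table[col].isin(levels)
        for idx in table.index[bad]:
            problems.append(
                f"row {idx}: field {col} value {table.at[idx, col]!r} not in {levels}"
            )

    for col in _BOOLEANS:
        coerced = _coerce_bool(table[col])
        for idx in table.index[coerced.isna()]:
            problems.append(f"row {idx}: field {col} not boolean: {table.at[idx, col]!r}")

    for snp in SNP_IDS:
        vals = table[snp]
        ok = vals.isna() | vals.astype(str).str.fullmatch(r"[ACGT]{2}").fillna(False)
        for idx in table.index[~ok]:
            problems.append(
                f"row {idx}: field {snp} genotype {vals[idx]!r} is not two bases or missing"
            )

    if problems:  # structural problems block the arithmetic checks below
        raise ValidationError(problems)

    num = table[list(_NUMERICS)].apply(pd.to_numeric)
    for idx in table.index[~(num["baseline_sbp"] > num["baseline_dbp"])]:
        problems.append(f"row {idx}: field baseline_sbp not greater than baseline_dbp")
    for idx in table.index[~(num["followup_sbp"] > num["followup_dbp"])]:
        problems.append(f"row {idx}: field followup_sbp not greater than followup_dbp")
    for col in ("baseline_sbp", "baseline_dbp", "followup_sbp", "followup_dbp", "bmi"):
        for idx in table.index[~(num[col] > 0)]:
            problems.append(f"row {idx}: field {col} must be positive")
    for idx in table.index[num["drinks_per_year"] < 0]:
        problems.append(f"row {idx}: field drinks_per_year negative")

    if problems:
        raise ValidationError(problems)

    derived = derive_outcome(
        num["followup_sbp"].to_numpy(),
        num["followup_dbp"].to_numpy(),
        _coerce_bool(table["antihypertensive_med"]).astype(bool).to_numpy(),
    )
    stated = _coerce_bool(table["hypertension"]).astype(bool).to_numpy()
    for idx in table.index[np.asarray(derived) != stated]:
        problems.append(
            f"row {idx}: field hypertension inconsistent with follow-up BP/medication"
        )
    if problems:
        raise ValidationError(problems)


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        True: True, False: False, 1: True, 0: False,
        "1": True, "0": False, "true": True, "false": False,
        "True": True, "False": False,
    }
    return series.map(mapping)


def read_cohort(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a cohort table from delimited text.

    ``sep=None`` sniffs comma vs tab from the header line.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    table = pd.read_csv(path, sep=sep, dtype={"subject_id": str}, keep_default_na=True)
    table = _normalize_types(table)
    validate_cohort(table)
    return table


def _normalize_types(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    for col in _BOOLEANS:
        if col in table.columns:
            coerced = _coerce_bool(table[col])
            if not coerced.isna().any():
                table[col] = coerced.astype(bool)
    for col in _NUMERICS + ("years_since_quit",):
        if col in table.columns:
            coerced = pd.to_numeric(table[col], errors="coerce")
            # keep original values where coercion fails so validation can
            # report them with the raw token
            if not (coerced.isna() & table[col].notna()).any():
                table[col] = coerced
    return table


def write_cohort(table: pd.DataFrame, path: str, sep: str = ",") -> None:
    """Write a cohort table as delimited text; inverse of :func:`read_cohort`.

    Booleans are serialised as 0/1 and missing values as empty fields so the
    round trip is lossless.
    """
    out = table.copy()
    for col in _BOOLEANS:
        out[col] = out[col].astype(int)
    out.to_csv(path, sep=sep, index=False)


@dataclass
class GenotypeFilter:
    """Outcome of splitting a cohort by genotype completeness."""

    complete: pd.DataFrame
    n_excluded: int = 0
    excluded_ids: list = field(default_factory=list)


def split_by_genotype_completeness(table: pd.DataFrame) -> GenotypeFilter:
    """Separate subjects with full genotype data from those with any missing.

    Subjects with incomplete genotypes are excluded from GRS-dependent
    analyses but may be retained for lifestyle-only ones.
    """
    has_missing = table[list(SNP_IDS)].isna().any(axis=1)
    return GenotypeFilter(
        complete=table.loc[~has_missing],
        n_excluded=int(has_missing.sum()),
        excluded_ids=table.loc[has_missing, "subject_id"].tolist(),
    )
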