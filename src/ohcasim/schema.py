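"""Cohort table schema: column set, categorical domains, and validation.

A cohort is a :class:`pandas.DataFrame` with one row per case and the columns
listed in :data:`COLUMNS`. Categorical variables are stored as plain lowercase
string tokens; missing cells are ``NaN``. All modules share this schema.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical column order of a cohort table (also the CSV header).
COLUMNS = (
    "case_id",
    "age",
    "gender",
    "witness_type",
    "arrest_location",
    "call_time",
    "first_rhythm",
    "alert_issued",
    "bcpr",
)

#: Declared domain (and tie-break order) of each categorical variable.
DOMAINS: dict[str, tuple[str, ...]] = {
    "gender": ("female", "male"),
    "witness_type": ("not_witnessed", "family", "healthcare", "lay"),
    "arrest_location": ("home", "public"),
    "call_time": ("t00_05", "t06_18", "t19_23"),
    "first_rhythm": ("non_shockable", "shockable", "unknown"),
}

CATEGORICAL = tuple(DOMAINS)
BINARY = ("alert_issued", "bcpr")

#: Variables that may receive missing values during amputation.
AMPUTABLE = ("age", "witness_type", "call_time")
#: Covariates guaranteed fully observed (eligible missingness predictors).
FULLY_OBSERVED = ("gender", "arrest_location", "first_rhythm")

#: Sentinel level added to a categorical variable by the missingness-indicator
#: imputer; never valid in a reference cohort.
MISSING_LEVEL = "missing"

AGE_MIN = 18.0
AGE_MAX = 110.0

#: Extra indicator column added by the missingness-indicator imputer for the
#: continuous variable (categoricals get the MISSING_LEVEL level instead).
AGE_MISSING_COLUMN = "age_missing"


class CohortValidationError(ValueError):
    """A cohort table violates the schema."""


def _fail(msg: str) -> None:
    raise CohortValidationError(msg)


def validate_cohort(
    table: pd.DataFrame,
    *,
    allow_missing: bool = False,
    allow_missing_level: bool = False,
) -> None:
    """Validate a cohort table against the schema.

    Parameters
    ----------
    table
        Candidate cohort table.
    allow_missing
        Permit NaN cells in the amputable columns.
    allow_missing_level
        Permit the ``missing`` sentinel level in categoricals and the
        ``age_missing`` indicator column (missingness-indicator output).

    Raises
    ------
    CohortValidationError
        On the first violation found, with a message naming the offending
        column and, where applicable, the first offending row.
    """
    expected = list(COLUMNS) + (
        [AGE_MISSING_COLUMN] if allow_missing_level and AGE_MISSING_COLUMN in table.columns else []
    )
    if list(table.columns) != expected:
        _fail(f"bad columns: expected {expected}, got {list(table.columns)}")
    if table["case_id"].duplicated().any():
        dup = table.loc[table["case_id"].duplicated(), "case_id"].iloc[0]
        _fail(f"case_id not unique (duplicate id {dup})")

    age = table["age"]
    if age.isna().any() and not allow_missing:
        _fail("age has missing cells but allow_missing=False")
    if allow_missing_level and AGE_MISSING_COLUMN in table.columns:
        # sentinel fill (0) of indicator rows is exempt from the age bounds
        age = age.where(table[AGE_MISSING_COLUMN] == 0)
    bad_age = (age < AGE_MIN) | (age > AGE_MAX)
    if bad_age.any():
        row = int(np.flatnonzero(bad_age.to_numpy())[0])
        _fail(f"age out of [{AGE_MIN}, {AGE_MAX}] at row {row}")

    for col, domain in DOMAINS.items():
        levels = set(domain)
        if allow_missing_level:
            levels.add(MISSING_LEVEL)
        vals = table[col]
        bad = ~(vals.isin(levels) | vals.isna())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            _fail(f"{col!r} value {vals.iloc[row]!r} at row {row} not in domain {sorted(levels)}")
        if vals.isna().any():
            if not allow_missing:
                _fail(f"{col!r} has missing cells but allow_missing=False")
            if col not in AMPUTABLE:
                _fail(f"{col!r} is declared fully observed but has missing cells")

    for col in BINARY:
        vals = table[col]
        if vals.isna().any():
            _fail(f"{col!r} has missing cells (exposure/outcome are always observed)")
        if not vals.isin((0, 1)).all():
            row = int(np.flatnonzero(~vals.isin((0, 1)).to_numpy())[0])
            _fail(f"{col!r} value {vals.iloc[row]!r} at row {row} not in {{0, 1}}")


def missing_pattern(table: pd.DataFrame) -> pd.Series:
    """Per-row missingness pattern label.

    Returns ``"none"`` for complete rows, the variable name for rows missing
    exactly one amputable variable, and ``"multiple"`` otherwise.
    """
    isna = table[list(AMPUTABLE)].isna()
    counts = isna.sum(axis=1)
    out = pd.Series("none", index=table.index, dtype=object)
    for var in AMPUTABLE:
        out[isna[var] & (counts == 1)] = var
    out[counts > 1] = "multiple"
    return out


def is_complete(table: pd.DataFrame) -> bool:
    """True when no model variable has a missing cell."""
    return not table[[c for c in COLUMNS if c != "case_id"]].isna().any().any()
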