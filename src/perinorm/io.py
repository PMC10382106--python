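"""CSV interchange for scan and covariate tables, with row-level validation.

All tables are UTF-8 CSV with "." decimals and empty cells as the missing
marker.  Units are fixed at the boundary: weeks for ages, days for postnatal
durations, minutes for bypass/circulatory arrest, mL for volumes, umol/L for
creatinine; no unit inference is attempted.  Round-trips through these
readers and writers are lossless, including missingness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, ValidationError
from .regions import CHD_CATEGORIES
from .simulate import SCAN_META_COLUMNS

__all__ = [
    "read_scan_table",
    "write_scan_table",
    "read_covariate_table",
    "write_covariate_table",
]

PMA_FLOOR_WEEKS = 37.0
PMA_CEIL_WEEKS = 46.0
_TIMEPOINTS = {"single", "pre", "post"}


def region_columns(table: pd.DataFrame) -> list[str]:
    """Columns holding regional volumes (everything beyond the metadata)."""
    return [c for c in table.columns if c not in SCAN_META_COLUMNS]


def read_scan_table(path) -> pd.DataFrame:
    """Read and validate a long-format scan table.

    One row per scan; metadata columns ``subject_id, group, sex,
    ga_birth_weeks, pma_scan_weeks, postnatal_days, timepoint`` followed by
    one column per region (mL).  Empty volume cells become missing values.
    Violations are reported together with their CSV line numbers.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = [c for c in SCAN_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataIntegrityError(
            f"{path}: missing required column(s): " + ", ".join(missing_cols)
        )
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        sex = str(row["sex"]).strip().upper()
        if sex in {"F", "M"}:
            df.at[idx, "sex"] = sex
        else:
            problems.append(f"line {line}: unknown sex code {row['sex']!r}")
        tp = str(row["timepoint"]).strip().lower()
        if tp in _TIMEPOINTS:
            df.at[idx, "timepoint"] = tp
        else:
            problems.append(f"line {line}: unknown timepoint {row['timepoint']!r}")
        pma, ga = row["pma_scan_weeks"], row["ga_birth_weeks"]
        if np.isfinite(pma) and pma < PMA_FLOOR_WEEKS:
            problems.append(
                f"line {line}: pma_scan_weeks {pma} below the "
                f"{PMA_FLOOR_WEEKS:g}-week floor of the modelled window"
            )
        if np.isfinite(pma) and pma > PMA_CEIL_WEEKS:
            problems.append(
                f"line {line}: pma_scan_weeks {pma} above the "
                f"{PMA_CEIL_WEEKS:g}-week ceiling of the modelled window"
            )
        if np.isfinite(pma) and np.isfinite(ga) and pma < ga:
            problems.append(
                f"line {line}: pma_scan_weeks {pma} earlier than ga_birth_weeks {ga}"
            )
        if np.isfinite(row["postnatal_days"]) and row["postnatal_days"] < 0:
            problems.append(f"line {line}: negative postnatal_days")
    for col in region_columns(df):
        bad = df.index[df[col].notna() & (df[col] <= 0)]
        for idx in bad:
            problems.append(f"line {idx + 2}: non-positive volume in {col!r}")
    if problems:
        raise ValidationError(problems)
    df["postnatal_days"] = df["postnatal_days"].astype(int)
    return df


def write_scan_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_covariate_table(path) -> pd.DataFrame:
    """Read and validate the per-subject clinical covariate table.

    Keyed by ``subject_id`` (duplicates are an error); flags are 0/1;
    ``chd_category`` is normalised case-insensitively to
    streaming/left/right; unrecognised columns are preserved untouched.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise DataIntegrityError(f"{path}: missing subject_id column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise DataIntegrityError(
            "duplicate subject_id(s): " + ", ".join(sorted(set(dup)))
        )
    problems = []
    if "chd_category" in df.columns:
        norm = df["chd_category"].astype(str).str.strip().str.lower()
        for idx, val in norm.items():
            if val in CHD_CATEGORIES:
                df.at[idx, "chd_category"] = val
            elif val in {"nan", ""}:
                df.at[idx, "chd_category"] = np.nan
            else:
                problems.append(
                    f"line {idx + 2}: unknown chd_category "
                    f"{df.at[idx, 'chd_category']!r}"
                )
    for flag in ("rrt", "nec", "brain_injury"):
        if flag in df.columns:
            vals = df[flag].dropna()
            if not vals.isin([0, 1]).all():
                problems.append(f"column {flag!r}: flags must be 0/1")
    if problems:
        raise ValidationError(problems)
    return df


def write_covariate_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
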