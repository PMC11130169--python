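"""Tabular containers for focus-count and clonogenic-survival data.

Both datasets are plain pandas DataFrames with fixed schemas (UTF-8 CSV,
header row, '.' decimal); these helpers validate and round-trip them.

foci:     cell_line, schedule_label, dose_Gy, timepoint_h, reference,
          nucleus_id, foci_count
survival: cell_line, schedule_label, dose_Gy, replicate, n_plated,
          colonies, sf, se
"""

from __future__ import annotations

import pandas as pd

FOCI_COLUMNS = [
    "cell_line",
    "schedule_label",
    "dose_Gy",
    "timepoint_h",
    "reference",
    "nucleus_id",
    "foci_count",
]

SURVIVAL_COLUMNS = [
    "cell_line",
    "schedule_label",
    "dose_Gy",
    "replicate",
    "n_plated",
    "colonies",
    "sf",
    "se",
]


def validate_foci(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(FOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"foci table missing columns: {sorted(missing)}")
    if (df["foci_count"] < 0).any():
        raise ValueError("foci_count must be non-negative")
    if not df["reference"].isin(["after_start", "after_end"]).all():
        raise ValueError("reference must be 'after_start' or 'after_end'")
    return df


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if (df["sf"] <= 0).any():
        raise ValueError("surviving fractions must be positive")
    return df


def read_foci_csv(path) -> pd.DataFrame:
    return validate_foci(pd.read_csv(path))


def read_survival_csv(path) -> pd.DataFrame:
    return validate_survival(pd.read_csv(path))


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
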