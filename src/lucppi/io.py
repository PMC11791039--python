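"""Reading and writing the canonical long-format plate table.

One row per well: ``pair_id, role, replicate, luminescence`` required;
``bait, prey, label, treatment, dose_molar`` optional. ``role`` is one of
``interaction``, ``B_handle``, ``P_handle``, ``floor``, ``ceiling``,
``binding``. Non-positive readings are floored at a small positive
epsilon (1e-6 of the median absolute reading) and counted in the
validation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import ReferencePairRecord

__all__ = [
    "REQUIRED_COLUMNS",
    "ROLES",
    "ValidationReport",
    "read_plate_table",
    "write_plate_table",
    "records_from_frame",
    "wide_to_long",
]

REQUIRED_COLUMNS = ("pair_id", "role", "replicate", "luminescence")
OPTIONAL_COLUMNS = ("bait", "prey", "label", "treatment", "dose_molar")
ROLES = ("interaction", "B_handle", "P_handle", "floor", "ceiling", "binding")


@dataclass
class ValidationReport:
    n_rows: int = 0
    n_floored: int = 0
    warnings: list[str] = field(default_factory=list)


def read_plate_table(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Load and validate a long-format plate CSV."""
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    report = ValidationReport(n_rows=len(df))
    lum = pd.to_numeric(df["luminescence"], errors="coerce")
    bad = lum.isna() & df["luminescence"].notna()
    if bad.any():
        raise ValueError(
            f"non-numeric luminescence at row index {int(np.flatnonzero(bad)[0])}"
        )
    if lum.isna().any():
        raise ValueError(
            f"missing luminescence at row index {int(np.flatnonzero(lum.isna())[0])}"
        )
    df = df.copy()
    df["luminescence"] = lum.astype(float)
    unknown_roles = set(df["role"].unique()) - set(ROLES)
    if unknown_roles:
        report.warnings.append(f"unknown roles present: {sorted(unknown_roles)}")
    nonpos = df["luminescence"] <= 0
    if nonpos.any():
        eps = 1e-6 * max(float(df["luminescence"].abs().median()), 1.0)
        df.loc[nonpos, "luminescence"] = eps
        report.n_floored = int(nonpos.sum())
        report.warnings.append(f"floored {report.n_floored} non-positive reading(s)")
    return df, report


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format table; full float precision for round-trips."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def records_from_frame(df: pd.DataFrame) -> list[ReferencePairRecord]:
    """Group screen wells into per-pair records (interaction + handles).

    Pairs missing a handle well group are skipped with their ids noted in
    the raised-free return; callers wanting strictness can compare counts.
    """
    records = []
    for pid, grp in df.groupby("pair_id", sort=True):
        roles = {role: g["luminescence"].tolist() for role, g in grp.groupby("role")}
        if "interaction" not in roles:
            continue
        if "B_handle" not in roles or "P_handle" not in roles:
            continue
        label = "unknown"
        if "label" in grp.columns:
            vals = grp["label"].dropna().unique()
            if len(vals) == 1 and vals[0] in ("PRS", "RRS"):
                label = str(vals[0])
        records.append(
            ReferencePairRecord(
                pair_id=str(pid),
                bait=str(grp["bait"].iloc[0]) if "bait" in grp.columns else "",
                prey=str(grp["prey"].iloc[0]) if "prey" in grp.columns else "",
                interaction_readings=tuple(roles["interaction"]),
                b_handle_readings=tuple(roles["B_handle"]),
                p_handle_readings=tuple(roles["P_handle"]),
                label=label,
            )
        )
    return records


def wide_to_long(
    plate: pd.DataFrame,
    well_map: pd.DataFrame,
) -> pd.DataFrame:
    """Convert a 384-well row×column reading matrix to the long format.

    ``plate`` is indexed by row letter with one column per plate column
    number; ``well_map`` assigns each well (``row``, ``column``) its
    ``pair_id``, ``role``, ``replicate`` and optional annotation columns.
    """
    melted = plate.reset_index(names="row").melt(
        id_vars="row", var_name="column", value_name="luminescence"
    )
    melted["column"] = melted["column"].astype(int)
    wm = well_map.copy()
    wm["column"] = wm["column"].astype(int)
    out = wm.merge(melted, on=["row", "column"], how="left")
    if out["luminescence"].isna().any():
        missing = out[out["luminescence"].isna()][["row", "column"]].iloc[0]
        raise ValueError(f"well {missing.row}{missing.column} absent from plate data")
    return out.drop(columns=["row", "column"])
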