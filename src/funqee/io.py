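"""Wide-CSV study reader/writer.

Schema: subject_id,school_id,age,sex,race,desk,bmi,sdee_h01..sdee_hMM.
The writer emits full-precision values plus an optional JSON sidecar
with the simulation truth and seed; the reader validates the schema,
drops rows with missing SDEE cells (recording row-level messages), and
rejects invalid values naming the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import (
    DESK_LEVELS,
    RACE_LEVELS,
    SEX_LEVELS,
    StudyData,
    TimeGrid,
)

__all__ = ["write_study_csv", "read_study_csv", "sdee_columns"]

BASE_COLUMNS = ["subject_id", "school_id", "age", "sex", "race", "desk", "bmi"]


def sdee_columns(m: int) -> list[str]:
    return [f"sdee_h{k:02d}" for k in range(1, m + 1)]


def write_study_csv(study: StudyData, path, truth_path=None) -> Path:
    """Write the wide CSV; optionally a JSON sidecar with truth + seed."""
    path = Path(path)
    frame = study.table[BASE_COLUMNS].copy()
    curve_frame = pd.DataFrame(study.curves, columns=sdee_columns(study.grid.m))
    frame = pd.concat([frame.reset_index(drop=True), curve_frame], axis=1)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    if truth_path is not None:
        Path(truth_path).write_text(
            json.dumps(study.metadata, indent=2, sort_keys=True, default=float)
        )
    return path


def read_study_csv(path, m: int | None = None) -> StudyData:
    """Read and validate a wide study CSV.

    Rows with any missing SDEE cell are rejected with row-level messages
    (collected in metadata['rejected_rows']); other schema violations
    raise ValueError naming the field.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing_cols = [c for c in BASE_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    curve_cols = sorted(c for c in frame.columns if c.startswith("sdee_h"))
    if m is None:
        m = len(curve_cols)
    if curve_cols != sdee_columns(m):
        raise ValueError(
            f"expected SDEE columns {sdee_columns(m)[0]}..{sdee_columns(m)[-1]}, "
            f"found {len(curve_cols)} sdee_h columns"
        )
    rejected = []
    curve_vals = frame[curve_cols].to_numpy(dtype=float)
    bad_rows = np.flatnonzero(~np.isfinite(curve_vals).all(axis=1))
    for i in bad_rows:
        cols = [curve_cols[j] for j in np.flatnonzero(~np.isfinite(curve_vals[i]))]
        rejected.append(
            f"row {i} (subject {frame.iloc[i]['subject_id']}): missing SDEE in {cols}"
        )
    keep = np.setdiff1d(np.arange(len(frame)), bad_rows)
    frame = frame.iloc[keep].reset_index(drop=True)
    curve_vals = curve_vals[keep]
    if (frame["bmi"] <= 0).any() or not np.isfinite(frame["bmi"]).all():
        bad = frame.loc[(frame["bmi"] <= 0) | ~np.isfinite(frame["bmi"]), "subject_id"]
        raise ValueError(f"field 'bmi' must be positive and finite; bad: {list(bad)}")
    for col, levels in (("sex", SEX_LEVELS), ("race", RACE_LEVELS), ("desk", DESK_LEVELS)):
        unknown = set(frame[col].unique()) - set(levels)
        if unknown:
            raise ValueError(f"field {col!r} has unknown levels {sorted(unknown)}")
    table = frame[BASE_COLUMNS].copy()
    table["age"] = table["age"].astype(float)
    table["bmi"] = table["bmi"].astype(float)
    table["log_bmi"] = np.log(table["bmi"].to_numpy())
    return StudyData(
        grid=TimeGrid.hourly(m),
        table=table,
        curves=curve_vals,
        metadata={"source": str(path), "rejected_rows": rejected},
    )
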