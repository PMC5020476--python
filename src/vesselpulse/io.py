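"""CSV dialects shared by the generator and the pipeline.

Units are fixed by the schema: lengths mm, areas mm^2, volumes ml, times ms,
flows ml/s, pressures mmHg, path lengths m, PWV m/s.  Files:

* waveform CSV: columns ``time_ms,flow_ml_s``, one file per site, laid out as
  ``waveforms/<subject_id>_<segment>_<proximal|distal>.csv``;
* contour CSV: columns ``subject_id,structure,slice_index,phase,vertex_index,
  x_mm,y_mm``, one row per vertex, one file per subject under ``contours/``;
* subject table ``subjects.csv`` with demographics, cuff pressures and the
  centerline path lengths ``delta_x_arch_m, delta_x_dao_m, delta_x_carotid_m``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contours import CONTOUR_COLUMNS, ContourSet
from .pulsewave import FlowWaveform

SEGMENTS = ("arch", "dao", "carotid_left", "carotid_right")

SUBJECT_REQUIRED_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age_at_mri",
    "height",
    "weight",
    "systolic",
    "diastolic",
    "heart_rate",
    "delta_x_arch_m",
    "delta_x_dao_m",
]


class SchemaError(ValueError):
    """Input file violates the documented CSV schema."""


def write_waveform_csv(path, w: FlowWaveform) -> None:
    pd.DataFrame({"time_ms": w.times, "flow_ml_s": w.flow}).to_csv(path, index=False)


def read_waveform_csv(path, site: str = "") -> FlowWaveform:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_ms", "flow_ml_s"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    try:
        return FlowWaveform(site=site or path.stem, times=df["time_ms"].to_numpy(),
                            flow=df["flow_ml_s"].to_numpy())
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_contours_csv(path, subject_id: str, contours: ContourSet) -> None:
    df = contours.data[CONTOUR_COLUMNS].copy()
    df.insert(0, "subject_id", subject_id)
    df.to_csv(path, index=False)


def read_contours_csv(path, slice_thickness: float) -> ContourSet:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("x_mm", "y_mm"):
        bad = ~np.isfinite(df[col].to_numpy(dtype=float))
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise SchemaError(f"{path}: non-finite value in column {col!r} at row {row}")
    return ContourSet(data=df[CONTOUR_COLUMNS], slice_thickness=slice_thickness)


def write_subjects_csv(path, subjects: pd.DataFrame) -> None:
    subjects.to_csv(path, index=False)


def read_subjects_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_group = set(df["group"].unique()) - {"patient", "control"}
    if bad_group:
        raise SchemaError(f"{path}: unknown group labels {sorted(bad_group)} in column 'group'")
    for col in ("height", "weight", "systolic", "diastolic", "heart_rate"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            row = int(np.nonzero(~np.isfinite(vals) | (vals <= 0))[0][0])
            raise SchemaError(f"{path}: non-positive or missing value in column {col!r} at row {row}")
    if np.any(df["systolic"].to_numpy() <= df["diastolic"].to_numpy()):
        row = int(np.nonzero(df["systolic"].to_numpy() <= df["diastolic"].to_numpy())[0][0])
        raise SchemaError(f"{path}: systolic <= diastolic at row {row}")
    return df


def write_cohort_directory(out_dir, subjects: pd.DataFrame, data: dict) -> None:
    """Materialize a simulated cohort as the pipeline's input directory."""
    out = Path(out_dir)
    (out / "waveforms").mkdir(parents=True, exist_ok=True)
    (out / "contours").mkdir(parents=True, exist_ok=True)
    write_subjects_csv(out / "subjects.csv", subjects)
    for sid, sdata in data.items():
        for segment, (prox, dist) in sdata.waveforms.items():
            write_waveform_csv(out / "waveforms" / f"{sid}_{segment}_proximal.csv", prox)
            write_waveform_csv(out / "waveforms" / f"{sid}_{segment}_distal.csv", dist)
        write_contours_csv(out / "contours" / f"{sid}.csv", sid, sdata.contours)
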