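"""End-to-end orchestration: raw tables in, biomarker and statistics reports out.

``run_subject`` turns one subject's waveform and contour files into a flat
biomarker record (PWV per segment, distensibility per location, the LA and LV
function blocks, carotid wall metrics); missing optional inputs yield explicit
nulls, never silent zeros, and every null is logged.  ``run_cohort`` assembles
the per-subject records, compares the groups with Mann-Whitney tests, fits the
random-intercept distensibility model on the patient group, and writes the
report CSVs plus a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chambers import la_function, la_landmarks, lv_function, volume_curve
from .contours import ContourSet
from .io import (
    SchemaError,
    read_contours_csv,
    read_subjects_csv,
    read_waveform_csv,
)
from .lumen import (
    AORTIC_LOCATIONS,
    CAROTID_LUMEN_LOCATIONS,
    AreaCurve,
    BloodPressure,
    bsa as bsa_formula,
    distensibility_result,
)
from .pulsewave import pulse_wave_velocity, transit_time
from .stats import (
    fit_distensibility_lme,
    group_comparison_table,
    stage_hypertension_adult,
)
from .wall import WallContourPair, wall_metrics

logger = logging.getLogger("vesselpulse")

_LOCATION_COLUMNS = {
    "aortic root": "dist_aortic_root",
    "ascending aorta": "dist_ascending_aorta",
    "isthmus": "dist_isthmus",
    "descending aorta at diaphragm": "dist_descending_aorta",
    "carotid left proximal": "dist_carotid_left_proximal",
    "carotid left distal": "dist_carotid_left_distal",
    "carotid right proximal": "dist_carotid_right_proximal",
    "carotid right distal": "dist_carotid_right_distal",
}


@dataclass
class RunConfig:
    """Tunables for a pipeline run; defaults mirror the module-level defaults."""

    input_dir: str = "."
    output_dir: str = "out"
    foot_fraction: float = 0.1
    interp_factor: int = 16
    max_lag: float = 120.0  # ms
    bsa_formula: str = "mosteller"
    slice_thickness_mm: float = 6.0
    gap_mm: float = 0.0  # inter-slice gap; added to thickness for volumes
    wall_positions: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.foot_fraction < 0.5:
            raise ValueError("foot_fraction must lie in (0, 0.5)")
        if self.interp_factor < 1:
            raise ValueError("interp_factor must be >= 1")
        if self.max_lag <= 0:
            raise ValueError("max_lag must be positive")
        if self.slice_thickness_mm <= 0 or self.gap_mm < 0:
            raise ValueError("invalid slice geometry")
        if self.wall_positions < 2:
            raise ValueError("wall_positions must be >= 2")


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig(**data)


def _waveform_path(base: Path, sid: str, segment: str, which: str) -> Path:
    return base / "waveforms" / f"{sid}_{segment}_{which}.csv"


def _segment_pwv(base: Path, sid: str, segment: str, delta_x: float, config: RunConfig):
    prox = read_waveform_csv(_waveform_path(base, sid, segment, "proximal"), site=f"{segment} proximal")
    dist = read_waveform_csv(_waveform_path(base, sid, segment, "distal"), site=f"{segment} distal")
    est = transit_time(
        prox, dist,
        interp_factor=config.interp_factor,
        max_lag=config.max_lag,
        foot_fraction=config.foot_fraction,
    )
    return pulse_wave_velocity(est, delta_x, segment)


def run_subject(config: RunConfig, subject_id: str, subjects: pd.DataFrame | None = None) -> dict:
    """Compute the full biomarker record for one subject.

    Returns a flat dict; optional blocks (carotid) are ``None`` when their
    input files are absent.
    """
    base = Path(config.input_dir)
    if subjects is None:
        subjects = read_subjects_csv(base / "subjects.csv")
    match = subjects[subjects["subject_id"] == subject_id]
    if match.empty:
        raise SchemaError(f"subject {subject_id!r} not in subjects.csv")
    row = match.iloc[0]

    record: dict = {"subject_id": subject_id, "group": row["group"]}
    bsa = bsa_formula(row["height"], row["weight"], config.bsa_formula)
    record["bsa"] = bsa
    bp = BloodPressure(systolic=float(row["systolic"]), diastolic=float(row["diastolic"]))
    record["hypertension_stage"] = (
        stage_hypertension_adult(bp.systolic, bp.diastolic)
        if row["age_at_mri"] >= 18
        else None
    )

    # --- PWV per segment -------------------------------------------------- #
    for segment, col in (("arch", "delta_x_arch_m"), ("dao", "delta_x_dao_m"),
                         ("carotid_left", "delta_x_carotid_m"),
                         ("carotid_right", "delta_x_carotid_m")):
        out_col = f"pwv_{segment}"
        delta_x = row.get(col, np.nan)
        path = _waveform_path(base, subject_id, segment, "proximal")
        if not path.exists() or not np.isfinite(delta_x):
            record[out_col] = None
            logger.info("subject %s: no %s waveforms, PWV null", subject_id, segment)
            continue
        record[out_col] = _segment_pwv(base, subject_id, segment, float(delta_x), config).pwv

    # --- contours: distensibility, LA, LV, carotid wall ------------------- #
    spacing = config.slice_thickness_mm + config.gap_mm
    contour_path = base / "contours" / f"{subject_id}.csv"
    if not contour_path.exists():
        raise SchemaError(f"missing contour file for subject {subject_id}: {contour_path}")
    contours = read_contours_csv(contour_path, slice_thickness=spacing)
    present = set(contours.structures())

    for location, out_col in _LOCATION_COLUMNS.items():
        if location not in present:
            record[out_col] = None
            if location in AORTIC_LOCATIONS:
                logger.info("subject %s: no %s contours, distensibility null",
                            subject_id, location)
            continue
        phases = contours.phases(location)
        areas = [
            sum(_areas_at(contours, location, int(p)).values()) for p in phases
        ]
        curve = AreaCurve(location=location, areas=np.asarray(areas))
        record[out_col] = distensibility_result(curve, bp).distensibility

    # LA block
    if "LA" in present:
        vc = volume_curve(contours, "LA")
        lm = la_landmarks(vc)
        laf = la_function(
            float(vc.volumes[lm.phase_max]),
            float(vc.volumes[lm.phase_ac]),
            float(vc.volumes[lm.phase_min]),
            bsa,
        )
        record.update(
            la_vol_max_i=laf.vol_max, la_vol_ac_i=laf.vol_ac, la_vol_min_i=laf.vol_min,
            la_total_emptying_i=laf.total_emptying, v_passive_i=laf.v_passive,
            v_contractile_i=laf.v_contractile, laef_passive=laf.laef_passive,
            laef_contractile=laf.laef_contractile, laef_reservoir=laf.laef_reservoir,
            la_ac_fallback=lm.ac_fallback,
        )
    else:
        logger.info("subject %s: no LA contours, LA block null", subject_id)
        record.update({k: None for k in (
            "la_vol_max_i", "la_vol_ac_i", "la_vol_min_i", "la_total_emptying_i",
            "v_passive_i", "v_contractile_i", "laef_passive", "laef_contractile",
            "laef_reservoir", "la_ac_fallback")})

    # LV block
    if "LV-endo" in present:
        endo = volume_curve(contours, "LV-endo")
        ed_phase = int(contours.phases("LV-endo")[int(np.argmax(endo.volumes))])
        edv, esv = float(np.max(endo.volumes)), float(np.min(endo.volumes))
        if "LV-epi" in present:
            epi_phases = contours.phases("LV-epi")
            epi_phase = ed_phase if ed_phase in epi_phases else int(epi_phases[0])
            epi_ed = sum(
                _areas_at(contours, "LV-epi", epi_phase).values()
            ) * spacing / 1000.0
        else:
            epi_ed = edv
            logger.info("subject %s: no LV-epi contours, mass from endo only", subject_id)
        lvf = lv_function(edv, esv, max(epi_ed, edv), bsa)
        record.update(lvedv_i=lvf.edv, lvesv_i=lvf.esv, lvsv_i=lvf.sv,
                      lvef=lvf.ef, lv_mass_i=lvf.mass)
    else:
        logger.info("subject %s: no LV contours, LV block null", subject_id)
        record.update({k: None for k in ("lvedv_i", "lvesv_i", "lvsv_i", "lvef", "lv_mass_i")})

    # carotid wall block
    for side in ("left", "right"):
        areas, thicknesses = [], []
        for level in ("proximal", "distal"):
            inner_s, outer_s = f"carotid-inner-{side}-{level}", f"carotid-outer-{side}-{level}"
            if inner_s not in present or outer_s not in present:
                continue
            pair = WallContourPair(
                side=side, level=level,
                inner=contours.polygon(inner_s, 0, 0),
                outer=contours.polygon(outer_s, 0, 0),
            )
            wm = wall_metrics(pair, config.wall_positions)
            areas.append(wm.wall_area)
            thicknesses.append(wm.wall_thickness)
        if areas:
            record[f"wall_area_{side}"] = float(np.mean(areas))
            record[f"wall_thickness_{side}"] = float(np.mean(thicknesses))
        else:
            record[f"wall_area_{side}"] = None
            record[f"wall_thickness_{side}"] = None
            logger.info("subject %s: no %s carotid wall contours, wall block null",
                        subject_id, side)
    return record


def _areas_at(contours: ContourSet, structure: str, phase: int) -> dict:
    from .lumen import polygon_area

    return {sl: polygon_area(v) for sl, v in contours.polygons_at_phase(structure, phase).items()}


def run_cohort(config: RunConfig):
    """Run every subject, compare groups, fit the LME, write report files.

    Writes ``records.csv``, ``group_comparison.csv``, ``lme_coefficients.csv``
    and ``run_log.txt`` under ``config.output_dir``; returns the three tables.
    """
    base = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = read_subjects_csv(base / "subjects.csv")
    for group in ("patient", "control"):
        if (subjects["group"] == group).sum() < 2:
            raise SchemaError(f"group {group!r} missing or has fewer than 2 subjects")

    records = pd.DataFrame(
        [run_subject(config, sid, subjects) for sid in subjects["subject_id"]]
    )
    records.to_csv(out / "records.csv", index=False)

    numeric = records.drop(columns=["hypertension_stage", "la_ac_fallback"], errors="ignore")
    for col in numeric.columns:
        if col not in ("subject_id", "group"):
            numeric[col] = pd.to_numeric(numeric[col])
    comparison = group_comparison_table(numeric.drop(columns=["subject_id"]))
    comparison.to_csv(out / "group_comparison.csv", index=False)

    # random-intercept distensibility model, patient group only
    pat = records[records["group"] == "patient"].merge(
        subjects[["subject_id", "age_at_repair", "age_at_mri"]], on="subject_id"
    )
    long_rows = []
    for location in AORTIC_LOCATIONS:
        col = _LOCATION_COLUMNS[location]
        for _, r in pat.iterrows():
            if r[col] is not None and np.isfinite(r[col]):
                long_rows.append(
                    {"subject_id": r["subject_id"], "location": location,
                     "distensibility": float(r[col]),
                     "age_at_repair": r["age_at_repair"], "age_at_mri": r["age_at_mri"]}
                )
    lme_table = None
    if long_rows:
        fit = fit_distensibility_lme(pd.DataFrame(long_rows))
        lme_table = fit.fixed_effects.copy()
        lme_table.insert(0, "term", lme_table.index)
        lme_table = pd.concat(
            [lme_table, pd.DataFrame([
                {"term": "random_intercept_sd", "coef": fit.random_intercept_sd},
                {"term": "residual_sd", "coef": fit.residual_sd},
            ])],
            ignore_index=True,
        )
        lme_table.to_csv(out / "lme_coefficients.csv", index=False)

    log_lines = [f"vesselpulse {__version__}", "config:"]
    log_lines += [f"  {k}: {v}" for k, v in asdict(config).items()]
    log_lines.append(f"subjects: {len(subjects)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return records, comparison, lme_table
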