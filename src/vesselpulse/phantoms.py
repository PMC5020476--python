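"""Synthetic phantoms and simulated cohorts with known ground truth.

Every downstream estimator in this package is exercised on inputs built here:

* flow-waveform pairs with a known transit delay on the 9 ms phase-contrast
  sampling grid (half-sine systolic pulse on a constant baseline);
* lumen-area curves with a known distensibility;
* ellipsoidal chamber stacks whose analytic volume is recorded;
* annular carotid wall phantoms with prescribed wall area and thickness;
* two-group cohorts drawn from published group means/SDs with rank
  correlations induced by a Gaussian copula, then materialized down to raw
  waveforms and contours so the full pipeline runs end-to-end.

All generation is reproducible under an integer seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contours import ContourSet, contours_from_polygons
from .lumen import AORTIC_LOCATIONS, AreaCurve, bsa as bsa_formula

__all__ = [
    "WaveformSpec",
    "LumenPulsationSpec",
    "EllipsoidStackSpec",
    "EllipsoidStack",
    "CohortSpec",
    "GroupParam",
    "make_waveform_pair",
    "make_area_curve",
    "make_ellipsoid_stack",
    "make_cohort",
    "draw_cohort_parameters",
    "materialize_subject",
    "default_cohort_spec",
    "la_volume_profile",
    "circle_polygon",
    "annulus_pair",
    "pulsation_profile",
    "SubjectData",
]


# --------------------------------------------------------------------------- #
# flow waveforms
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class WaveformSpec:
    """Half-sine systolic pulse on a constant baseline, sampled at 9 ms.

    The systolic upstroke lasts ``upstroke_duration`` ms (half of the full
    half-sine pulse); the distal curve is the proximal curve delayed by
    ``true_delay`` ms and its pulsatile component scaled by ``attenuation``.
    """

    rr_interval: float = 830.0  # ms
    sample_spacing: float = 9.0  # ms
    systole_onset: float = 50.0  # ms
    upstroke_duration: float = 120.0  # ms
    peak_flow: float = 350.0  # ml/s
    baseline_flow: float = 10.0  # ml/s
    true_delay: float = 20.0  # ms
    attenuation: float = 0.85
    noise_sd: float = 0.0  # ml/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be positive")
        if not 0 < self.upstroke_duration < self.rr_interval:
            raise ValueError("require 0 < upstroke_duration < rr_interval")
        if self.true_delay < 0:
            raise ValueError("true_delay must be non-negative")
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must lie in (0, 1]")
        if self.true_delay >= self.rr_interval - self.systole_onset - self.upstroke_duration:
            raise ValueError("true_delay too large: pulse would leave the cardiac cycle window")

    def continuous_flow(self, t) -> np.ndarray:
        """Noise-free proximal flow at arbitrary times t (ms)."""
        t = np.asarray(t, dtype=float)
        width = 2.0 * self.upstroke_duration
        s = (t - self.systole_onset) / width
        pulse = np.where((s >= 0) & (s <= 1), np.sin(np.pi * np.clip(s, 0, 1)), 0.0)
        return self.baseline_flow + (self.peak_flow - self.baseline_flow) * pulse


def make_waveform_pair(spec: WaveformSpec):
    """Proximal and distal :class:`~vesselpulse.pulsewave.FlowWaveform`.

    The distal samples are the continuous proximal pulse evaluated at
    ``t - true_delay`` with its pulsatile part scaled by ``attenuation``;
    i.i.d. Gaussian noise of sd ``noise_sd`` is added to both curves.
    """
    from .pulsewave import FlowWaveform

    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.rr_interval, spec.sample_spacing)
    prox = spec.continuous_flow(t)
    dist = spec.baseline_flow + spec.attenuation * (
        spec.continuous_flow(t - spec.true_delay) - spec.baseline_flow
    )
    if spec.noise_sd > 0:
        prox = prox + rng.normal(0.0, spec.noise_sd, t.size)
        dist = dist + rng.normal(0.0, spec.noise_sd, t.size)
    return (
        FlowWaveform(site="proximal", times=t, flow=prox),
        FlowWaveform(site="distal", times=t, flow=dist),
    )


# --------------------------------------------------------------------------- #
# lumen pulsation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class LumenPulsationSpec:
    """Single-peak lumen-area curve with a prescribed distensibility.

    ``target_distensibility`` is expressed in the reporting unit of
    1e-3 / mmHg, so the maximal area is
    ``a_min * (1 + target_distensibility * 1e-3 * pulse_pressure)``.
    """

    a_min: float = 250.0  # mm^2
    target_distensibility: float = 4.0  # 1e-3 / mmHg
    pulse_pressure: float = 50.0  # mmHg
    phases: int = 25
    noise_sd: float = 0.0  # mm^2
    seed: int = 0
    location: str = "ascending aorta"

    def __post_init__(self) -> None:
        if self.a_min <= 0:
            raise ValueError("a_min must be positive")
        if self.target_distensibility < 0:
            raise ValueError("target_distensibility must be non-negative")
        if self.pulse_pressure <= 0:
            raise ValueError("pulse_pressure must be positive")
        if self.phases < 3:
            raise ValueError("need at least 3 phases")

    @property
    def a_max(self) -> float:
        return self.a_min * (1.0 + self.target_distensibility * 1e-3 * self.pulse_pressure)


def pulsation_profile(phases: int) -> np.ndarray:
    """Smooth single-peak profile over one cycle, rescaled to [0, 1] exactly."""
    k = np.arange(phases)
    s = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / phases))
    return (s - s.min()) / (s.max() - s.min())


def make_area_curve(spec: LumenPulsationSpec) -> AreaCurve:
    """Per-phase cross-sectional area with min ``a_min`` and max ``a_max``."""
    rng = np.random.default_rng(spec.seed)
    s = pulsation_profile(spec.phases)
    areas = spec.a_min * (1.0 + spec.target_distensibility * 1e-3 * spec.pulse_pressure * s)
    if spec.noise_sd > 0:
        areas = areas + rng.normal(0.0, spec.noise_sd, spec.phases)
        areas = np.maximum(areas, 1e-6)
    return AreaCurve(location=spec.location, areas=areas)


# --------------------------------------------------------------------------- #
# ellipsoid chamber stacks
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class EllipsoidStackSpec:
    """Ellipsoid sliced perpendicular to its c axis into contour polygons."""

    semi_axes: tuple[float, float, float] = (20.0, 20.0, 30.0)  # mm
    slice_thickness: float = 6.0  # mm
    vertices_per_contour: int = 64
    phases: int = 1
    volume_time_profile: object = "constant"  # name or per-phase scale factors
    structure: str = "LA"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(ax <= 0 for ax in self.semi_axes):
            raise ValueError("all semi-axes must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if self.vertices_per_contour < 8:
            raise ValueError("need at least 8 vertices per contour")
        if self.phases < 1:
            raise ValueError("need at least 1 phase")

    def scale_factors(self) -> np.ndarray:
        prof = self.volume_time_profile
        if isinstance(prof, str):
            if prof == "constant":
                return np.ones(self.phases)
            raise ValueError(f"unknown volume_time_profile {prof!r}")
        scales = np.asarray(prof, dtype=float)
        if scales.shape != (self.phases,) or np.any(scales <= 0):
            raise ValueError("scale factors must be positive, one per phase")
        return scales


@dataclass(frozen=True)
class EllipsoidStack:
    contours: ContourSet
    analytic_volumes_ml: np.ndarray  # per phase


def _exact_area_ellipse(cx, cy, rx, ry, n) -> np.ndarray:
    """n-gon whose shoelace area equals pi*rx*ry exactly (inflated vertices)."""
    inflate = 1.0 / math.sqrt(n * math.sin(2.0 * math.pi / n) / (2.0 * math.pi))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [cx + inflate * rx * np.cos(ang), cy + inflate * ry * np.sin(ang)]
    )


def circle_polygon(area_mm2: float, n: int = 64, cx: float = 0.0, cy: float = 0.0) -> np.ndarray:
    """Regular n-gon whose shoelace area equals ``area_mm2`` exactly."""
    r = math.sqrt(area_mm2 / math.pi)
    return _exact_area_ellipse(cx, cy, r, r, n)


def make_ellipsoid_stack(spec: EllipsoidStackSpec) -> EllipsoidStack:
    """Slice a (per-phase scaled) ellipsoid into elliptical contour polygons.

    Slice planes sit at slab centres spaced by ``slice_thickness``; the
    polygon at each plane has the analytic section area of the ellipsoid, so
    the slab-summation volume differs from the analytic volume only by the
    midpoint-rule discretization error, which vanishes quadratically as the
    thickness shrinks.  A degenerate ellipsoid shorter than half a slice still
    emits its centre slice.
    """
    a, b, c = spec.semi_axes
    scales = spec.scale_factors()
    records = []
    volumes = []
    for phase, s in enumerate(scales):
        as_, bs, cs = a * s, b * s, c * s
        centers = np.arange(-cs + spec.slice_thickness / 2.0, cs, spec.slice_thickness)
        if centers.size == 0:
            centers = np.array([0.0])
        for idx, z in enumerate(centers):
            frac = max(0.0, 1.0 - (z / cs) ** 2)
            if frac <= 0:
                continue
            rx = as_ * math.sqrt(frac)
            ry = bs * math.sqrt(frac)
            records.append(
                (spec.structure, idx, phase,
                 _exact_area_ellipse(0.0, 0.0, rx, ry, spec.vertices_per_contour))
            )
        volumes.append(4.0 / 3.0 * math.pi * as_ * bs * cs / 1000.0)  # ml
    return EllipsoidStack(
        contours=contours_from_polygons(records, spec.slice_thickness),
        analytic_volumes_ml=np.asarray(volumes),
    )


def la_volume_profile(vol_max: float, vol_ac: float, vol_min: float, phases: int = 25):
    """Canonical biphasic LA volume curve through the three landmark volumes.

    Reservoir filling to the maximum at ~40 % of the cycle, conduit emptying
    with a shallow dip, a shoulder (local maximum) at ``vol_ac`` just before
    the atrial kick, and the minimum near end-cycle.  Returns
    ``(volumes, (phase_max, phase_ac, phase_min))``; the curve attains the
    three landmark volumes exactly at those phases.
    """
    if not vol_max > vol_ac > vol_min >= 0:
        raise ValueError("require vol_max > vol_ac > vol_min >= 0")
    if phases < 10:
        raise ValueError("need at least 10 phases for a biphasic LA curve")
    p_max = int(round(0.40 * (phases - 1)))
    p_min = phases - 2
    p_ac = p_max + int(round(0.70 * (p_min - p_max)))
    p_ac = min(max(p_ac, p_max + 2), p_min - 2)
    p_dip = (p_max + p_ac + 1) // 2

    rng_range = vol_max - vol_min
    v0 = vol_min + 0.10 * rng_range
    dip = vol_ac - min(0.04 * rng_range, 0.45 * (vol_ac - vol_min))
    v_end = vol_min + 0.05 * rng_range

    knots = [(0, v0), (p_max, vol_max), (p_dip, dip), (p_ac, vol_ac),
             (p_min, vol_min), (phases - 1, v_end)]
    v = np.empty(phases)
    for (pa, va), (pb, vb) in zip(knots[:-1], knots[1:]):
        idx = np.arange(pa, pb + 1)
        s = (idx - pa) / max(pb - pa, 1)
        v[idx] = va + (vb - va) * 0.5 * (1.0 - np.cos(np.pi * s))
    return v, (p_max, p_ac, p_min)


def annulus_pair(wall_area_mm2: float, thickness_mm: float, n: int = 64):
    """Concentric inner/outer ring polygons with exact wall area.

    Radii solve pi*(R_out^2 - R_in^2) = wall_area with R_out - R_in =
    thickness; vertices are area-exact polygons, so the polygon wall area
    equals the target to floating-point precision.
    """
    if wall_area_mm2 <= math.pi * thickness_mm**2:
        raise ValueError("wall area too small for the requested thickness")
    r_sum = wall_area_mm2 / (math.pi * thickness_mm)
    r_in = (r_sum - thickness_mm) / 2.0
    r_out = r_in + thickness_mm
    inner = circle_polygon(math.pi * r_in**2, n)
    outer = circle_polygon(math.pi * r_out**2, n)
    return inner, outer


# --------------------------------------------------------------------------- #
# cohort simulation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class GroupParam:
    """Normal marginal (truncated at a physiologic floor) for one parameter."""

    patient_mean: float
    patient_sd: float
    control_mean: float
    control_sd: float
    floor: float = -np.inf

    def __post_init__(self) -> None:
        if self.patient_sd < 0 or self.control_sd < 0:
            raise ValueError("SDs must be non-negative")


def _table_parameters() -> dict[str, GroupParam]:
    """Published group means/SDs used as simulation parameters."""
    g = GroupParam
    return {
        # clinical characteristics
        "age_at_mri": g(17.3, 10.0, 19.8, 10.0, 0.9),
        "age_at_repair": g(4.2, 6.1, np.nan, np.nan, 0.01),
        "height": g(163.7, 24.2, 165.5, 20.9, 60.0),
        "weight": g(61.8, 26.6, 58.0, 21.3, 7.0),
        "systolic": g(111.9, 15.4, 107.0, 8.7, 80.0),
        "diastolic": g(60.5, 9.6, 61.6, 10.5, 40.0),
        "heart_rate": g(74.1, 15.7, 70.3, 16.9, 45.0),
        # aortic bioelasticity (distensibility in 1e-3/mmHg, PWV in m/s)
        "dist_aortic_root": g(5.6, 3.8, 7.4, 3.0, 0.3),
        "dist_ascending_aorta": g(5.8, 3.1, 8.1, 3.6, 0.3),
        "dist_isthmus": g(5.7, 3.0, 6.8, 2.3, 0.3),
        "dist_descending_aorta": g(6.8, 2.8, 8.0, 2.8, 0.3),
        "pwv_arch": g(4.6, 1.7, 3.5, 0.8, 1.3),
        "pwv_dao": g(4.3, 1.6, 3.9, 0.8, 1.3),
        # maximal aortic areas, BSA-indexed (mm^2/m^2)
        "max_area_root_i": g(449.5, 126.1, 440.5, 93.0, 120.0),
        "max_area_asc_i": g(353.2, 104.5, 356.3, 68.4, 90.0),
        "max_area_isthmus_i": g(163.2, 61.5, 176.9, 32.0, 45.0),
        "max_area_dao_i": g(151.9, 35.3, 155.2, 38.0, 45.0),
        # left heart, BSA-indexed
        "la_vol_max_i": g(47.5, 10.2, 43.2, 8.7, 15.0),
        "la_vol_ac_i": g(32.3, 8.0, 27.4, 5.9, 8.0),
        "la_vol_min_i": g(24.6, 6.1, 20.9, 5.1, 5.0),
        "lvedv_i": g(81.0, 15.3, 80.1, 12.0, 30.0),
        "lvesv_i": g(30.4, 12.0, 31.0, 6.2, 8.0),
        "lv_mass_i": g(60.7, 14.1, 57.5, 14.2, 20.0),
        # carotid substudy
        "wall_area_right": g(19.4, 2.4, 15.3, 2.6, 6.0),
        "wall_area_left": g(19.7, 4.1, 15.8, 1.9, 6.0),
        "wall_thickness_right": g(0.90, 0.12, 0.75, 0.09, 0.35),
        "wall_thickness_left": g(0.90, 0.12, 0.76, 0.08, 0.35),
        "pwv_carotid_right": g(6.8, 4.1, 3.3, 1.5, 1.3),
        "pwv_carotid_left": g(6.9, 4.0, 4.2, 1.7, 1.3),
        "dist_carotid_right_proximal": g(10.4, 7.0, 5.9, 3.8, 0.3),
        "dist_carotid_right_distal": g(8.3, 2.9, 7.9, 3.0, 0.3),
        "dist_carotid_left_proximal": g(8.7, 5.8, 8.1, 5.5, 0.3),
        "dist_carotid_left_distal": g(7.1, 4.8, 6.2, 2.2, 0.3),
    }


def _default_correlations() -> dict[tuple[str, str], float]:
    """Default Spearman rank-correlation targets between latent parameters."""
    return {
        ("height", "weight"): 0.85,
        ("systolic", "diastolic"): 0.50,
        ("age_at_mri", "age_at_repair"): 0.50,
        ("la_vol_max_i", "la_vol_ac_i"): 0.90,
        ("la_vol_ac_i", "la_vol_min_i"): 0.90,
        ("la_vol_max_i", "la_vol_min_i"): 0.81,
        ("lvedv_i", "lvesv_i"): 0.70,
        # associations reported for the patient group; arch PWV correlates
        # with all three LA volumes (they are mutually near-collinear, so a
        # correlation with vol_ac alone would be jointly infeasible)
        ("age_at_repair", "pwv_dao"): 0.33,
        ("age_at_repair", "dist_isthmus"): -0.33,
        ("pwv_arch", "la_vol_ac_i"): 0.33,
        ("pwv_arch", "la_vol_max_i"): 0.28,
        ("pwv_arch", "la_vol_min_i"): 0.30,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort specification.

    ``parameters`` maps latent parameter names to truncated-normal group
    marginals; ``spearman_correlations`` lists target rank correlations
    induced through a Gaussian copula (identical in both groups).
    """

    n_patients: int = 51
    n_controls: int = 54
    n_carotid_patients: int = 11
    n_carotid_controls: int = 13
    parameters: dict = field(default_factory=_table_parameters)
    spearman_correlations: dict = field(default_factory=_default_correlations)
    phases: int = 25
    slice_thickness: float = 6.0
    waveform_noise_fraction: float = 0.02  # of pulse amplitude
    area_noise_sd: float = 0.0  # mm^2, on lumen area curves
    delta_x_arch_m: float = 0.12
    delta_x_dao_m: float = 0.14
    delta_x_carotid_m: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        for (a, b), rho in self.spearman_correlations.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation {a}~{b} outside [-1, 1]")
            if a not in self.parameters or b not in self.parameters:
                raise ValueError(f"correlation references unknown parameter: {a}~{b}")


def default_cohort_spec(**overrides) -> CohortSpec:
    """The study-conditions cohort: published group sizes, means and SDs."""
    return CohortSpec(**overrides)


def _copula_matrix(names: list[str], spearman: dict[tuple[str, str], float]) -> np.ndarray:
    """Pearson copula correlation matrix from Spearman targets; PSD-checked."""
    idx = {n: i for i, n in enumerate(names)}
    r = np.eye(len(names))
    for (a, b), rho_s in spearman.items():
        rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho_p
    eig = np.linalg.eigvalsh(r)
    if eig.min() < -1e-10:
        raise ValueError(
            f"infeasible correlation matrix: smallest eigenvalue {eig.min():.3g} < 0"
        )
    return r


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, floor: float) -> np.ndarray:
    if sd == 0:
        return np.full_like(u, mean)
    a = (floor - mean) / sd
    return sps.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)


def draw_cohort_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Latent per-subject parameter table (the simulation's ground truth).

    Marginals are truncated normals at physiologic floors; rank correlations
    are induced by ordering through a Gaussian copula.  A handful of hard
    physiologic constraints are enforced after the draw (LA volume ordering,
    ESV < EDV, pulse pressure >= 5 mmHg); these clip a small tail of draws.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.parameters)
    corr = _copula_matrix(names, spec.spearman_correlations)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))

    frames = []
    for group, n in (("patient", spec.n_patients), ("control", spec.n_controls)):
        z = rng.standard_normal((n, len(names))) @ chol.T
        u = sps.norm.cdf(z)
        cols: dict[str, np.ndarray] = {}
        for j, name in enumerate(names):
            p = spec.parameters[name]
            mean = p.patient_mean if group == "patient" else p.control_mean
            sd = p.patient_sd if group == "patient" else p.control_sd
            if np.isnan(mean):
                cols[name] = np.full(n, np.nan)
            else:
                cols[name] = _truncnorm_ppf(u[:, j], mean, sd, p.floor)
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        prefix = "P" if group == "patient" else "C"
        df.insert(0, "subject_id", [f"{prefix}{i + 1:03d}" for i in range(n)])
        p_female = 18 / 51 if group == "patient" else 31 / 54
        df["sex"] = np.where(rng.random(n) < p_female, "F", "M")
        if group == "patient":
            df["antihypertensive_treatment"] = rng.random(n) < 13 / 51
            df["age_at_repair"] = np.minimum(df["age_at_repair"], df["age_at_mri"] - 0.01)
        else:
            df["antihypertensive_treatment"] = False
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)

    # hard physiologic constraints (documented tail clipping)
    out["systolic"] = np.maximum(out["systolic"], out["diastolic"] + 5.0)
    out["la_vol_ac_i"] = np.minimum(out["la_vol_ac_i"], 0.98 * out["la_vol_max_i"])
    out["la_vol_min_i"] = np.minimum(out["la_vol_min_i"], 0.98 * out["la_vol_ac_i"])
    out["lvesv_i"] = np.minimum(out["lvesv_i"], 0.95 * out["lvedv_i"])

    out["bsa"] = [bsa_formula(h, w) for h, w in zip(out["height"], out["weight"])]
    out["delta_x_arch_m"] = spec.delta_x_arch_m
    out["delta_x_dao_m"] = spec.delta_x_dao_m
    # carotid data only for the substudy subgroup (first n per group)
    has_carotid = np.zeros(len(out), dtype=bool)
    has_carotid[: spec.n_carotid_patients] = True
    ctrl_start = spec.n_patients
    has_carotid[ctrl_start : ctrl_start + spec.n_carotid_controls] = True
    out["has_carotid"] = has_carotid
    out["delta_x_carotid_m"] = np.where(has_carotid, spec.delta_x_carotid_m, np.nan)
    return out


# --------------------------------------------------------------------------- #
# materialization: latent truth -> raw waveforms and contours
# --------------------------------------------------------------------------- #

@dataclass
class SubjectData:
    """Raw per-subject inputs: waveform pairs per segment plus one contour set."""

    subject_id: str
    waveforms: dict  # segment -> (proximal FlowWaveform, distal FlowWaveform)
    contours: ContourSet


_AORTIC_LATENT = {
    "aortic root": ("dist_aortic_root", "max_area_root_i"),
    "ascending aorta": ("dist_ascending_aorta", "max_area_asc_i"),
    "isthmus": ("dist_isthmus", "max_area_isthmus_i"),
    "descending aorta at diaphragm": ("dist_descending_aorta", "max_area_dao_i"),
}

_WAVEFORM_SHAPES = {
    # segment -> (peak ml/s, baseline ml/s)
    "arch": (350.0, 10.0),
    "dao": (200.0, 5.0),
    "carotid_left": (8.0, 0.5),
    "carotid_right": (8.0, 0.5),
}


def _segment_waveforms(row, segment: str, delta_x_m: float, pwv: float,
                       spec: CohortSpec, seed: int):
    peak, base = _WAVEFORM_SHAPES[segment]
    rr = 60000.0 / row["heart_rate"]
    delay = delta_x_m / pwv * 1000.0
    wspec = WaveformSpec(
        rr_interval=rr,
        sample_spacing=9.0,
        systole_onset=0.06 * rr,
        upstroke_duration=min(120.0, 0.25 * rr),
        peak_flow=peak,
        baseline_flow=base,
        true_delay=delay,
        attenuation=0.85,
        noise_sd=spec.waveform_noise_fraction * (peak - base),
        seed=seed,
    )
    return make_waveform_pair(wspec)


def materialize_subject(row: pd.Series, spec: CohortSpec) -> SubjectData:
    """Raw waveforms and contours realizing one subject's latent parameters."""
    sid = row["subject_id"]
    seed_base = (spec.seed * 1000003 + zlib.crc32(sid.encode())) % (2**31 - 64)
    bsa = row["bsa"]
    pulse_pressure = row["systolic"] - row["diastolic"]
    records = []

    # aortic + carotid lumen area curves as single-slice circle polygons
    lumen_targets = dict(_AORTIC_LATENT)
    if row["has_carotid"]:
        for side in ("left", "right"):
            for level in ("proximal", "distal"):
                lumen_targets[f"carotid {side} {level}"] = (
                    f"dist_carotid_{side}_{level}",
                    None,
                )
    for location, (dist_key, area_key) in lumen_targets.items():
        if area_key is not None:
            a_max = row[area_key] * bsa
        else:
            a_max = 32.0  # carotid lumen, mm^2
        d = row[dist_key]
        a_min = a_max / (1.0 + d * 1e-3 * pulse_pressure)
        curve = make_area_curve(
            LumenPulsationSpec(
                a_min=a_min,
                target_distensibility=d,
                pulse_pressure=pulse_pressure,
                phases=spec.phases,
                noise_sd=spec.area_noise_sd,
                seed=seed_base + 11,
                location=location,
            )
        )
        for phase, area in enumerate(curve.areas):
            records.append((location, 0, phase, circle_polygon(area, 64)))

    # LA stack: biphasic volume curve realized as a scaled sphere stack
    la_max = row["la_vol_max_i"] * bsa
    la_ac = row["la_vol_ac_i"] * bsa
    la_min = row["la_vol_min_i"] * bsa
    la_vols, _ = la_volume_profile(la_max, la_ac, la_min, spec.phases)
    r0 = (3.0 * la_max * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    la_stack = make_ellipsoid_stack(
        EllipsoidStackSpec(
            semi_axes=(r0, r0, r0),
            slice_thickness=spec.slice_thickness,
            vertices_per_contour=48,
            phases=spec.phases,
            volume_time_profile=(la_vols / la_max) ** (1.0 / 3.0),
            structure="LA",
        )
    )
    records.extend(_contour_records(la_stack.contours))

    # LV: prolate ellipsoid, phase 0 = end-diastole, phase 1 = end-systole
    edv = row["lvedv_i"] * bsa
    esv = row["lvesv_i"] * bsa
    epi_ed = edv + row["lv_mass_i"] * bsa / 1.05
    a_endo = (3.0 * edv * 1000.0 / (4.0 * math.pi * 2.5)) ** (1.0 / 3.0)
    endo_stack = make_ellipsoid_stack(
        EllipsoidStackSpec(
            semi_axes=(a_endo, a_endo, 2.5 * a_endo),
            slice_thickness=spec.slice_thickness,
            vertices_per_contour=48,
            phases=2,
            volume_time_profile=np.array([1.0, (esv / edv) ** (1.0 / 3.0)]),
            structure="LV-endo",
        )
    )
    records.extend(_contour_records(endo_stack.contours))
    a_epi = a_endo * (epi_ed / edv) ** (1.0 / 3.0)
    epi_stack = make_ellipsoid_stack(
        EllipsoidStackSpec(
            semi_axes=(a_epi, a_epi, 2.5 * a_epi),
            slice_thickness=spec.slice_thickness,
            vertices_per_contour=48,
            phases=1,
            structure="LV-epi",
        )
    )
    records.extend(_contour_records(epi_stack.contours))

    # carotid wall rings
    if row["has_carotid"]:
        for side in ("left", "right"):
            inner, outer = annulus_pair(
                row[f"wall_area_{side}"], row[f"wall_thickness_{side}"], n=64
            )
            for level in ("proximal", "distal"):
                records.append((f"carotid-inner-{side}-{level}", 0, 0, inner))
                records.append((f"carotid-outer-{side}-{level}", 0, 0, outer))

    contours = contours_from_polygons(records, spec.slice_thickness)

    waveforms = {
        "arch": _segment_waveforms(row, "arch", row["delta_x_arch_m"], row["pwv_arch"],
                                   spec, seed_base + 1),
        "dao": _segment_waveforms(row, "dao", row["delta_x_dao_m"], row["pwv_dao"],
                                  spec, seed_base + 2),
    }
    if row["has_carotid"]:
        for k, side in enumerate(("left", "right")):
            waveforms[f"carotid_{side}"] = _segment_waveforms(
                row, f"carotid_{side}", row["delta_x_carotid_m"],
                row[f"pwv_carotid_{side}"], spec, seed_base + 3 + k,
            )
    return SubjectData(subject_id=sid, waveforms=waveforms, contours=contours)


def _contour_records(cs: ContourSet):
    for (structure, sl, ph), grp in cs.data.groupby(
        ["structure", "slice_index", "phase"], sort=False
    ):
        verts = grp.sort_values("vertex_index")[["x_mm", "y_mm"]].to_numpy()
        yield (structure, int(sl), int(ph), verts)


def make_cohort(spec: CohortSpec, materialize: bool = True):
    """Draw a two-group cohort; optionally materialize raw inputs per subject.

    Returns ``(subjects, data)`` where ``subjects`` is the latent parameter
    table and ``data`` maps subject_id to :class:`SubjectData` (empty dict
    when ``materialize`` is False).
    """
    subjects = draw_cohort_parameters(spec)
    data: dict[str, SubjectData] = {}
    if materialize:
        for _, row in subjects.iterrows():
            data[row["subject_id"]] = materialize_subject(row, spec)
    return subjects, data
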