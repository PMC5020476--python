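"""Chamber volumetrics: Simpson's-rule volumes, LA phase landmarks, LA and LV function.

"Simpson's rule" is used here in its cardiac-MR sense — the chamber volume is
the sum of planimetered slice areas times the slice spacing (a slab/disk
summation), not the quadrature rule of the same name.

Left-atrial function is summarized by three landmark volumes read off the LA
volume-versus-phase curve,

* ``vol_max`` — maximal LA volume just before mitral valve opening,
* ``vol_ac``  — LA volume just before atrial contraction (the pre-kick shoulder),
* ``vol_min`` — minimal LA volume at mitral valve closure,

and the six derived parameters

* total emptying volume      = vol_max - vol_min
* passive emptying volume    = vol_max - vol_ac
* contractile volume         = vol_ac - vol_min
* LAEF_passive (%)           = (vol_max - vol_ac) * 100 / vol_max
* LAEF_contractile (%)       = (vol_ac - vol_min) * 100 / vol_ac
* LAEF_reservoir (%)         = (vol_max - vol_min) * 100 / vol_max

which serve as surrogate markers of LV diastolic function.  LV systolic
function uses the standard end-diastolic/end-systolic endocardial volumes with
myocardial mass from the epicardial-endocardial shell at 1.05 g/ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import ContourSet
from .lumen import polygon_area

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


class LandmarkError(ValueError):
    """Raised when the LA volume curve does not show an atrial cycle."""


@dataclass(frozen=True)
class VolumeCurve:
    """Chamber volume (ml) per cardiac phase."""

    chamber: str  # "LA" | "LV-endo" | "LV-epi"
    volumes: np.ndarray
    slice_thickness: float  # mm

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "volumes", vols)
        if vols.ndim != 1 or vols.size < 1:
            raise ValueError("volumes must be a non-empty 1-D array")
        if np.any(vols < 0) or not np.isfinite(vols).all():
            raise ValueError("volumes must be finite and non-negative")


@dataclass(frozen=True)
class LaLandmarks:
    phase_max: int
    phase_ac: int
    phase_min: int
    ac_fallback: bool = False  # True when the minimal-downslope rule fired


@dataclass(frozen=True)
class LaFunction:
    """Six-parameter LA function; volumes BSA-indexed (ml/m^2), fractions in %."""

    vol_max: float
    vol_ac: float
    vol_min: float
    total_emptying: float
    v_passive: float
    v_contractile: float
    laef_passive: float
    laef_contractile: float
    laef_reservoir: float


@dataclass(frozen=True)
class LvFunction:
    """LV volumetrics; volumes and mass BSA-indexed, EF in %."""

    edv: float
    esv: float
    sv: float
    ef: float
    mass: float


def simpson_volume(contours: ContourSet, chamber: str, phase: int) -> float:
    """Slice-summation volume (ml) of a chamber at one cardiac phase.

    Sum over slices of polygon area (mm^2) x slice thickness (mm), converted
    mm^3 -> ml.  A phase with no contour at all is an error, never a silent
    zero; slices absent at this phase simply do not contribute.
    """
    polys = contours.polygons_at_phase(chamber, phase)
    if not polys:
        raise KeyError(f"no contours for chamber {chamber!r} at phase {phase}")
    total_mm3 = sum(polygon_area(v) for v in polys.values()) * contours.slice_thickness
    return total_mm3 / 1000.0


def volume_curve(contours: ContourSet, chamber: str) -> VolumeCurve:
    """Simpson volume at every phase where the chamber has contours."""
    phases = contours.phases(chamber)
    if phases.size == 0:
        raise KeyError(f"no contours for chamber {chamber!r}")
    vols = np.array([simpson_volume(contours, chamber, int(p)) for p in phases])
    return VolumeCurve(chamber=chamber, volumes=vols, slice_thickness=contours.slice_thickness)


def la_landmarks(volcurve: VolumeCurve) -> LaLandmarks:
    """Locate the three LA landmark phases on a full-cycle volume curve.

    ``phase_max`` is the global maximum; ``phase_min`` is the global minimum,
    required to occur after the maximum within the acquired (R-wave-gated)
    cycle; ``phase_ac`` is the last strict local maximum between them — the
    shoulder just before the atrial kick.  When no interior local maximum
    exists (fused phases, e.g. at high heart rate), a fallback picks the phase
    of minimal downslope magnitude between mid-diastole and the minimum, and
    the result is flagged.
    """
    v = volcurve.volumes
    n = v.size
    if n < 3:
        raise LandmarkError("no atrial cycle detected: fewer than 3 phases")
    pmax = int(np.argmax(v))
    vmin = float(np.min(v))
    if float(v[pmax]) <= vmin:
        raise LandmarkError("no atrial cycle detected: constant volume curve")
    after = np.nonzero(v[pmax + 1 :] == vmin)[0]
    if after.size == 0:
        raise LandmarkError(
            "no atrial cycle detected: global minimum precedes the maximum in the cycle"
        )
    pmin = pmax + 1 + int(after[0])
    if pmin - pmax < 2:
        raise LandmarkError("no atrial cycle detected: emptying spans fewer than 2 phases")

    # last strict interior local maximum between pmax and pmin
    pac = None
    for i in range(pmin - 1, pmax, -1):
        if v[i - 1] < v[i] and v[i] > v[i + 1]:
            pac = i
            break
    if pac is not None:
        return LaLandmarks(phase_max=pmax, phase_ac=pac, phase_min=pmin, ac_fallback=False)

    mid = pmax + (pmin - pmax) // 2
    lo = max(pmax + 1, mid)
    slopes = np.abs(np.diff(v))  # slopes[i] = |v[i+1]-v[i]|
    i_candidates = np.arange(lo, pmin)
    pac = int(i_candidates[np.argmin(slopes[lo:pmin])])
    return LaLandmarks(phase_max=pmax, phase_ac=pac, phase_min=pmin, ac_fallback=True)


def la_function(vol_max: float, vol_ac: float, vol_min: float, bsa: float) -> LaFunction:
    """Six LA parameters from the landmark volumes (ml), BSA-indexed.

    Emptying fractions are ratios and therefore identical on raw and indexed
    volumes; the volumes in the result are divided by BSA (m^2).
    """
    if not (vol_max >= vol_ac >= vol_min >= 0):
        raise ValueError("require vol_max >= vol_ac >= vol_min >= 0")
    if vol_max <= 0:
        raise ValueError("vol_max must be positive")
    if bsa <= 0:
        raise ValueError("bsa must be positive")
    v_passive = vol_max - vol_ac
    v_contractile = vol_ac - vol_min
    laef_passive = v_passive * 100.0 / vol_max
    laef_contractile = v_contractile * 100.0 / vol_ac if vol_ac > 0 else 0.0
    laef_reservoir = (vol_max - vol_min) * 100.0 / vol_max
    v_passive_i = v_passive / bsa
    v_contractile_i = v_contractile / bsa
    return LaFunction(
        vol_max=vol_max / bsa,
        vol_ac=vol_ac / bsa,
        vol_min=vol_min / bsa,
        # summed after indexing so the volume-split identity is exact
        total_emptying=v_passive_i + v_contractile_i,
        v_passive=v_passive_i,
        v_contractile=v_contractile_i,
        laef_passive=laef_passive,
        laef_contractile=laef_contractile,
        laef_reservoir=laef_reservoir,
    )


def lv_function(endo_ed: float, endo_es: float, epi_ed: float, bsa: float) -> LvFunction:
    """LV EDV/ESV/SV/EF and mass from end-diastolic/systolic volumes (ml)."""
    if not (epi_ed >= endo_ed >= endo_es >= 0):
        raise ValueError("require epi_ed >= endo_ed >= endo_es >= 0")
    if endo_ed <= 0:
        raise ValueError("end-diastolic volume must be positive")
    if bsa <= 0:
        raise ValueError("bsa must be positive")
    sv = endo_ed - endo_es
    ef = sv * 100.0 / endo_ed
    mass = (epi_ed - endo_ed) * MYOCARDIAL_DENSITY_G_PER_ML
    return LvFunction(edv=endo_ed / bsa, esv=endo_es / bsa, sv=sv / bsa, ef=ef, mass=mass / bsa)
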