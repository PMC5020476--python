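"""Lumen cross-sectional areas and regional distensibility.

Distensibility relates the pulsatile change in lumen cross-sectional area to
the driving pulse pressure:

    D = (A_max - A_min) / (A_min * (P_sys - P_dia))

with A_min/A_max the minimal and maximal cross-sectional area over the cardiac
cycle and the pressures taken from the brachial cuff.  It is reported here in
units of 1e-3 per mmHg, the customary scale for aortic and carotid values.
Lower distensibility means a stiffer vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

AORTIC_LOCATIONS = (
    "aortic root",
    "ascending aorta",
    "isthmus",
    "descending aorta at diaphragm",
)

CAROTID_LUMEN_LOCATIONS = tuple(
    f"carotid {side} {level}" for side in ("left", "right") for level in ("proximal", "distal")
)


@dataclass(frozen=True)
class AreaCurve:
    """Cross-sectional area per cardiac phase at one anatomic location."""

    location: str
    areas: np.ndarray  # mm^2, one per phase

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", areas)
        if areas.ndim != 1 or areas.size < 3:
            raise ValueError("need at least 3 cardiac phases")
        if not np.isfinite(areas).all() or np.any(areas <= 0):
            raise ValueError("areas must be finite and positive")


@dataclass(frozen=True)
class BloodPressure:
    """Cuff systolic/diastolic pressure in mmHg."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic > 0:
            raise ValueError("require systolic > diastolic > 0")

    @property
    def pulse_pressure(self) -> float:
        return self.systolic - self.diastolic


@dataclass(frozen=True)
class DistensibilityResult:
    location: str
    a_min: float  # mm^2
    a_max: float  # mm^2
    distensibility: float  # 1e-3 / mmHg


def polygon_area(vertices) -> float:
    """Absolute (orientation-independent) shoelace area of a simple polygon.

    ``vertices`` is an (n, 2) array of planar points in mm; the polygon is
    closed implicitly.  Self-intersecting polygons are rejected.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 planar vertices")
    if not np.isfinite(pts).all():
        raise ValueError("polygon vertices must be finite")
    ring = shapely.LinearRing(pts)
    if not ring.is_simple:
        raise ValueError("self-intersecting polygon")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return abs(float(area))


def area_extremes(curve: AreaCurve, smooth_window: int | None = None) -> tuple[float, float]:
    """Global (A_min, A_max) over cardiac phases.

    ``smooth_window`` optionally applies a centred moving average (cyclic, odd
    window) before taking the extremes, for noisy contour series; the default
    uses the raw per-phase areas.
    """
    areas = curve.areas
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        kernel = np.ones(smooth_window) / smooth_window
        padded = np.concatenate([areas[-(smooth_window // 2):], areas, areas[: smooth_window // 2]])
        areas = np.convolve(padded, kernel, mode="valid")
    return float(np.min(areas)), float(np.max(areas))


def distensibility(a_min: float, a_max: float, bp: BloodPressure) -> float:
    """Distensibility in 1e-3 / mmHg from area extremes and cuff pressures."""
    if a_min <= 0:
        raise ValueError("a_min must be positive")
    if a_max < a_min:
        raise ValueError("a_max must be >= a_min")
    return (a_max - a_min) / (a_min * bp.pulse_pressure) * 1e3


def distensibility_result(curve: AreaCurve, bp: BloodPressure) -> DistensibilityResult:
    """Convenience wrapper: extremes plus distensibility for one location."""
    a_min, a_max = area_extremes(curve)
    return DistensibilityResult(
        location=curve.location,
        a_min=a_min,
        a_max=a_max,
        distensibility=distensibility(a_min, a_max, bp),
    )


def bsa(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """Body surface area in m^2 (Mosteller by default, Du Bois optional)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    if formula == "dubois":
        return float(0.007184 * height_cm**0.725 * weight_kg**0.425)
    raise ValueError(f"unknown BSA formula: {formula!r}")
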