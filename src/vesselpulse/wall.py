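"""Carotid wall morphometry from paired inner/outer contours.

On dark-blood vessel-wall images the wall appears as the annulus between the
lumen (inner) and outer-wall contour.  Wall area is the difference of the two
polygon areas; wall thickness is measured along rays cast from the lumen
centroid at evenly spaced angles — a reproducible analogue of manual caliper
placement, defaulting to two positions per vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .lumen import polygon_area


@dataclass(frozen=True)
class WallContourPair:
    """Inner (lumen) and outer wall boundary of one carotid site."""

    side: str  # "left" | "right"
    level: str  # "proximal" | "distal"
    inner: np.ndarray  # (n, 2) mm
    outer: np.ndarray  # (m, 2) mm

    def __post_init__(self) -> None:
        inner = np.asarray(self.inner, dtype=float)
        outer = np.asarray(self.outer, dtype=float)
        object.__setattr__(self, "inner", inner)
        object.__setattr__(self, "outer", outer)
        ip = shapely.Polygon(inner)
        op = shapely.Polygon(outer)
        if not (ip.is_valid and op.is_valid):
            raise ValueError("wall contours must be simple polygons")
        if not shapely.contains_properly(op, ip):
            raise ValueError("outer contour must strictly enclose the inner contour")


@dataclass(frozen=True)
class WallMetrics:
    wall_area: float  # mm^2
    wall_thickness: float  # mm, mean over sampled positions
    n_positions: int


def wall_area(pair: WallContourPair) -> float:
    """Wall (annulus) area in mm^2: outer polygon area minus lumen area."""
    return polygon_area(pair.outer) - polygon_area(pair.inner)


def wall_thickness(pair: WallContourPair, positions: int = 2) -> float:
    """Mean wall thickness (mm) from centroid rays at evenly spaced angles.

    Each ray starts at the inner polygon's centroid; the thickness at that
    position is the distance between the last crossing of the inner boundary
    and the first subsequent crossing of the outer boundary.  Positions whose
    ray fails to cross both boundaries are skipped; if every position is
    skipped an error is raised.
    """
    if positions < 2:
        raise ValueError("need at least 2 positions")
    inner_poly = shapely.Polygon(pair.inner)
    outer_poly = shapely.Polygon(pair.outer)
    cx, cy = inner_poly.centroid.x, inner_poly.centroid.y
    # ray length safely beyond the outer contour
    minx, miny, maxx, maxy = outer_poly.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1.0

    thicknesses = []
    for k in range(positions):
        ang = 2.0 * np.pi * k / positions
        ray = shapely.LineString(
            [(cx, cy), (cx + reach * np.cos(ang), cy + reach * np.sin(ang))]
        )
        r_in = _crossing_distances(ray, inner_poly.exterior, cx, cy)
        r_out = _crossing_distances(ray, outer_poly.exterior, cx, cy)
        if r_in.size == 0 or r_out.size == 0:
            continue
        exit_inner = float(r_in.max())
        beyond = r_out[r_out > exit_inner]
        if beyond.size == 0:
            continue
        thicknesses.append(float(beyond.min()) - exit_inner)
    if not thicknesses:
        raise ValueError("no ray crossed both wall boundaries")
    return float(np.mean(thicknesses))


def wall_metrics(pair: WallContourPair, positions: int = 2) -> WallMetrics:
    return WallMetrics(
        wall_area=wall_area(pair),
        wall_thickness=wall_thickness(pair, positions),
        n_positions=positions,
    )


def _crossing_distances(ray, boundary, cx: float, cy: float) -> np.ndarray:
    inter = ray.intersection(boundary)
    if inter.is_empty:
        return np.array([])
    pts = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if g.geom_type == "Point":
            pts.append((g.x, g.y))
        else:  # collinear overlap: use segment endpoints
            pts.extend(list(g.coords))
    pts = np.asarray(pts, dtype=float)
    return np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
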