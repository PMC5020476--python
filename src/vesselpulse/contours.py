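"""Contour container shared by the volumetric and vessel-wall modules.

A :class:`ContourSet` holds planar polygons keyed by anatomic structure, slice
index and cardiac phase — the common substrate for cross-sectional areas,
Simpson's-rule chamber volumes and carotid wall morphometry.  Vertices are in
mm in the slice plane; the through-plane geometry is carried by a single slice
thickness (mm) for the whole set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTOUR_COLUMNS = ["structure", "slice_index", "phase", "vertex_index", "x_mm", "y_mm"]

CHAMBER_STRUCTURES = ("LA", "LV-endo", "LV-epi")


@dataclass(frozen=True)
class ContourSet:
    """Per-structure, per-slice, per-phase planar polygons.

    ``data`` has columns ``structure, slice_index, phase, vertex_index, x_mm,
    y_mm`` with one row per vertex; vertices of one polygon are ordered by
    ``vertex_index``.
    """

    data: pd.DataFrame
    slice_thickness: float  # mm

    def __post_init__(self) -> None:
        missing = [c for c in CONTOUR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"contour table missing columns: {missing}")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")

    def structures(self) -> list[str]:
        return sorted(self.data["structure"].unique())

    def phases(self, structure: str) -> np.ndarray:
        sel = self.data.loc[self.data["structure"] == structure, "phase"]
        return np.sort(sel.unique())

    def polygon(self, structure: str, slice_index: int, phase: int) -> np.ndarray:
        """Vertex array (n, 2) of one polygon; raises KeyError if absent."""
        mask = (
            (self.data["structure"] == structure)
            & (self.data["slice_index"] == slice_index)
            & (self.data["phase"] == phase)
        )
        sub = self.data.loc[mask].sort_values("vertex_index")
        if sub.empty:
            raise KeyError(f"no contour for {structure!r} slice {slice_index} phase {phase}")
        return sub[["x_mm", "y_mm"]].to_numpy(dtype=float)

    def polygons_at_phase(self, structure: str, phase: int) -> dict[int, np.ndarray]:
        """All slice polygons of a structure at one phase, keyed by slice index."""
        mask = (self.data["structure"] == structure) & (self.data["phase"] == phase)
        sub = self.data.loc[mask].sort_values(["slice_index", "vertex_index"])
        out: dict[int, np.ndarray] = {}
        for sl, grp in sub.groupby("slice_index", sort=True):
            out[int(sl)] = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        return out


def concat_contour_sets(sets: list[ContourSet]) -> ContourSet:
    """Merge contour sets; rejects inconsistent slice thicknesses."""
    if not sets:
        raise ValueError("no contour sets to merge")
    thicknesses = {s.slice_thickness for s in sets}
    if len(thicknesses) > 1:
        raise ValueError(f"inconsistent slice thickness across the set: {sorted(thicknesses)}")
    data = pd.concat([s.data for s in sets], ignore_index=True)
    return ContourSet(data=data, slice_thickness=sets[0].slice_thickness)


def regular_polygon(cx: float, cy: float, rx: float, ry: float, n: int, phase_offset: float = 0.0) -> np.ndarray:
    """Vertices of an axis-aligned ellipse approximated by a regular n-gon."""
    if n < 3:
        raise ValueError("need at least 3 vertices")
    ang = phase_offset + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([cx + rx * np.cos(ang), cy + ry * np.sin(ang)])


def contours_from_polygons(records, slice_thickness: float) -> ContourSet:
    """Build a ContourSet from ``(structure, slice_index, phase, vertices)`` tuples."""
    frames = []
    for structure, slice_index, phase, verts in records:
        verts = np.asarray(verts, dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "structure": structure,
                    "slice_index": int(slice_index),
                    "phase": int(phase),
                    "vertex_index": np.arange(verts.shape[0]),
                    "x_mm": verts[:, 0],
                    "y_mm": verts[:, 1],
                }
            )
        )
    if not frames:
        raise ValueError("no polygons supplied")
    return ContourSet(data=pd.concat(frames, ignore_index=True), slice_thickness=slice_thickness)
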