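"""Size and shape measures of an articular surface in its anatomic frame.

* maximum medial-lateral width and dorsal-plantar height,
* width profiles: medial and lateral distances from the dorsal-plantar axis
  at heights every ``step`` mm (the saw-blade thickness used in joint
  preparation motivates the 2 mm default),
* quadrant subdivision by the sagittal and transverse planes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely.geometry as sgeom

from .frames import AnatomicFrame
from .mesh_core import SurfacePatch, boundary_loops, surface_centroid

__all__ = ["QUADRANTS", "WidthProfile", "max_extents", "width_profile", "quadrant_split"]

QUADRANTS = ("dorsal-medial", "plantar-medial", "dorsal-lateral", "plantar-lateral")


@dataclass
class WidthProfile:
    """Signed medial/lateral distances of the surface contour at fixed heights.

    Heights are integer multiples of ``step`` (mm), dorsal positive.  The
    medial distance is the ML coordinate of the outermost crossing on the
    medial side; the lateral distance is the (sign-flipped) ML coordinate of
    the outermost lateral crossing.  Either can be negative when the whole
    contour at that height lies on one side of the dorsal-plantar axis.
    """

    step: float
    table: pd.DataFrame  # columns: height, medial_distance, lateral_distance, present

    def row(self, height: float) -> pd.Series:
        return self.table.set_index("height").loc[height]


def max_extents(patch: SurfacePatch, frame: AnatomicFrame) -> tuple[float, float]:
    """(width, height): ML span and DP span of the patch in the frame (mm)."""
    if len(patch) == 0:
        raise ValueError("empty patch")
    local = frame.to_local(patch.parent.vertices[patch.vertex_indices])
    width = float(local[:, 0].max() - local[:, 0].min())
    height = float(local[:, 1].max() - local[:, 1].min())
    return width, height


def _outer_loop_local(patch: SurfacePatch, frame: AnatomicFrame) -> np.ndarray:
    loops = boundary_loops(patch)
    if not loops:
        raise ValueError("patch has no boundary loop")
    local_loops = [frame.to_local(patch.parent.vertices[lp])[:, :2] for lp in loops]
    lengths = [
        np.linalg.norm(ll - np.roll(ll, -1, axis=0), axis=1).sum() for ll in local_loops
    ]
    return local_loops[int(np.argmax(lengths))]


def width_profile(
    patch: SurfacePatch,
    frame: AnatomicFrame,
    step: float = 2.0,
    centroid_tol: float = 1e-6,
) -> WidthProfile:
    """Medial/lateral distances at heights every ``step`` mm.

    The patch's outer boundary loop is projected onto the frontal plane
    through the frame origin (which must be the patch centroid); at each
    height the projected contour is intersected with the line parallel to the
    ML axis and the outermost crossings on each side are reported, signed.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    offset = np.linalg.norm(surface_centroid(patch) - frame.origin)
    if offset > centroid_tol:
        raise ValueError(
            f"frame origin is {offset:.3g} mm from the patch centroid; the "
            "profile is defined about the surface's center of gravity"
        )
    contour = _outer_loop_local(patch, frame)  # columns (ml, dp)
    ring = sgeom.LineString(np.vstack([contour, contour[:1]]))
    m_lo, m_hi = contour[:, 0].min() - 1.0, contour[:, 0].max() + 1.0
    k_lo = int(np.floor(contour[:, 1].min() / step))
    k_hi = int(np.ceil(contour[:, 1].max() / step))
    rows = []
    for k in range(k_lo, k_hi + 1):
        h = k * step
        line = sgeom.LineString([(m_lo, h), (m_hi, h)])
        inter = ring.intersection(line)
        ms = [pt[0] for geom in _iter_geoms(inter) for pt in geom.coords]
        if ms:
            rows.append((h, float(max(ms)), float(-min(ms)), True))
        else:
            rows.append((h, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["height", "medial_distance", "lateral_distance", "present"]
    )
    table["total_distance"] = table["medial_distance"] + table["lateral_distance"]
    return WidthProfile(step=step, table=table)


def _iter_geoms(geom):
    if geom.is_empty:
        return []
    if hasattr(geom, "geoms"):
        return list(geom.geoms)
    return [geom]


def quadrant_split(
    patch: SurfacePatch, frame: AnatomicFrame, strict: bool = True
) -> dict[str, SurfacePatch]:
    """Cut the patch into dorsal/plantar x medial/lateral quadrants.

    Faces are assigned by the sign of their centroid's frame coordinates
    (an exact area partition).  Empty quadrants warn (or are returned empty).
    """
    if len(patch) == 0:
        raise ValueError("empty patch")
    centers = frame.to_local(patch.parent.triangles_center[patch.faces])
    medial = centers[:, 0] >= 0
    dorsal = centers[:, 1] >= 0
    masks = {
        "dorsal-medial": dorsal & medial,
        "plantar-medial": ~dorsal & medial,
        "dorsal-lateral": dorsal & ~medial,
        "plantar-lateral": ~dorsal & ~medial,
    }
    out = {}
    for name, mask in masks.items():
        if strict and not mask.any():
            warnings.warn(f"quadrant {name} is empty")
        out[name] = SurfacePatch(patch.parent, patch.faces[mask], label=patch.label)
    return out
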