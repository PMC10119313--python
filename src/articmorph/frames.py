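"""Automatic anatomic coordinate frames for cuneiforms and metatarsal bases.

Axes and conventions
--------------------
Every frame has its origin at the centroid of the analyzed articular surface
and three orthonormal axes:

* ``axis_pd`` points from the analyzed surface *into* the bone (cuneiform:
  distal-surface centroid toward proximal-surface centroid; metatarsal:
  proximal-surface centroid toward the bone's volume centroid).
* ``axis_dp`` always points dorsally.
* ``axis_ml`` always points medially.

With anatomically-fixed axis senses, left and right frames are mirror images,
so the triple cannot be right-handed on both sides: the determinant of
``[ml, dp, pd]`` is +-1 with a sign fixed by side and bone class.  Medial is
derived from the dorsal axis and the *distalward* direction ``d`` (``-pd``
for cuneiforms, ``+pd`` for metatarsals): ``ml = dp x d`` on the right side
and its negation on the left.

Orientation hints (approximate dorsal / lateral directions, e.g. scanner +z)
are required: the extremum constructions need a dorsal or lateral reference
that scan orientation supplied implicitly in the original protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh_core import SurfacePatch, surface_centroid, volume_centroid

__all__ = [
    "AnatomicFrame",
    "directional_extremum",
    "cuneiform_frame",
    "metatarsal_frame",
]

_MIN_HINT_ANGLE_DEG = 5.0


@dataclass
class AnatomicFrame:
    """Origin (mm) plus orthonormal medial / dorsal / proximal-distal axes."""

    origin: np.ndarray
    axis_ml: np.ndarray
    axis_dp: np.ndarray
    axis_pd: np.ndarray
    side: str
    bone: str | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("axis_ml", "axis_dp", "axis_pd"):
            v = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(v)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError(f"{name} is not unit length")
            setattr(self, name, v / n)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("axes are not orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        """Columns are (ml, dp, pd) in world coordinates."""
        return np.stack([self.axis_ml, self.axis_dp, self.axis_pd], axis=1)

    @property
    def handedness(self) -> float:
        return float(np.sign(np.linalg.det(self.rotation)))

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World points -> (ml, dp, pd) coordinates."""
        return (np.atleast_2d(points) - self.origin) @ self.rotation

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axis_ml": self.axis_ml.tolist(),
            "axis_dp": self.axis_dp.tolist(),
            "axis_pd": self.axis_pd.tolist(),
            "side": self.side,
            "bone": self.bone,
        }


def directional_extremum(points: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """The point furthest along ``direction`` (ties -> lowest index)."""
    points = np.atleast_2d(points)
    if len(points) == 0:
        raise ValueError("empty point set")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return points[int(np.argmax(points @ direction))].copy()


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _reject(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Component of v orthogonal to a unit axis."""
    return v - (v @ axis) * axis


def _check_hint(hint: np.ndarray, pd: np.ndarray, what: str) -> np.ndarray:
    hint = _unit(np.asarray(hint, dtype=float))
    if abs(hint @ pd) > np.cos(np.deg2rad(_MIN_HINT_ANGLE_DEG)):
        raise ValueError(f"ambiguous {what} direction: hint within 5 deg of PD axis")
    return hint


def _medial_axis(dp: np.ndarray, distalward: np.ndarray, side: str) -> np.ndarray:
    ml = np.cross(dp, distalward)
    return _unit(ml if side == "right" else -ml)


def cuneiform_frame(
    prox: SurfacePatch,
    dist: SurfacePatch,
    variant: str,
    dorsal_hint: np.ndarray,
    side: str,
    bone: str | None = None,
) -> AnatomicFrame:
    """Frame of a cuneiform from its two articular surfaces.

    PD runs from the distal-surface centroid (the origin: the distal surface
    is the analyzed one) to the proximal-surface centroid.  One extremum per
    surface is taken along the dorsal hint (medial variant, "most dorsal
    points") or its negation (intermediate variant, "most plantar points");
    DP is the direction from the mid-centroid to the mid-extremum,
    orthogonalized against PD and oriented dorsally.
    """
    if variant not in ("medial", "intermediate"):
        raise ValueError(f"unknown cuneiform variant {variant!r}")
    c_prox = surface_centroid(prox)
    c_dist = surface_centroid(dist)
    pd = _unit(c_prox - c_dist)
    dorsal = _check_hint(dorsal_hint, pd, "dorsal")
    probe = _unit(_reject(dorsal, pd))
    if variant == "intermediate":
        probe = -probe
    pts_p = prox.parent.vertices[prox.vertex_indices]
    pts_d = dist.parent.vertices[dist.vertex_indices]
    ext_p = directional_extremum(pts_p, probe)
    ext_d = directional_extremum(pts_d, probe)
    mid_c = 0.5 * (c_prox + c_dist)
    mid_e = 0.5 * (ext_p + ext_d)
    dp = _unit(_reject(mid_e - mid_c, pd))
    if variant == "intermediate":
        dp = -dp  # plantar extrema: flip so DP points dorsal
    ml = _medial_axis(dp, -pd, side)  # cuneiform PD points proximally
    return AnatomicFrame(
        origin=c_dist, axis_ml=ml, axis_dp=dp, axis_pd=pd, side=side, bone=bone
    )


def metatarsal_frame(
    prox: SurfacePatch,
    bone_mesh: trimesh.Trimesh,
    variant: str,
    dorsal_hint: np.ndarray,
    lateral_hint: np.ndarray | None,
    side: str,
    bone: str | None = None,
) -> AnatomicFrame:
    """Frame of a metatarsal base from its proximal surface and bone body.

    PD runs from the proximal-surface centroid (the origin) toward the volume
    centroid of the closed bone mesh.  MT1: the surface is split into dorsal
    and plantar halves, the most lateral point of each half is found, and ML
    runs from the origin to their midpoint (flipped to point medially).  MT2:
    DP runs from the origin toward the most plantar point, negated.
    """
    if variant not in ("MT1", "MT2"):
        raise ValueError(f"unknown metatarsal variant {variant!r}")
    origin = surface_centroid(prox)
    c_vol = volume_centroid(bone_mesh)
    axis = c_vol - origin
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("degenerate PD axis: surface centroid equals volume centroid")
    pd = _unit(axis)
    dorsal = _check_hint(dorsal_hint, pd, "dorsal")
    pts = prox.parent.vertices[prox.vertex_indices]

    if variant == "MT1":
        if lateral_hint is None:
            raise ValueError("MT1 frame requires a lateral hint")
        lateral = _check_hint(lateral_hint, pd, "lateral")
        lat_dir = _unit(_reject(lateral, pd))
        dors_dir = _unit(_reject(dorsal, pd))
        halves = (pts @ dors_dir - origin @ dors_dir) >= 0
        ml_pts = []
        for mask in (halves, ~halves):
            if not mask.any():
                raise ValueError("empty dorsal or plantar half on MT1 surface")
            ml_pts.append(directional_extremum(pts[mask], lat_dir))
        mid = 0.5 * (ml_pts[0] + ml_pts[1])
        ml = -_unit(_reject(mid - origin, pd))  # extrema are lateral; ML is medial
        dp = _unit(np.cross(pd, ml))
        if dp @ dorsal < 0:
            dp = -dp
    else:
        plantar = -_unit(_reject(dorsal, pd))
        ext = directional_extremum(pts, plantar)
        dp = -_unit(_reject(ext - origin, pd))  # toward plantar extremum, negated
        ml = _medial_axis(dp, pd, side)  # metatarsal PD points distally

    return AnatomicFrame(
        origin=origin, axis_ml=ml, axis_dp=dp, axis_pd=pd, side=side, bone=bone
    )
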