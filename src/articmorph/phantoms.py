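"""Synthetic bone phantoms with analytic ground truth.

A phantom bone is a closed, prism-like solid whose two end caps are spherical
patches of prescribed signed Gaussian curvature and extents, joined to the
shaft by a rounded rim (fillet) of principal curvature ~1/rim_radius.  The
shaft walls carry a smooth egg-crate relief so that, like real periarticular
bone, they are nowhere flat at the extraction scale: the only large
low-curvature regions are the articular caps.  Every quantity the analysis
pipeline later measures -- cap membership, cap curvature, anatomic frame,
extents, boundary contour, joint similarity -- is recorded exactly at build
time.

Footprints are superellipses (tall, narrow, squarish, like tarsometatarsal
facets).  Boundary sampling anchors vertices exactly at the
dorsal/plantar/medial/lateral extremes, so extremum-based frame recovery is
not limited by sampling.  The rim carries one-signed radial ridges (damped
at the compass extremes) and the shaft an egg-crate relief plus a gentle
metaphyseal neck: periarticular texture that keeps everything but the caps
well below any extraction threshold, even after voxelization artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .frames import AnatomicFrame
from .mesh_core import PatchLabel, SurfacePatch, orient_outward, surface_centroid
from .similarity import curvature_similarity

__all__ = [
    "CapSpec",
    "PhantomBone",
    "JointPhantom",
    "make_primitive",
    "make_phantom_bone",
    "make_joint_phantom",
    "voxelize_remesh",
    "add_vertex_noise",
    "random_rotation",
    "apply_pose",
    "cap_jaccard",
    "max_feasible_curvature",
    "generate_cohort",
]

# maximum cap polar extent as a fraction of the cap sphere radius; beyond
# this the cap gets too steep to join cleanly to the shaft
_MAX_RHO_OVER_R = 0.75

# shaft relief: amplitude (mm) and wavelength (mm) chosen so the walls'
# second-principal curvature magnitude (~amp * (2 pi / wavelength)^2 ~ 0.9/mm)
# sits far below any extraction threshold
_WALL_BUMP_AMP = 0.2
_WALL_BUMP_WAVELENGTH = 3.0

# rim corrugation: relative amplitude of the radial ridges crossing the rim
# and their spacing along the facet boundary
_RIM_RIDGE_AMP = 0.3  # mm, at the rim outer edge
_RIM_RIDGE_WAVELENGTH = 2.5

# metaphyseal neck: depth (mm) of the narrowing below each cap junction,
# its center distance below the junction and its axial spread
_NECK_DEPTH = 1.0
_NECK_CENTER = 2.5
_NECK_SIGMA = 1.2

# rim meridian profile: arc length (mm) of the curvature ramp from cap to
# rim curvature, and the ramp's power-law exponent
_RIM_TRANSITION = 1.1
_RIM_RAMP_EXPONENT = 1.0

_ANALYZED_END = {
    "medial_cuneiform": "distal",
    "intermediate_cuneiform": "distal",
    "metatarsal1": "proximal",
    "metatarsal2": "proximal",
}


@dataclass(frozen=True)
class CapSpec:
    """Prescription for one articular end cap."""

    curvature: float  # signed Gaussian curvature K_signed, 1/mm^2 (+convex)
    width: float  # medial-lateral extent, mm
    height: float  # dorsal-plantar extent, mm


@dataclass
class PhantomBone:
    mesh: trimesh.Trimesh
    bone: str
    side: str
    truth_caps: dict  # end -> face index array
    truth_curvature: dict  # end -> signed Gaussian curvature
    truth_frame: AnatomicFrame  # frame of the analyzed articular surface
    truth_extents: dict  # end -> (width, height), exact mesh extents
    truth_contour: dict  # end -> (M, 2) cap boundary in (ml, dp) frame coords
    hints: dict  # 'dorsal', 'lateral', 'distal' unit vectors (world)
    seed_points: dict  # end -> 3-D point on the cap (world)
    pose: tuple  # (R, t) applied so far

    @property
    def analyzed_end(self) -> str:
        return _ANALYZED_END[self.bone]

    def cap_patch(self, end: str) -> SurfacePatch:
        return SurfacePatch(
            self.mesh,
            self.truth_caps[end],
            label=PatchLabel(self.bone, end, self.side),
        )


@dataclass
class JointPhantom:
    cuneiform: PhantomBone
    metatarsal: PhantomBone
    k_cun: float
    k_met: float
    truth_similarity: float
    gap: float
    joint: str
    side: str
    specimen: str = ""


def max_feasible_curvature(width: float, height: float) -> float:
    """Largest |K| a spherical cap of the given extents can carry."""
    rho = _footprint_max_radius(width / 2.0, height / 2.0)
    return (_MAX_RHO_OVER_R / rho) ** 2


# ---------------------------------------------------------------------------
# footprint


def _superellipse_dense(a: float, b: float, p: float, waist: float, n: int = 1200):
    """One dense closed polyline per quadrant, compass points exact."""
    quads = []
    for q in range(4):
        t = np.linspace(q * np.pi / 2, (q + 1) * np.pi / 2, n, endpoint=False)
        x = np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / p) * a
        y = np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / p) * b
        if waist:
            x = x * (1.0 + waist * np.exp(-((np.abs(y) / b - 0.5) ** 2) / (2 * 0.18**2)))
        quads.append(np.stack([x, y], axis=1))
    return quads


def _resample_arc(seg: np.ndarray, n_pts: int) -> np.ndarray:
    """Resample an open polyline to n_pts+1 points, endpoints kept."""
    d = np.linalg.norm(np.diff(seg, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    target = np.linspace(0.0, s[-1], n_pts + 1)
    return np.stack(
        [np.interp(target, s, seg[:, 0]), np.interp(target, s, seg[:, 1])], axis=1
    )


def _footprint(a: float, b: float, resolution: float, p: float = 4.0, waist: float = 0.0):
    """Closed polygon (M, 2), CCW, anchored at the compass/bulge extremes."""
    quads = _superellipse_dense(a, b, p, waist)
    dense = np.concatenate(quads)
    n = len(quads[0])
    anchors = [0, n, 2 * n, 3 * n]  # compass points (exact by construction)
    if waist:
        for q in range(4):
            k = q * n + int(np.argmax(np.abs(dense[q * n : (q + 1) * n, 0])))
            if k not in anchors:
                anchors.append(k)
    anchors = sorted(anchors)
    closed = np.vstack([dense, dense[:1]])
    bounds = anchors + [len(dense)]
    pts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = closed[lo : hi + 1]
        length = np.linalg.norm(np.diff(seg, axis=0), axis=1).sum()
        n_pts = max(2, int(round(length / resolution)))
        rs = _resample_arc(seg, n_pts)
        pts.append(rs[:-1])  # drop endpoint; the next segment starts with it
    return np.concatenate(pts)


def _footprint_max_radius(a: float, b: float, p: float = 4.0, waist: float = 0.0) -> float:
    quads = _superellipse_dense(a, b, p, waist)
    return float(max(np.hypot(q[:, 0], q[:, 1]).max() for q in quads))


def _polygon_normals(poly: np.ndarray) -> np.ndarray:
    """Outward unit normals per vertex of a CCW polygon."""
    e = np.roll(poly, -1, axis=0) - poly
    edge_n = np.stack([e[:, 1], -e[:, 0]], axis=1)
    edge_n /= np.linalg.norm(edge_n, axis=1, keepdims=True)
    v_n = edge_n + np.roll(edge_n, 1, axis=0)
    return v_n / np.linalg.norm(v_n, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# bone assembly


def _cap_height(rho: np.ndarray, R: float | None, sign: float, rho_ref: float):
    """Height of the spherical cap above its junction plane (0 if planar)."""
    if R is None:
        return np.zeros_like(rho)
    f = np.sqrt(R * R - rho * rho)
    return sign * (f - math.sqrt(R * R - rho_ref * rho_ref))


def _stack_rings(rings: list[np.ndarray]):
    """Triangulate apex + rings + apex into a closed mesh (vertices, faces, bands)."""
    M = len(rings[0])
    verts = [rings[0].mean(axis=0, keepdims=True)]  # top apex
    for r in rings:
        verts.append(r)
    verts.append(rings[-1].mean(axis=0, keepdims=True))
    V = np.concatenate(verts)
    faces = []
    bands = []
    # top fan
    start = len(faces)
    for i in range(M):
        faces.append((0, 1 + i, 1 + (i + 1) % M))
    bands.append(("fan_top", start, len(faces)))
    for r in range(len(rings) - 1):
        base_a = 1 + r * M
        base_b = 1 + (r + 1) * M
        start = len(faces)
        for i in range(M):
            j = (i + 1) % M
            faces.append((base_a + i, base_b + i, base_b + j))
            faces.append((base_a + i, base_b + j, base_a + j))
        bands.append((f"band_{r}", start, len(faces)))
    apex = len(V) - 1
    base = 1 + (len(rings) - 1) * M
    start = len(faces)
    for i in range(M):
        faces.append((apex, base + (i + 1) % M, base + i))
    bands.append(("fan_bottom", start, len(faces)))
    return V, np.asarray(faces, dtype=np.int64), bands


def make_phantom_bone(
    body_length: float,
    cap_specs: dict,
    rim_radius: float = 0.6,
    resolution: float = 0.3,
    seed: int | None = None,
    bone: str = "medial_cuneiform",
    side: str = "right",
) -> PhantomBone:
    """Build a phantom bone; the distal end sits at +z, dorsal at +y.

    ``cap_specs`` maps 'proximal'/'distal' to :class:`CapSpec`.  Raises if a
    cap's curvature is too high for its extents or the rim radius is not
    positive.
    """
    if rim_radius <= 0:
        raise ValueError("rim_radius must be positive")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    for end in ("proximal", "distal"):
        if end not in cap_specs:
            raise ValueError(f"missing cap spec for {end} end")
    waist = _WAIST_AMP if bone == "metatarsal1" else 0.0
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 2.0 * np.pi))

    caps = {}
    for end, spec in cap_specs.items():
        if spec.width <= 0 or spec.height <= 0:
            raise ValueError("cap extents must be positive")
        a, b = spec.width / 2.0, spec.height / 2.0
        rho_max = _footprint_max_radius(a, b, waist=waist)
        if spec.curvature == 0.0:
            R = None
        else:
            R = 1.0 / math.sqrt(abs(spec.curvature))
            if rho_max > _MAX_RHO_OVER_R * R:
                raise ValueError(
                    f"infeasible cap: |K|={abs(spec.curvature):.4g} needs sphere "
                    f"radius {R:.1f} mm but the cap half-diagonal is {rho_max:.1f} mm"
                )
        poly = _footprint(a, b, resolution, waist=waist)
        caps[end] = {"spec": spec, "poly": poly, "R": R, "rho_max": rho_max}

    # both ends must share the boundary sampling count: reuse the denser one
    n_pts = {e: len(caps[e]["poly"]) for e in caps}
    master = max(caps, key=lambda e: n_pts[e])
    M = n_pts[master]
    for end in caps:
        if len(caps[end]["poly"]) != M:
            spec = caps[end]["spec"]
            dense = np.concatenate(
                _superellipse_dense(spec.width / 2, spec.height / 2, 4.0, waist)
            )
            caps[end]["poly"] = _resample_arc(np.vstack([dense, dense[:1]]), M)[:-1]

    z_j = {"distal": body_length / 2.0, "proximal": -body_length / 2.0}
    out_sign = {"distal": 1.0, "proximal": -1.0}

    def cap_rings(end):
        info = caps[end]
        poly, R = info["poly"], info["R"]
        sgn = math.copysign(1.0, info["spec"].curvature) if R is not None else 0.0
        n_r = max(3, int(round((info["spec"].width + info["spec"].height) / 4.0 / resolution)))
        rings = []
        for k in range(1, n_r + 1):
            ring_xy = poly * (k / n_r)
            rho = np.hypot(ring_xy[:, 0], ring_xy[:, 1])
            h = _cap_height(rho, R, sgn, info["rho_max"])
            z = z_j[end] + out_sign[end] * h
            rings.append(np.column_stack([ring_xy, z]))
        return rings, n_r

    def fillet_rings(end):
        # clothoid-style fillet, curvature-continuous with the cap: the
        # meridian turning rate ramps linearly from the cap's own curvature
        # to 1/rim_radius while the tangent angle runs from the cap edge
        # slope (alpha, signed: convex caps descend outward, concave dishes
        # rise) to vertical.  A G2 junction keeps the local curvature fit
        # near the cap boundary uncontaminated by the rim.
        info = caps[end]
        poly = info["poly"]
        nrm = _polygon_normals(poly)
        rho = np.hypot(poly[:, 0], poly[:, 1])
        sgn = math.copysign(1.0, info["spec"].curvature) if info["R"] is not None else 0.0
        z_edge = z_j[end] + out_sign[end] * _cap_height(rho, info["R"], sgn, info["rho_max"])
        if info["R"] is None:
            sin_a = np.zeros(len(poly))
            kappa0 = 0.0
        else:
            sin_a = sgn * rho / info["R"]
            kappa0 = sgn / info["R"]
        alpha = np.arcsin(sin_a)  # per boundary vertex
        kappa1 = 1.0 / rim_radius
        # two-phase meridian: curvature ramps from the cap value to the rim
        # value over a short transition (power-law ramp), then stays at the
        # rim value until the tangent is vertical.  G2 at the cap edge (no
        # curvature jump to contaminate boundary fits) but a compact rim.
        L0, gamma = _RIM_TRANSITION, _RIM_RAMP_EXPONENT
        L = L0 + (0.5 * math.pi + float(np.abs(alpha).max())) / kappa1
        n_f = max(4, int(math.ceil(L / resolution)))
        n_fine = 4 * n_f
        l = np.linspace(0.0, L, n_fine + 1)  # (n_fine+1,)
        kappa = kappa0 + (kappa1 - kappa0) * np.minimum(l / L0, 1.0) ** gamma
        dl = L / n_fine
        dpsi = (kappa[1:] + kappa[:-1]) * 0.5 * dl
        psi = alpha[:, None] + np.concatenate([[0.0], np.cumsum(dpsi)])[None, :]
        psi = np.minimum(psi, 0.5 * math.pi)
        off = np.cumsum((np.cos(psi[:, 1:]) + np.cos(psi[:, :-1])) * 0.5 * dl, axis=1)
        drop = np.cumsum((np.sin(psi[:, 1:]) + np.sin(psi[:, :-1])) * 0.5 * dl, axis=1)
        # radial ridge corrugation across the rim (periarticular texture):
        # vertical ripples whose amplitude scales with the outward offset, so
        # they vanish exactly at the cap boundary and never disturb the facet
        # edge or the shaft cross-section, while chopping the rim's threshold
        # contour into short, non-percolating segments
        theta_f = 2.0 * np.pi * np.arange(len(poly)) / len(poly)
        perim = np.linalg.norm(np.diff(np.vstack([poly, poly[:1]]), axis=0), axis=1).sum()
        n_ridge = max(6, int(round(perim / _RIM_RIDGE_WAVELENGTH)))
        # one-signed wave: ridges only deepen the meridian drop, so between
        # ridges the profile is exactly the base ramp and no flat spot can
        # appear from ripple-ramp cancellation.  Ridges are damped near the
        # four compass extremes, where extents and frame extrema are read.
        ridge_wave = 0.5 * (1.0 + np.sin(n_ridge * theta_f + phase))
        seg_len = np.linalg.norm(np.diff(np.vstack([poly, poly[:1]]), axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg_len[:-1])])
        anchors_idx = [
            int(np.argmax(poly[:, 0])), int(np.argmin(poly[:, 0])),
            int(np.argmax(poly[:, 1])), int(np.argmin(poly[:, 1])),
        ]
        damp = np.ones(len(poly))
        for ai in anchors_idx:
            d = np.abs(arc - arc[ai])
            d = np.minimum(d, perim - d)
            damp *= 1.0 - np.exp(-0.5 * (d / 1.2) ** 2)
        ridge_wave = ridge_wave * damp
        off_max = float(off[:, -1].max())
        rings = []
        for j in range(1, n_f + 1):
            k = j * 4 - 1  # fine-grid index of this ring
            xy = poly + off[:, k, None] * nrm
            ripple = _RIM_RIDGE_AMP * (off[:, k] / off_max) ** 2 * ridge_wave
            z = z_edge - out_sign[end] * (drop[:, k] + ripple)
            rings.append(np.column_stack([xy, z]))
        return rings

    d_cap, n_r_d = cap_rings("distal")
    p_cap, n_r_p = cap_rings("proximal")
    d_fil = fillet_rings("distal")
    p_fil = fillet_rings("proximal")

    top = d_fil[-1]  # wall top ring (xyz)
    bot = p_fil[-1]
    n_w = max(4, int(round(body_length / resolution)))
    m_z = max(2, int(round(body_length / _WALL_BUMP_WAVELENGTH)))
    perimeter = np.linalg.norm(
        np.diff(np.vstack([caps["distal"]["poly"], caps["distal"]["poly"][:1]]), axis=0),
        axis=1,
    ).sum()
    n_u = max(3, int(round(perimeter / _WALL_BUMP_WAVELENGTH)))
    theta = 2.0 * np.pi * np.arange(M) / M
    wall = []
    # metaphyseal neck below each articular flare: the extra meridian turn
    # (down-in-down-out) makes the rim barrier survive heavy smoothing of
    # the curvature field, as the narrowing below a real joint surface does
    wall_len = float(top[:, 2].mean() - bot[:, 2].mean())
    for i in range(1, n_w):
        tau = i / n_w
        ring = (1.0 - tau) * top + tau * bot
        nrm = _polygon_normals(ring[:, :2])
        depth = tau * wall_len  # below the distal junction
        neck = _NECK_DEPTH * (
            math.exp(-0.5 * ((depth - _NECK_CENTER) / _NECK_SIGMA) ** 2)
            + math.exp(-0.5 * ((wall_len - depth - _NECK_CENTER) / _NECK_SIGMA) ** 2)
        )
        amp = _WALL_BUMP_AMP * np.sin(n_u * theta + phase) * math.sin(m_z * math.pi * tau)
        ring = ring.copy()
        ring[:, :2] += nrm * (amp - neck)[:, None]
        wall.append(ring)

    # rings run distal apex -> distal cap (inner to outer) -> distal fillet ->
    # wall -> proximal fillet -> proximal cap (outer to inner) -> proximal apex
    rings = d_cap + d_fil + wall + list(reversed(p_fil)) + list(reversed(p_cap))
    V, F, bands = _stack_rings(rings)

    # face regions: fan_top + first (n_r_d - 1) bands are the distal cap;
    # symmetric at the proximal end
    n_bands = len(bands) - 2  # without the fans
    distal_cap_bands = {f"band_{r}" for r in range(n_r_d - 1)}
    prox_cap_bands = {f"band_{r}" for r in range(n_bands - (n_r_p - 1), n_bands)}
    cap_faces = {"distal": [], "proximal": []}
    for name, lo, hi in bands:
        if name == "fan_top" or name in distal_cap_bands:
            cap_faces["distal"].extend(range(lo, hi))
        elif name == "fan_bottom" or name in prox_cap_bands:
            cap_faces["proximal"].extend(range(lo, hi))

    mesh = trimesh.Trimesh(vertices=V, faces=F, process=False)
    if not mesh.is_watertight:
        raise RuntimeError("phantom construction produced a non-watertight mesh")
    orient_outward(mesh)

    truth_caps = {e: np.asarray(idx, dtype=np.int64) for e, idx in cap_faces.items()}
    truth_curvature = {e: caps[e]["spec"].curvature for e in caps}
    truth_extents = {}
    truth_contour = {}
    analyzed = _ANALYZED_END[bone]

    # canonical anatomic axes: distalward is +z, dorsal +y
    dorsal = np.array([0.0, 1.0, 0.0])
    distalward = np.array([0.0, 0.0, 1.0])
    ml = np.cross(dorsal, distalward)
    if side == "left":
        ml = -ml
    pd = -distalward if analyzed == "distal" else distalward
    bone_obj = PhantomBone(
        mesh=mesh,
        bone=bone,
        side=side,
        truth_caps=truth_caps,
        truth_curvature=truth_curvature,
        truth_frame=None,  # set below
        truth_extents=truth_extents,
        truth_contour=truth_contour,
        hints={"dorsal": dorsal, "lateral": -ml, "distal": distalward},
        seed_points={},
        pose=(np.eye(3), np.zeros(3)),
    )
    origin = surface_centroid(bone_obj.cap_patch(analyzed))
    frame = AnatomicFrame(
        origin=origin, axis_ml=ml, axis_dp=dorsal, axis_pd=pd, side=side, bone=bone
    )
    bone_obj.truth_frame = frame
    for end in caps:
        poly = caps[end]["poly"]
        truth_extents[end] = (
            float(poly[:, 0].max() - poly[:, 0].min()),
            float(poly[:, 1].max() - poly[:, 1].min()),
        )
        rho = np.hypot(poly[:, 0], poly[:, 1])
        info = caps[end]
        sgn = math.copysign(1.0, info["spec"].curvature) if info["R"] is not None else 0.0
        z = z_j[end] + out_sign[end] * _cap_height(rho, info["R"], sgn, info["rho_max"])
        ring3 = np.column_stack([poly, z])
        truth_contour[end] = frame.to_local(ring3)[:, :2]
        apex_h = 0.0 if info["R"] is None else sgn * (info["R"] - math.sqrt(info["R"] ** 2 - info["rho_max"] ** 2))
        bone_obj.seed_points[end] = np.array([0.0, 0.0, z_j[end] + out_sign[end] * apex_h])
    return bone_obj


_WAIST_AMP = 0.0


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def apply_pose(bone: PhantomBone, rotation: np.ndarray, translation: np.ndarray) -> PhantomBone:
    """Rigidly move a phantom, updating all recorded truth."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
        raise ValueError("rotation must be proper orthonormal")
    mesh = trimesh.Trimesh(
        vertices=bone.mesh.vertices @ R.T + t, faces=bone.mesh.faces.copy(), process=False
    )
    f = bone.truth_frame
    frame = AnatomicFrame(
        origin=R @ f.origin + t,
        axis_ml=R @ f.axis_ml,
        axis_dp=R @ f.axis_dp,
        axis_pd=R @ f.axis_pd,
        side=f.side,
        bone=f.bone,
    )
    R0, t0 = bone.pose
    return replace(
        bone,
        mesh=mesh,
        truth_frame=frame,
        hints={k: R @ v for k, v in bone.hints.items()},
        seed_points={k: R @ v + t for k, v in bone.seed_points.items()},
        pose=(R @ R0, R @ t0 + t),
    )


# ---------------------------------------------------------------------------
# primitives, perturbations


def _grid_patch(width: float, height: float, resolution: float, zfun) -> trimesh.Trimesh:
    nx = max(2, int(round(width / resolution)))
    ny = max(2, int(round(height / resolution)))
    xs = np.linspace(-width / 2, width / 2, nx + 1)
    ys = np.linspace(-height / 2, height / 2, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), zfun(X.ravel(), Y.ravel())])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            faces.append((a, b, b + 1))
            faces.append((a, b + 1, a + 1))
    return trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)


def make_primitive(kind: str, params: dict, resolution: float) -> trimesh.Trimesh:
    """Analytic test surfaces: sphere, ellipsoid, cylinder, saddle, plane."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if any(v <= 0 for k, v in params.items() if k != "R"):
        raise ValueError("dimensions must be positive")
    if kind == "sphere":
        r = params["radius"]
        sub = max(1, int(math.ceil(math.log2(1.05 * r / resolution))))
        return trimesh.creation.icosphere(subdivisions=sub, radius=r)
    if kind == "ellipsoid":
        rx, ry, rz = params["rx"], params["ry"], params["rz"]
        sub = max(1, int(math.ceil(math.log2(1.05 * max(rx, ry, rz) / resolution))))
        m = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
        m.vertices = m.vertices * np.array([rx, ry, rz])
        return m
    if kind == "cylinder":
        # built from rings so the side wall is sampled along the axis too
        r, h = params["radius"], params["height"]
        sections = max(8, int(round(2 * np.pi * r / resolution)))
        theta = 2 * np.pi * np.arange(sections) / sections
        circle = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        nz = max(2, int(round(h / resolution)))
        rings = [
            np.column_stack([circle, np.full(sections, z)])
            for z in np.linspace(h / 2, -h / 2, nz + 1)
        ]
        V, F, _ = _stack_rings(rings)
        mesh = trimesh.Trimesh(vertices=V, faces=F, process=False)
        return orient_outward(mesh)
    if kind == "plane":
        return _grid_patch(
            params["width"], params["height"], resolution, lambda x, y: np.zeros_like(x)
        )
    if kind == "saddle":
        R = params["R"]
        if R <= 0:
            raise ValueError("saddle R must be positive")
        return _grid_patch(
            params["width"],
            params["height"],
            resolution,
            lambda x, y: (x * x - y * y) / (2.0 * R),
        )
    raise ValueError(f"unknown primitive kind {kind!r}")


def voxelize_remesh(mesh: trimesh.Trimesh, voxel: float) -> trimesh.Trimesh:
    """Voxelize at the given pitch and re-triangulate by isosurfacing.

    Emulates the staircase/averaging artifacts a volumetric imaging and
    segmentation chain imprints on a surface.
    """
    from scipy.ndimage import gaussian_filter
    from skimage import measure

    if voxel <= 0:
        raise ValueError("voxel must be positive")
    vox = mesh.voxelized(pitch=voxel).fill()
    grid = vox.matrix.astype(np.float32)
    if grid.sum() == 0:
        raise ValueError("voxel larger than the object: empty voxelization")
    grid = np.pad(grid, 2)
    # soften the binary occupancy by one voxel before isosurfacing, as an
    # image-to-mesh chain does implicitly; a raw binary marching-cubes
    # surface is blocky and overestimates areas by ~10%.  Occupancy marks
    # every voxel the surface touches, dilating the solid by half a voxel;
    # the matching isosurface level for a unit-sigma smoothed edge is
    # Phi(0.5) ~ 0.69 rather than 0.5.
    grid = gaussian_filter(grid, sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.6915, spacing=(voxel,) * 3)
    origin = vox.translation - 2 * voxel  # padding offset
    out = trimesh.Trimesh(vertices=verts + origin, faces=faces, process=False)
    out.merge_vertices()
    out = orient_outward(out)
    if not out.is_watertight:
        out.fill_holes()
    return out


def add_vertex_noise(mesh: trimesh.Trimesh, amplitude: float, seed: int) -> trimesh.Trimesh:
    """Displace each vertex along its normal by uniform(-amplitude, amplitude)."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    disp = rng.uniform(-amplitude, amplitude, size=len(mesh.vertices))
    V = mesh.vertices + mesh.vertex_normals * disp[:, None]
    return trimesh.Trimesh(vertices=V, faces=mesh.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# evaluation against truth


def cap_jaccard(bone: PhantomBone, end: str, patch: SurfacePatch) -> float:
    """Area-weighted Jaccard index between a patch and the true cap.

    The comparison is made on the faces of the underlying (pre-hole-filling)
    mesh: fill fans appended by hole filling are dropped and the hole faces
    they cover are credited to the patch instead (any connected component of
    the patch's complement other than the largest one is an enclosed hole).
    On a remeshed surface, truth membership is transferred by nearest
    original face centroid.
    """
    from scipy.spatial import cKDTree

    from .mesh_core import connected_components, patch_area

    parent = patch.parent
    n_orig = patch.provenance.get("n_original_faces", len(parent.faces))
    in_patch = np.zeros(n_orig, dtype=bool)
    in_patch[patch.faces[patch.faces < n_orig]] = True
    complement = np.flatnonzero(~in_patch)
    if len(complement):
        comps = connected_components(parent, complement)  # area-sorted
        for hole in comps[1:]:
            in_patch[hole.faces] = True

    same_mesh = n_orig == len(bone.mesh.faces) and np.array_equal(
        parent.faces[:n_orig], bone.mesh.faces
    )
    if same_mesh:
        in_truth = np.zeros(n_orig, dtype=bool)
        in_truth[bone.truth_caps[end]] = True
    else:
        tree = cKDTree(bone.mesh.triangles_center)
        _, nearest = tree.query(parent.triangles_center[:n_orig])
        in_truth = np.isin(nearest, bone.truth_caps[end])
    areas = parent.area_faces[:n_orig]
    inter = areas[in_patch & in_truth].sum()
    union = areas[in_patch | in_truth].sum()
    return float(inter / union) if union > 0 else 0.0


# ---------------------------------------------------------------------------
# joints and cohorts

# cap extents (width, height): mean and SD per bone, mm -- the cohort's
# generating distributions (tall, narrow tarsometatarsal facets)
EXTENT_DISTRIBUTIONS = {
    "medial_cuneiform": ((18.20, 1.98), (29.21, 1.63)),
    "metatarsal1": ((17.59, 1.58), (28.53, 1.57)),
    "intermediate_cuneiform": ((13.26, 1.23), (21.85, 2.03)),
    "metatarsal2": ((12.48, 1.08), (20.59, 2.09)),
}

_JOINT_BONES = {
    "TMT1": ("medial_cuneiform", "metatarsal1"),
    "TMT2": ("intermediate_cuneiform", "metatarsal2"),
}

_BODY_LENGTH = {"cuneiform": 20.0, "metatarsal": 11.0}


def make_joint_phantom(
    k_cun: float,
    k_met: float,
    gap: float = 2.0,
    extents: dict | None = None,
    resolution: float = 0.35,
    joint: str = "TMT1",
    side: str = "right",
    seed: int | None = None,
    rim_radius: float = 0.6,
) -> JointPhantom:
    """Two opposed phantom bones with prescribed cap curvatures.

    The cuneiform's distal cap (curvature ``k_cun``) faces the metatarsal's
    proximal cap (``k_met``) across ``gap`` mm of joint space; the closed-form
    similarity of the prescribed pair is recorded as ground truth.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    cun_name, met_name = _JOINT_BONES[joint]
    if extents is None:
        extents = {
            cun_name: tuple(m for m, _ in EXTENT_DISTRIBUTIONS[cun_name]),
            met_name: tuple(m for m, _ in EXTENT_DISTRIBUTIONS[met_name]),
        }
    cw, ch = extents[cun_name]
    mw, mh = extents[met_name]
    back_k = 0.002  # gentle convex cap on the non-analyzed end
    cun = make_phantom_bone(
        body_length=_BODY_LENGTH["cuneiform"],
        cap_specs={
            "distal": CapSpec(k_cun, cw, ch),
            "proximal": CapSpec(back_k, cw * 0.9, ch * 0.9),
        },
        rim_radius=rim_radius,
        resolution=resolution,
        seed=None if seed is None else seed * 2 + 1,
        bone=cun_name,
        side=side,
    )
    met = make_phantom_bone(
        body_length=_BODY_LENGTH["metatarsal"],
        cap_specs={
            "proximal": CapSpec(k_met, mw, mh),
            "distal": CapSpec(back_k, mw * 0.9, mh * 0.9),
        },
        rim_radius=rim_radius,
        resolution=resolution,
        seed=None if seed is None else seed * 2 + 2,
        bone=met_name,
        side=side,
    )
    dz = cun.mesh.vertices[:, 2].max() - met.mesh.vertices[:, 2].min() + gap
    met = apply_pose(met, np.eye(3), np.array([0.0, 0.0, dz]))
    return JointPhantom(
        cuneiform=cun,
        metatarsal=met,
        k_cun=k_cun,
        k_met=k_met,
        truth_similarity=curvature_similarity(k_cun, k_met),
        gap=gap,
        joint=joint,
        side=side,
    )


def _jitter_direction(v: np.ndarray, rng: np.random.Generator, degrees: float) -> np.ndarray:
    """Rotate a unit vector by a random small angle (hints are approximate)."""
    angle = np.deg2rad(rng.uniform(0.0, degrees))
    axis = rng.normal(size=3)
    axis -= (axis @ v) * v
    axis /= np.linalg.norm(axis)
    return v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)


def generate_cohort(
    n_joints: int = 12,
    seed: int = 0,
    resolution: float = 0.35,
    gap: float = 2.0,
    hint_jitter_deg: float = 0.0,
) -> list[JointPhantom]:
    """A seeded cohort of posed joint phantoms (half TMT1-like, half TMT2-like).

    Extents are drawn from the per-bone generating distributions; curvature
    magnitudes are drawn uniformly inside the spherical-cap feasibility band
    for the drawn extents, with random convex/concave sense.  Each joint is
    posed by a random rigid motion; stored orientation hints are the posed
    scanner axes (optionally jittered to model imperfect scan alignment).
    """
    rng = np.random.default_rng(seed)
    joints = []
    for i in range(n_joints):
        joint = "TMT1" if i % 2 == 0 else "TMT2"
        side = "right" if (i // 2) % 2 == 0 else "left"
        cun_name, met_name = _JOINT_BONES[joint]
        extents = {}
        for name in (cun_name, met_name):
            (wm, ws), (hm, hs) = EXTENT_DISTRIBUTIONS[name]
            w = float(np.clip(rng.normal(wm, ws), wm - 2 * ws, wm + 2 * ws))
            h = float(np.clip(rng.normal(hm, hs), hm - 2 * hs, hm + 2 * hs))
            extents[name] = (w, h)
        ks = []
        for name in (cun_name, met_name):
            k_max = max_feasible_curvature(*extents[name])
            mag = rng.uniform(8e-4, 0.9 * k_max)
            ks.append(float(mag * rng.choice([-1.0, 1.0])))
        jp = make_joint_phantom(
            ks[0],
            ks[1],
            gap=gap,
            extents=extents,
            resolution=resolution,
            joint=joint,
            side=side,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        R = random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, size=3)
        cun = apply_pose(jp.cuneiform, R, t)
        met = apply_pose(jp.metatarsal, R, t)
        for b in (cun, met):
            b.hints = {
                k: _jitter_direction(v, rng, hint_jitter_deg) for k, v in b.hints.items()
            }
        jp = replace(
            jp, cuneiform=cun, metatarsal=met, specimen=f"S{i // 2 + 1:02d}"
        )
        joints.append(jp)
    return joints
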