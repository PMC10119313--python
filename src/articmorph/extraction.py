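"""Articular-surface extraction by second-principal-curvature thresholding.

An articular facet is an area of low curvature inside a bounding area of high
curvature.  Vertices whose second-principal curvature ``k2`` lies at or above
the (negative) threshold are "flat"; faces whose three vertices are all flat
form the candidate set; the selected connected component, with its interior
holes filled, is the articular surface.
"""

from __future__ import annotations

import logging

import numpy as np
import trimesh

from .curvature import CurvatureField
from .mesh_core import PatchLabel, SurfacePatch, connected_components, fill_interior_holes

__all__ = ["extract_articular_surface", "DEFAULT_THRESHOLDS"]

log = logging.getLogger(__name__)

# 1/mm; bound to bone labels following the validated per-bone values
DEFAULT_THRESHOLDS = {
    "medial_cuneiform": -0.25,
    "metatarsal1": -0.25,
    "intermediate_cuneiform": -0.35,
    "metatarsal2": -0.35,
}


def extract_articular_surface(
    mesh: trimesh.Trimesh,
    field: CurvatureField,
    threshold: float,
    seed_point: np.ndarray | None = None,
    label: PatchLabel | None = None,
) -> SurfacePatch:
    """Select the flat region bounded by high curvature.

    Faces with all three vertices at ``k2 >= threshold`` are candidates.  The
    connected component nearest ``seed_point`` (by face centroid) is chosen,
    or the largest-area one when no seed is given; interior holes are then
    filled.  Raises if the threshold excludes everything or excludes nothing
    (the facet must be a proper subset of the bone surface).
    """
    if threshold >= 0:
        raise ValueError("threshold must be negative (convex-negative convention)")
    if len(field.k2) != len(mesh.vertices):
        raise ValueError("field does not cover the mesh")
    flat_v = field.k2 >= threshold
    flat_f = flat_v[mesh.faces].all(axis=1)
    cand = np.flatnonzero(flat_f)
    if len(cand) == 0:
        raise ValueError("threshold excludes entire surface")
    if len(cand) == len(mesh.faces):
        raise ValueError("no bounding high-curvature region")

    comps = connected_components(mesh, cand, label=label)
    if seed_point is not None:
        # the facet containing (or nearest) the seed; noise can shed tiny
        # candidate slivers right at the seed, so among components within one
        # fitting radius of the closest one, prefer the largest area
        seed_point = np.asarray(seed_point, dtype=float)
        dists = np.array(
            [
                np.linalg.norm(mesh.triangles_center[p.faces] - seed_point, axis=1).min()
                for p in comps
            ]
        )
        near = np.flatnonzero(dists <= dists.min() + field.fitting_radius)
        rank = int(near[0])  # components are area-sorted; first near = largest
    else:
        rank = 0  # components are sorted by descending area
    patch = comps[rank]
    patch = fill_interior_holes(patch)
    patch.provenance.update(
        threshold=threshold,
        component_rank=rank,
        n_candidates=len(comps),
        seeded=seed_point is not None,
    )
    log.info(
        "extracted articular surface: threshold=%.3f rank=%d of %d components, "
        "%d faces",
        threshold,
        rank,
        len(comps),
        len(patch),
    )
    return patch
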