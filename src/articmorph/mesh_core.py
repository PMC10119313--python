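"""Mesh substrate: I/O, validity, centroids, areas, components, hole filling.

All geometry is in millimetres.  Meshes are represented as
:class:`trimesh.Trimesh`; closed meshes are kept outward-oriented (positive
signed volume) because the curvature sign convention depends on it.  Subsets
of a mesh's faces are represented as :class:`SurfacePatch`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "PatchLabel",
    "SurfacePatch",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "orient_outward",
    "surface_centroid",
    "volume_centroid",
    "patch_area",
    "vertex_patch_areas",
    "boundary_loops",
    "fill_interior_holes",
    "connected_components",
]

BONES = ("medial_cuneiform", "intermediate_cuneiform", "metatarsal1", "metatarsal2")
ENDS = ("proximal", "distal")
SIDES = ("left", "right")


@dataclass(frozen=True)
class PatchLabel:
    """Anatomical identity of a surface patch."""

    bone: str
    end: str
    side: str

    def __post_init__(self) -> None:
        if self.bone not in BONES:
            raise ValueError(f"unknown bone {self.bone!r}")
        if self.end not in ENDS:
            raise ValueError(f"unknown end {self.end!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class SurfacePatch:
    """A subset of a mesh's faces (e.g. one articular surface).

    ``faces`` indexes into ``parent.faces``.  The patch is only a view; use
    :meth:`submesh` to obtain a standalone mesh for patch-local computations.
    """

    parent: trimesh.Trimesh
    faces: np.ndarray
    label: PatchLabel | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 1:
            raise ValueError("faces must be a 1-D index array")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.parent.faces)
        ):
            raise ValueError("face indices out of range for parent mesh")

    def __len__(self) -> int:
        return len(self.faces)

    @property
    def vertex_indices(self) -> np.ndarray:
        """Sorted unique parent-vertex indices used by the patch."""
        return np.unique(self.parent.faces[self.faces])

    def submesh(self) -> tuple[trimesh.Trimesh, np.ndarray, np.ndarray]:
        """Extract the patch as its own mesh.

        Returns ``(mesh, vertex_map, face_map)`` where ``vertex_map[i]`` is the
        parent index of submesh vertex ``i`` and ``face_map[j]`` the parent
        index of submesh face ``j`` (the patch's own ordering).
        """
        vidx = self.vertex_indices
        remap = np.full(len(self.parent.vertices), -1, dtype=np.int64)
        remap[vidx] = np.arange(len(vidx))
        faces = remap[self.parent.faces[self.faces]]
        mesh = trimesh.Trimesh(
            vertices=self.parent.vertices[vidx].copy(), faces=faces, process=False
        )
        return mesh, vidx, self.faces.copy()


def validate_mesh(mesh: trimesh.Trimesh, name: str = "mesh") -> None:
    """Raise ``ValueError`` on out-of-range indices or zero-area triangles."""
    if len(mesh.faces) == 0:
        raise ValueError(f"{name}: empty mesh")
    if mesh.faces.min() < 0 or mesh.faces.max() >= len(mesh.vertices):
        raise ValueError(f"{name}: face indices out of range")
    bad = np.flatnonzero(mesh.area_faces <= 0.0)
    if len(bad):
        raise ValueError(
            f"{name}: degenerate (zero-area) triangles at faces {bad[:20].tolist()}"
            + ("..." if len(bad) > 20 else "")
        )


def orient_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Flip triangle winding in place if a closed mesh encloses negative volume."""
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def read_mesh(path: str | Path, fmt: str | None = None) -> trimesh.Trimesh:
    """Read an STL/PLY/OBJ surface mesh (units taken as mm verbatim).

    The mesh is validated and, if watertight, re-oriented outward.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    kwargs = {"file_type": fmt} if fmt else {}
    loaded = trimesh.load_mesh(str(path), process=False, **kwargs)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise IOError(f"no geometry in {path}")
        loaded = trimesh.util.concatenate(geoms)
    mesh = trimesh.Trimesh(
        vertices=np.asarray(loaded.vertices, dtype=float),
        faces=np.asarray(loaded.faces, dtype=np.int64),
        process=False,
    )
    # STL stores triangle soup: merge coincident vertices to restore topology.
    if path.suffix.lower() == ".stl" or fmt == "stl":
        mesh.merge_vertices()
    validate_mesh(mesh, name=str(path))
    return orient_outward(mesh)


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))


def patch_area(patch: SurfacePatch) -> float:
    """Total triangle area of the patch (mm^2)."""
    if len(patch) == 0:
        raise ValueError("empty patch")
    return float(patch.parent.area_faces[patch.faces].sum())


def surface_centroid(patch: SurfacePatch) -> np.ndarray:
    """Area-weighted centroid ("center of gravity") of a surface patch."""
    if len(patch) == 0:
        raise ValueError("empty patch")
    tris = patch.parent.triangles[patch.faces]
    centers = tris.mean(axis=1)
    areas = patch.parent.area_faces[patch.faces]
    return np.asarray((centers * areas[:, None]).sum(axis=0) / areas.sum())


def volume_centroid(mesh: trimesh.Trimesh) -> np.ndarray:
    """Centroid of the enclosed solid (divergence theorem).

    Requires a closed, outward-oriented mesh ("center of gravity of the bone
    object").
    """
    if not mesh.is_watertight:
        raise ValueError("not watertight: volume centroid undefined for open meshes")
    orient_outward(mesh)
    return np.asarray(mesh.center_mass, dtype=float)


def vertex_patch_areas(patch: SurfacePatch) -> np.ndarray:
    """Per-parent-vertex barycentric area restricted to the patch.

    Each triangle contributes one third of its area to each of its vertices;
    only patch faces contribute.  Returns an array over *all* parent vertices
    (zero outside the patch), so that quadrant sub-patches partition the
    whole-patch weights exactly.
    """
    areas = np.zeros(len(patch.parent.vertices))
    f = patch.parent.faces[patch.faces]
    np.add.at(areas, f.ravel(), np.repeat(patch.parent.area_faces[patch.faces] / 3.0, 3))
    return areas


def _directed_boundary_edges(patch: SurfacePatch) -> list[tuple[int, int]]:
    f = patch.parent.faces[patch.faces]
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    border = counts[inv] == 1
    return [tuple(e) for e in edges[border]]


def boundary_loops(patch: SurfacePatch) -> list[list[int]]:
    """Closed vertex loops bounding the patch, following face winding.

    Returns a list of vertex-index cycles (parent indexing).  A closed patch
    has no loops.
    """
    edges = _directed_boundary_edges(patch)
    succ: dict[int, list[int]] = {}
    for a, b in edges:
        succ.setdefault(a, []).append(b)
    loops = []
    visited: set[tuple[int, int]] = set()
    for a0, b0 in edges:
        if (a0, b0) in visited:
            continue
        loop = [a0]
        a, b = a0, b0
        while True:
            visited.add((a, b))
            loop.append(b)
            nxts = succ.get(b, [])
            nxt = None
            for cand in nxts:
                if (b, cand) not in visited:
                    nxt = cand
                    break
            if nxt is None:
                break
            a, b = b, nxt
        if loop[0] == loop[-1]:
            loop.pop()
        loops.append(loop)
    return loops


def _loop_length(vertices: np.ndarray, loop: list[int]) -> float:
    pts = vertices[loop]
    return float(np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).sum())


def fill_interior_holes(patch: SurfacePatch) -> SurfacePatch:
    """Fill all boundary loops except the outer one by centroid fans.

    The outer loop is the boundary of greatest total edge length (articular
    patches are disk-like, so the rim is the longest loop).  Each interior
    hole is triangulated by a fan from a new vertex at the loop centroid.
    Input faces and vertex coordinates are never modified; the returned patch
    references a new parent mesh with the fan geometry appended.
    """
    loops = boundary_loops(patch)
    if not loops:
        warnings.warn("patch is closed (no boundary); returned unchanged")
        return patch
    if len(loops) == 1:
        return patch
    lengths = [_loop_length(patch.parent.vertices, lp) for lp in loops]
    outer = int(np.argmax(lengths))

    verts = [np.asarray(patch.parent.vertices, dtype=float)]
    new_faces = []
    next_v = len(patch.parent.vertices)
    for i, lp in enumerate(loops):
        if i == outer:
            continue
        center = patch.parent.vertices[lp].mean(axis=0)
        verts.append(center[None, :])
        # boundary edges run a->b with the patch on their left; the fan fills
        # the opposite side, so wind b->a to keep orientation consistent
        for a, b in zip(lp, lp[1:] + lp[:1]):
            new_faces.append((b, a, next_v))
        next_v += 1

    all_verts = np.concatenate(verts)
    all_faces = np.concatenate([patch.parent.faces, np.asarray(new_faces, dtype=np.int64)])
    new_parent = trimesh.Trimesh(vertices=all_verts, faces=all_faces, process=False)
    added = np.arange(len(patch.parent.faces), len(all_faces), dtype=np.int64)
    return replace(
        patch,
        parent=new_parent,
        faces=np.concatenate([patch.faces, added]),
        provenance={
            **patch.provenance,
            "holes_filled": len(loops) - 1,
            "n_original_faces": len(patch.parent.faces),
        },
    )


def connected_components(
    mesh: trimesh.Trimesh, faces: np.ndarray, label: PatchLabel | None = None
) -> list[SurfacePatch]:
    """Partition a face subset into maximal edge-connected components.

    Components are returned as patches sorted by descending area.
    """
    faces = np.asarray(faces, dtype=np.int64)
    if len(faces) == 0:
        return []
    sub = mesh.faces[faces]
    edges = np.sort(
        np.concatenate([sub[:, [0, 1]], sub[:, [1, 2]], sub[:, [2, 0]]]), axis=1
    )
    face_of_edge = np.tile(np.arange(len(faces)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_s, face_s = edges[order], face_of_edge[order]
    same = np.all(edges_s[1:] == edges_s[:-1], axis=1)
    pairs = np.stack([face_s[:-1][same], face_s[1:][same]], axis=1)

    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components as cc

    n = len(faces)
    if len(pairs):
        adj = sp.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = sp.coo_matrix((n, n))
    ncomp, lab = cc(adj, directed=False)
    patches = []
    for c in range(ncomp):
        patches.append(SurfacePatch(mesh, faces[lab == c], label=label))
    patches.sort(key=patch_area, reverse=True)
    return patches
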