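"""Mesh substrate: I/O round-trips, centroids, areas, holes, components."""

import numpy as np
import pytest
import trimesh

from articmorph.mesh_core import (
    SurfacePatch,
    boundary_loops,
    connected_components,
    fill_interior_holes,
    patch_area,
    read_mesh,
    surface_centroid,
    validate_mesh,
    volume_centroid,
    write_mesh,
)


@pytest.mark.parametrize("ext", ["stl", "ply", "obj"])
def test_read_write_round_trip(tmp_path, unit_square_patch, ext):
    """Vertices (to 1e-6 mm) and connectivity survive a write/read cycle."""
    mesh = unit_square_patch.parent
    path = tmp_path / f"square.{ext}"
    write_mesh(mesh, path)
    back = read_mesh(path)
    assert len(back.vertices) == len(mesh.vertices)
    assert len(back.faces) == len(mesh.faces)
    # vertex order may differ (STL is a triangle soup): compare as sets
    d = np.sort(np.linalg.norm(back.vertices[:, None] - mesh.vertices, axis=2).min(1))
    assert d.max() < 1e-6


def test_inward_cube_is_flipped_outward(tmp_path):
    box = trimesh.creation.box(extents=(1, 1, 1))
    box.invert()
    assert box.volume < 0
    path = tmp_path / "in.ply"
    box.export(path)
    back = read_mesh(path)
    assert back.is_watertight and back.volume > 0


def test_zero_area_triangle_is_reported(tmp_path):
    mesh = trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]],
        faces=[[0, 1, 3], [0, 1, 2]],  # second face is collinear
        process=False,
    )
    with pytest.raises(ValueError, match="faces \\[1\\]"):
        validate_mesh(mesh)


def test_missing_file_raises():
    with pytest.raises(IOError):
        read_mesh("no/such/file.stl")


def test_surface_centroid(unit_square_patch):
    assert np.allclose(surface_centroid(unit_square_patch), [0.5, 0.5, 0.0])
    single = SurfacePatch(unit_square_patch.parent, np.array([0]))
    tri = unit_square_patch.parent.vertices[[0, 1, 2]]
    assert np.allclose(surface_centroid(single), tri.mean(axis=0))


def test_surface_centroid_hemisphere_on_axis():
    """An axisymmetric cap's area centroid lies on the symmetry axis."""
    sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    upper = np.flatnonzero(sph.triangles_center[:, 2] > 0.2)
    c = surface_centroid(SurfacePatch(sph, upper))
    assert np.hypot(c[0], c[1]) < 5e-3  # lateral offset bounded by mesh symmetry


def test_empty_patch_errors(unit_square_patch):
    empty = SurfacePatch(unit_square_patch.parent, np.array([], dtype=int))
    with pytest.raises(ValueError):
        surface_centroid(empty)
    with pytest.raises(ValueError):
        patch_area(empty)


def test_volume_centroid_cube_and_sphere():
    box = trimesh.creation.box(extents=(1, 1, 1))
    box.apply_translation([0.5, 0.5, 0.5])
    assert np.allclose(volume_centroid(box), [0.5, 0.5, 0.5], atol=1e-9)
    sph = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
    sph.apply_translation([3.0, -2.0, 7.0])
    assert np.allclose(volume_centroid(sph), [3.0, -2.0, 7.0], atol=1e-6)


def test_volume_centroid_translation_equivariance(small_bone):
    c0 = volume_centroid(small_bone.mesh)
    moved = small_bone.mesh.copy()
    t = np.array([1.5, -2.0, 0.25])
    moved.apply_translation(t)
    assert np.allclose(volume_centroid(moved), c0 + t, atol=1e-9)


def test_volume_centroid_open_mesh_errors(unit_square_patch):
    with pytest.raises(ValueError, match="watertight"):
        volume_centroid(unit_square_patch.parent)


def test_patch_area_unit_square_and_sphere(unit_square_patch):
    assert patch_area(unit_square_patch) == pytest.approx(1.0)
    sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    whole = SurfacePatch(sph, np.arange(len(sph.faces)))
    assert patch_area(whole) == pytest.approx(4 * np.pi, rel=0.005)


def test_patch_area_rigid_invariance(unit_square_patch):
    mesh = unit_square_patch.parent.copy()
    rot = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3], [0.3, 0.1, -0.2])
    mesh.apply_transform(rot)
    moved = SurfacePatch(mesh, unit_square_patch.faces)
    assert patch_area(moved) == pytest.approx(patch_area(unit_square_patch), abs=1e-12)


def _annulus_patch():
    """A square sheet with a square hole (one interior boundary loop)."""
    n = 8
    xs = np.arange(n + 1, dtype=float)
    V = np.array([[x, y, 0.0] for y in xs for x in xs])
    faces = []
    hole = {(3, 3), (3, 4), (4, 3), (4, 4)}
    for j in range(n):
        for i in range(n):
            if (i, j) in hole:
                continue
            a = j * (n + 1) + i
            b = a + 1
            c = a + n + 1
            faces.append([a, b, c + 1])
            faces.append([a, c + 1, c])
    mesh = trimesh.Trimesh(vertices=V, faces=np.array(faces), process=False)
    return SurfacePatch(mesh, np.arange(len(mesh.faces)))


def test_fill_interior_holes_annulus_to_disk():
    patch = _annulus_patch()
    assert len(boundary_loops(patch)) == 2
    filled = fill_interior_holes(patch)
    assert len(boundary_loops(filled)) == 1
    # never removes input faces or moves input vertices
    assert set(patch.faces).issubset(set(filled.faces))
    n = len(patch.parent.vertices)
    assert np.array_equal(filled.parent.vertices[:n], patch.parent.vertices)


def test_fill_interior_holes_no_hole_identity(unit_square_patch):
    out = fill_interior_holes(unit_square_patch)
    assert np.array_equal(out.faces, unit_square_patch.faces)


def test_fill_interior_holes_closed_patch_warns():
    sph = trimesh.creation.icosphere(subdivisions=2)
    patch = SurfacePatch(sph, np.arange(len(sph.faces)))
    with pytest.warns(UserWarning, match="closed"):
        out = fill_interior_holes(patch)
    assert len(out.faces) == len(patch.faces)


def test_fill_two_known_holes():
    """Two interior holes with known loop lengths are both triangulated."""
    n = 10
    xs = np.arange(n + 1, dtype=float)
    V = np.array([[x, y, 0.0] for y in xs for x in xs])
    faces = []
    holes = {(2, 2), (6, 6), (7, 6), (6, 7), (7, 7)}
    for j in range(n):
        for i in range(n):
            if (i, j) in holes:
                continue
            a = j * (n + 1) + i
            faces.append([a, a + 1, a + n + 2])
            faces.append([a, a + n + 2, a + n + 1])
    mesh = trimesh.Trimesh(vertices=V, faces=np.array(faces), process=False)
    patch = SurfacePatch(mesh, np.arange(len(mesh.faces)))
    loops = boundary_loops(patch)
    assert len(loops) == 3
    loop_sizes = sorted(len(lp) for lp in loops)
    assert loop_sizes[0] == 4 and loop_sizes[1] == 8  # 1-cell and 4-cell holes
    filled = fill_interior_holes(patch)
    assert len(boundary_loops(filled)) == 1
    assert filled.provenance["holes_filled"] == 2


def test_connected_components_counts(unit_square_patch):
    two = trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 0], [6, 5, 0], [5, 6, 0]],
        faces=[[0, 1, 2], [3, 4, 5]],
        process=False,
    )
    assert len(connected_components(two, np.array([0, 1]))) == 2
    assert len(connected_components(unit_square_patch.parent, np.array([0, 1]))) == 1
    assert connected_components(two, np.array([], dtype=int)) == []


def test_components_partition_area(small_bone):
    """Component areas sum exactly to the input face subset's area."""
    mesh = small_bone.mesh
    rng = np.random.default_rng(3)
    faces = rng.choice(len(mesh.faces), size=len(mesh.faces) // 3, replace=False)
    comps = connected_components(mesh, faces)
    total = sum(patch_area(c) for c in comps)
    assert total == pytest.approx(mesh.area_faces[faces].sum(), abs=1e-9)
    areas = [patch_area(c) for c in comps]
    assert areas == sorted(areas, reverse=True)
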