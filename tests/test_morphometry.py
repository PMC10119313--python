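"""Extents, width profiles and quadrant subdivision in the anatomic frame."""

import numpy as np
import pytest
import trimesh

from articmorph.curvature import CurvatureField, region_mean_curvature
from articmorph.frames import AnatomicFrame
from articmorph.mesh_core import SurfacePatch, patch_area
from articmorph.morphometry import max_extents, quadrant_split, width_profile


def _grid_rect_patch(width, height, nx=10, ny=16, center=(0.0, 0.0)):
    xs = np.linspace(-width / 2, width / 2, nx + 1) + center[0]
    ys = np.linspace(-height / 2, height / 2, ny + 1) + center[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    return SurfacePatch(mesh, np.arange(len(mesh.faces)))


def _xy_frame(origin=(0.0, 0.0, 0.0), side="right"):
    return AnatomicFrame(
        origin=np.asarray(origin, dtype=float),
        axis_ml=np.array([1.0, 0, 0]),
        axis_dp=np.array([0, 1.0, 0]),
        axis_pd=np.array([0, 0, 1.0]),
        side=side,
    )


def test_max_extents_rectangle():
    patch = _grid_rect_patch(10.0, 20.0)
    w, h = max_extents(patch, _xy_frame())
    assert (w, h) == pytest.approx((10.0, 20.0), abs=1e-12)


def test_max_extents_rigid_invariance(small_bone):
    patch = small_bone.cap_patch("distal")
    frame = small_bone.truth_frame
    w0, h0 = max_extents(patch, frame)
    # rotate both patch and frame by the same motion
    from articmorph.phantoms import apply_pose, random_rotation

    rng = np.random.default_rng(8)
    moved = apply_pose(small_bone, random_rotation(rng), rng.uniform(-5, 5, 3))
    w1, h1 = max_extents(moved.cap_patch("distal"), moved.truth_frame)
    assert (w1, h1) == pytest.approx((w0, h0), abs=1e-9)


def test_phantom_extents_match_truth(small_bone):
    """Truth-cap extents in the truth frame equal the generator inputs."""
    patch = small_bone.cap_patch("distal")
    w, h = max_extents(patch, small_bone.truth_frame)
    tw, th = small_bone.truth_extents["distal"]
    edge = small_bone.mesh.edges_unique_length.mean()
    assert abs(w - tw) <= edge and abs(h - th) <= edge


def test_width_profile_centered_rectangle():
    """10 x 8 rectangle: medial 5, lateral 5, total 10 at h in {-2, 0, 2}."""
    patch = _grid_rect_patch(10.0, 8.0)
    prof = width_profile(patch, _xy_frame(), step=2.0)
    for h in (-2.0, 0.0, 2.0):
        row = prof.row(h)
        assert row["medial_distance"] == pytest.approx(5.0, abs=1e-9)
        assert row["lateral_distance"] == pytest.approx(5.0, abs=1e-9)
        assert row["total_distance"] == pytest.approx(10.0, abs=1e-9)


def test_width_profile_trapezoid_interpolates_edges():
    """A symmetric trapezoid's profile equals the analytic edge section."""
    # vertices: bottom width 12, top width 4, height 8, centroid at origin
    V = np.array(
        [[-6, -4, 0], [6, -4, 0], [2, 4, 0], [-2, 4, 0], [0, 0, 0]], dtype=float
    )
    faces = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    mesh = trimesh.Trimesh(vertices=V, faces=faces, process=False)
    patch = SurfacePatch(mesh, np.arange(4))
    from articmorph.mesh_core import surface_centroid

    cy = surface_centroid(patch)[1]
    frame = _xy_frame(origin=surface_centroid(patch))
    prof = width_profile(patch, frame, step=2.0)
    # analytic half-width of the side edges: w(y) = 6 - y/2 for y in [-4, 4]
    for _, row in prof.table[prof.table["present"]].iterrows():
        y_world = row["height"] + cy
        half = 4.0 - y_world / 2.0  # linear from 6 at y=-4 to 2 at y=4
        assert row["medial_distance"] == pytest.approx(half, abs=1e-9)
        assert row["lateral_distance"] == pytest.approx(half, abs=1e-9)


def test_width_profile_absent_beyond_extent():
    patch = _grid_rect_patch(10.0, 8.0)
    prof = width_profile(patch, _xy_frame(), step=2.0)
    heights = prof.table["height"].to_numpy()
    assert heights.min() <= -4.0 and heights.max() >= 4.0
    present = prof.table[prof.table["present"]]["height"]
    assert present.abs().max() <= 4.0


def test_width_profile_negative_medial_distance():
    """A contour lying entirely lateral at some height gives medial < 0."""
    # L-shaped patch: full rectangle minus the medial half below y = -2
    patch_full = _grid_rect_patch(8.0, 12.0, nx=8, ny=12)
    mesh = patch_full.parent
    keep = []
    for f in range(len(mesh.faces)):
        c = mesh.triangles_center[f]
        if not (c[1] < -2.0 and c[0] > -1.0):
            keep.append(f)
    patch = SurfacePatch(mesh, np.asarray(keep))
    from articmorph.mesh_core import surface_centroid

    frame = _xy_frame(origin=surface_centroid(patch))
    prof = width_profile(patch, frame, step=2.0)
    tab = prof.table[prof.table["present"]]
    low = tab[tab["height"] == tab["height"].min()]
    assert float(low["medial_distance"].iloc[0]) < 0  # outermost crossing is lateral
    assert float(low["total_distance"].iloc[0]) > 0


def test_width_profile_requires_centroid_origin():
    patch = _grid_rect_patch(10.0, 8.0)
    with pytest.raises(ValueError, match="centroid"):
        width_profile(patch, _xy_frame(origin=(3.0, 0.0, 0.0)))


def test_quadrant_split_partition_and_symmetry():
    patch = _grid_rect_patch(10.0, 8.0)
    quads = quadrant_split(patch, _xy_frame())
    total = sum(patch_area(q) for q in quads.values())
    assert total == pytest.approx(patch_area(patch), abs=1e-12)
    areas = [patch_area(q) for q in quads.values()]
    face_area = patch.parent.area_faces.max()
    assert max(areas) - min(areas) <= face_area + 1e-12
    assert set(quads) == {
        "dorsal-medial", "plantar-medial", "dorsal-lateral", "plantar-lateral"
    }


def test_quadrant_split_degenerate_warns():
    patch = _grid_rect_patch(4.0, 4.0, center=(10.0, 10.0))
    with pytest.warns(UserWarning, match="empty"):
        quads = quadrant_split(patch, _xy_frame())
    assert len(quads["dorsal-medial"]) == len(patch)


def test_quadrant_means_recombine_to_whole():
    """Area-weighted quadrant curvature means equal the whole-patch mean."""
    patch = _grid_rect_patch(10.0, 8.0)
    n = len(patch.parent.vertices)
    rng = np.random.default_rng(4)
    ks = rng.normal(0.0, 0.01, n)
    fld = CurvatureField(k1=np.zeros(n), k2=np.zeros(n), K=np.zeros(n),
                         K_signed=ks, fitting_radius=1.0)
    quads = quadrant_split(patch, _xy_frame())
    num = 0.0
    den = 0.0
    for q in quads.values():
        a = patch_area(q)
        num += region_mean_curvature(fld, q) * a
        den += a
    whole = region_mean_curvature(fld, patch)
    assert num / den == pytest.approx(whole, abs=1e-12)


def test_profile_total_bounded_by_extent(small_bone):
    patch = small_bone.cap_patch("distal")
    frame = small_bone.truth_frame
    w, _ = max_extents(patch, frame)
    prof = width_profile(patch, frame, step=2.0)
    tab = prof.table[prof.table["present"]]
    edge = small_bone.mesh.edges_unique_length.mean()
    assert tab["total_distance"].max() <= w + 1e-9
    assert tab["total_distance"].max() >= w - 4 * edge  # profile nearly attains it
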