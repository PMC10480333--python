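"""ICP registration, transform application, field voxelization."""

import numpy as np
import pytest
import trimesh

from aneuwall.mesh import ScalarField, TriangleMesh
from aneuwall.transfer import (
    VoxelGrid,
    apply_transform,
    assign_field_to_voxels,
    field_to_slice,
    icp_register,
    load_transform,
    save_transform,
)


@pytest.fixture(scope="module")
def ellipsoid():
    """Asymmetric phantom: an ellipsoid with three distinct axes plus a
    one-sided radial bulge, so no nontrivial rotation maps it onto
    itself and the registration problem has a unique solution."""
    tm = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    unit = np.asarray(tm.vertices)
    w = np.array([0.8, 0.5, 0.33])
    w /= np.linalg.norm(w)
    bulge = 1.0 + 0.25 * np.tanh(3.0 * (unit @ w))
    verts = unit * bulge[:, None] * np.array([3.0, 4.0, 5.0])
    return TriangleMesh(verts, np.asarray(tm.faces))


def rigid(angle_deg, axis, translation):
    T = trimesh.transformations.rotation_matrix(
        np.deg2rad(angle_deg), axis)
    T[:3, 3] = translation
    return T


def rotation_angle_deg(R):
    c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return np.degrees(np.arccos(c))


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------

def test_identical_meshes_give_identity(ellipsoid):
    res = icp_register(ellipsoid, ellipsoid)
    assert res.rms == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.transform, np.eye(4), atol=1e-7)


def test_known_transform_recovered(ellipsoid):
    T_true = rigid(10.0, (0.3, 0.5, 0.8), (1.0, 2.0, 3.0))
    target = apply_transform(ellipsoid, T_true)
    res = icp_register(ellipsoid, target)
    dR = res.transform[:3, :3] @ T_true[:3, :3].T
    assert rotation_angle_deg(dR) < 0.5
    assert np.linalg.norm(res.transform[:3, 3] - T_true[:3, 3]) < 0.1


def test_transform_recovered_under_vertex_noise(ellipsoid):
    rng = np.random.default_rng(3)
    T_true = rigid(10.0, (0.3, 0.5, 0.8), (1.0, 2.0, 3.0))
    target = apply_transform(ellipsoid, T_true)
    scale = 0.01 * np.linalg.norm(np.ptp(ellipsoid.vertices, axis=0)) / 2
    noisy = TriangleMesh(
        target.vertices + rng.normal(0, scale, target.vertices.shape),
        target.faces)
    res = icp_register(ellipsoid, noisy)
    dR = res.transform[:3, :3] @ T_true[:3, :3].T
    assert rotation_angle_deg(dR) < 2.0
    assert np.linalg.norm(res.transform[:3, 3] - T_true[:3, 3]) < 0.5


def test_icp_rms_history_non_increasing(ellipsoid):
    T_true = rigid(25.0, (0, 1, 0), (2.0, -1.0, 0.5))
    res = icp_register(ellipsoid, apply_transform(ellipsoid, T_true))
    assert np.all(np.diff(res.rms_history) <= 1e-9)


# ---------------------------------------------------------------------------
# apply_transform
# ---------------------------------------------------------------------------

def test_identity_transform_is_noop(ellipsoid):
    out = apply_transform(ellipsoid, np.eye(4))
    assert np.allclose(out.vertices, ellipsoid.vertices)


def test_transform_composition(ellipsoid):
    T1 = rigid(15.0, (1, 0, 0), (1, 0, 0))
    T2 = rigid(-30.0, (0, 0, 1), (0, 2, -1))
    seq = apply_transform(apply_transform(ellipsoid, T1), T2)
    comp = apply_transform(ellipsoid, T2 @ T1)
    assert np.allclose(seq.vertices, comp.vertices, atol=1e-12)


def test_rigidity_preserves_pairwise_distances(ellipsoid):
    T = rigid(40.0, (1, 1, 0), (5, 5, 5))
    out = apply_transform(ellipsoid, T)
    idx = np.arange(0, ellipsoid.n_vertices, 37)
    d0 = np.linalg.norm(ellipsoid.vertices[idx][:, None]
                        - ellipsoid.vertices[idx][None], axis=2)
    d1 = np.linalg.norm(out.vertices[idx][:, None]
                        - out.vertices[idx][None], axis=2)
    assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)


def test_non_rigid_transform_rejected(ellipsoid):
    T = np.diag([2.0, 1.0, 1.0, 1.0])
    with pytest.raises(ValueError, match="rigid"):
        apply_transform(ellipsoid, T)


def test_transform_json_roundtrip(tmp_path):
    T = rigid(12.0, (0, 1, 1), (0.1, 0.2, 0.3))
    save_transform(T, tmp_path / "t.json")
    assert np.allclose(load_transform(tmp_path / "t.json"), T)


# ---------------------------------------------------------------------------
# voxel assignment
# ---------------------------------------------------------------------------

def two_vertex_mesh():
    verts = np.array([[0.2, 0.5, 0.5], [0.8, 0.5, 0.5]])
    faces = np.array([[0, 1, 1]])
    return TriangleMesh(verts, faces)


def test_single_vertex_value_fills_the_volume():
    mesh = TriangleMesh(np.array([[0.0, 0.0, 0.0]]),
                        np.array([[0, 0, 0]]))
    grid = VoxelGrid.make((0, 0, 0), 0.1, (5, 5, 5))
    vol = assign_field_to_voxels(mesh, [3.5], grid)
    assert np.all(vol == 3.5)


def test_two_vertex_partition_matches_brute_force():
    mesh = two_vertex_mesh()
    field = ScalarField([1.0, 2.0], mesh)
    grid = VoxelGrid.make((0, 0, 0), 0.05, (20, 20, 20))
    vol = assign_field_to_voxels(mesh, field, grid)
    centers = grid.voxel_centers()
    d = np.linalg.norm(centers[:, None, :] - mesh.vertices[None], axis=2)
    # exhaustive nearest-neighbor with lowest-index tie-break
    expected = np.where(d[:, 0] <= d[:, 1], 1.0, 2.0).reshape(grid.shape)
    assert np.array_equal(vol, expected)


def test_output_range_is_subset_of_field_values(dome_phantom):
    from aneuwall.synthetic import generate_wss_field

    field = generate_wss_field(dome_phantom.target, "gradient", seed=4)
    grid = VoxelGrid.make((-5, -5, 0), 1.0, (11, 11, 6))
    vol = assign_field_to_voxels(dome_phantom.target, field, grid)
    assert set(np.unique(vol)) <= set(np.asarray(field))


def test_empty_grid_rejected():
    mesh = two_vertex_mesh()
    with pytest.raises(ValueError):
        assign_field_to_voxels(mesh, [1.0, 2.0],
                               VoxelGrid.make((0, 0, 0), 0.1, (0, 4, 4)))


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def test_axis_aligned_slice_equals_voxel_plane():
    # volume whose value identifies the z-plane: any axis-aligned slice
    # must be constant at the plane's own value
    vol = np.broadcast_to(np.arange(8)[None, None, :], (6, 7, 8)).copy()
    grid = VoxelGrid.make((0, 0, 0), 1.0, (6, 7, 8))
    sl = field_to_slice(vol, grid, offset_mm=3.0, axis_direction=(0, 0, 1),
                        px_per_mm=1.0)
    assert np.all(sl == 3)


def test_constant_volume_gives_constant_slice():
    vol = np.full((5, 5, 5), 2.25)
    grid = VoxelGrid.make((0, 0, 0), 0.5, (5, 5, 5))
    sl = field_to_slice(vol, grid, offset_mm=1.0)
    assert np.all(sl == 2.25)


def test_two_value_volume_slice_has_straight_boundary():
    mesh = two_vertex_mesh()
    grid = VoxelGrid.make((0, 0, 0), 0.05, (20, 20, 20))
    vol = assign_field_to_voxels(mesh, [1.0, 2.0], grid)
    sl = field_to_slice(vol, grid, offset_mm=0.5, axis_direction=(0, 0, 1))
    # exactly one transition per row, all at the same position
    trans = [np.flatnonzero(np.diff(row)) for row in sl.T]
    counts = {len(t) for t in trans}
    assert counts == {1}
    cols = np.array([t[0] for t in trans])
    assert np.ptp(cols) <= 1


def test_plane_outside_volume_rejected():
    vol = np.zeros((4, 4, 4))
    grid = VoxelGrid.make((0, 0, 0), 0.1, (4, 4, 4))
    with pytest.raises(ValueError, match="outside"):
        field_to_slice(vol, grid, offset_mm=5.0)
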