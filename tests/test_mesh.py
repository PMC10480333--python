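"""Mesh model, centroid, inner/outer classification and wall thickness."""

import numpy as np
import pytest
import trimesh

from aneuwall.mesh import (
    ScalarField,
    TriangleMesh,
    VertexLabeling,
    classify_inner_outer,
    enclosed_volume,
    label_disagreements,
    load_field_csv,
    mesh_center,
    refine_labels,
    save_field_csv,
    wall_thickness,
)

from conftest import winding_numbers


def icosphere(subdivisions=2, radius=1.0):
    return TriangleMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    )


# ---------------------------------------------------------------------------
# mesh_center
# ---------------------------------------------------------------------------

def test_center_of_tetrahedron_is_vertex_mean():
    mesh = TriangleMesh(
        [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)],
        [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)],
    )
    assert np.allclose(mesh_center(mesh), (0.25, 0.25, 0.25))


def test_center_translates_with_the_mesh():
    mesh = icosphere()
    t = np.array([3.0, -2.0, 7.5])
    assert np.allclose(mesh_center(mesh.translated(t)),
                       mesh_center(mesh) + t)


def test_center_of_empty_mesh_raises():
    mesh = TriangleMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
    with pytest.raises(ValueError):
        mesh_center(mesh)


def test_invalid_face_indices_rejected():
    with pytest.raises(ValueError):
        TriangleMesh([(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1, 5)])


# ---------------------------------------------------------------------------
# classify_inner_outer
# ---------------------------------------------------------------------------

def test_closed_sphere_vertices_all_outer():
    # the center lies in the solid interior: every center-to-vertex
    # segment passes through tissue
    labels = classify_inner_outer(icosphere(2, radius=3.0))
    assert np.all(np.asarray(labels) == 1)


def test_bowl_phantom_matches_ground_truth(dome_phantom):
    labels = classify_inner_outer(dome_phantom.dome)
    assert np.array_equal(np.asarray(labels),
                          np.asarray(dome_phantom.labels))


def test_classification_matches_winding_number_oracle(small_dome_phantom):
    """Brute force: dense sampling of each center-vertex segment against
    a solid-angle (winding number) inside test."""
    mesh = small_dome_phantom.dome
    center = mesh_center(mesh)
    t = np.linspace(1e-3, 1.0 - 1e-3, 200)
    expected = np.empty(mesh.n_vertices, dtype=int)
    for i, v in enumerate(mesh.vertices):
        samples = center[None, :] + t[:, None] * (v - center)[None, :]
        inside = winding_numbers(samples, mesh.vertices, mesh.faces) > 0.5
        expected[i] = 1 if inside.any() else 0
    got = classify_inner_outer(mesh)
    assert np.array_equal(np.asarray(got), expected)


def test_non_watertight_mesh_rejected():
    tm = trimesh.creation.icosphere(subdivisions=1)
    holed = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces)[1:])
    with pytest.raises(ValueError, match="watertight"):
        classify_inner_outer(holed)
    with pytest.raises(ValueError, match="watertight"):
        enclosed_volume(holed)


# ---------------------------------------------------------------------------
# refine_labels
# ---------------------------------------------------------------------------

def test_uniform_labeling_is_a_fixed_point():
    mesh = icosphere(1)
    labels = VertexLabeling(np.zeros(mesh.n_vertices, dtype=int))
    assert np.array_equal(np.asarray(refine_labels(mesh, labels)),
                          np.asarray(labels))


def test_isolated_outlier_flips_to_neighbor_majority():
    mesh = icosphere(1)
    labels = np.zeros(mesh.n_vertices, dtype=int)
    labels[0] = 1
    refined = refine_labels(mesh, VertexLabeling(labels))
    assert np.all(np.asarray(refined) == 0)


def test_tie_keeps_current_label():
    # octahedron: every vertex has 4 neighbors; this labeling gives each
    # vertex a 2-2 neighbor split, so under the tie rule it is a fixed
    # point even though no label has a strict majority anywhere
    verts = [(0, 0, 1), (1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0),
             (0, 0, -1)]
    faces = [(0, 1, 2), (0, 2, 3), (0, 3, 4), (0, 4, 1),
             (5, 2, 1), (5, 3, 2), (5, 4, 3), (5, 1, 4)]
    mesh = TriangleMesh(verts, faces)
    labels = np.array([0, 0, 0, 1, 1, 1])
    refined = refine_labels(mesh, VertexLabeling(labels))
    assert np.array_equal(np.asarray(refined), labels)


def test_majority_smoothing_never_increases_boundary_length():
    mesh = icosphere(2)
    rng = np.random.default_rng(0)
    for _ in range(5):
        labels = VertexLabeling(rng.integers(0, 2, mesh.n_vertices))
        before = label_disagreements(mesh, labels)
        after = label_disagreements(mesh, refine_labels(mesh, labels))
        assert after <= before


# ---------------------------------------------------------------------------
# enclosed_volume
# ---------------------------------------------------------------------------

def test_unit_cube_volume():
    box = TriangleMesh.from_trimesh(trimesh.creation.box((1.0, 1.0, 1.0)))
    assert enclosed_volume(box) == pytest.approx(1.0)


def test_icosphere_volume_approaches_ball():
    mesh = icosphere(3, radius=1.0)
    assert enclosed_volume(mesh) == pytest.approx(4 * np.pi / 3, rel=0.01)


def test_volume_scales_cubically_and_is_rigid_invariant():
    mesh = icosphere(2, radius=2.0)
    v = enclosed_volume(mesh)
    scaled = TriangleMesh(mesh.vertices * 1.7, mesh.faces)
    assert enclosed_volume(scaled) == pytest.approx(v * 1.7**3, rel=1e-9)
    rot = trimesh.transformations.rotation_matrix(0.7, (1, 2, 3))[:3, :3]
    moved = TriangleMesh(mesh.vertices @ rot.T + [5, -3, 2], mesh.faces)
    assert enclosed_volume(moved) == pytest.approx(v, rel=1e-9)


# ---------------------------------------------------------------------------
# wall_thickness
# ---------------------------------------------------------------------------

def test_concentric_shell_thickness_is_gap_width(shell_4_5):
    mesh, labels = shell_4_5
    th = wall_thickness(mesh, labels)
    assert np.all(np.asarray(th) >= 0)
    assert np.asarray(th) == pytest.approx(1.0, abs=0.05)


def test_duplicated_opposite_vertex_bounds_thickness(shell_4_5):
    mesh, labels = shell_4_5
    d = 0.25
    v_new = np.vstack([mesh.vertices, mesh.vertices[0] + [d, 0, 0]])
    # append a degenerate-free face reusing two existing vertices
    f_new = np.vstack([mesh.faces, [[0, 1, len(v_new) - 1]]])
    lab_new = np.append(np.asarray(labels), 1 - labels[0])
    th = wall_thickness(TriangleMesh(v_new, f_new), lab_new)
    assert th[0] <= d + 1e-12


def test_single_class_labeling_rejected(shell_4_5):
    mesh, _ = shell_4_5
    with pytest.raises(ValueError):
        wall_thickness(mesh, np.zeros(mesh.n_vertices, dtype=int))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ext", ["ply", "stl", "obj"])
def test_mesh_io_roundtrip(tmp_path, ext):
    mesh = icosphere(1, radius=2.5)
    path = tmp_path / f"m.{ext}"
    mesh.save(path)
    back = TriangleMesh.load(path)
    assert back.n_vertices == mesh.n_vertices
    assert enclosed_volume(back) == pytest.approx(enclosed_volume(mesh),
                                                  rel=1e-5)


def test_scalar_field_csv_roundtrip(tmp_path):
    values = ScalarField([0.5, 1.25, 3.75])
    path = tmp_path / "field.csv"
    save_field_csv(values, path)
    assert np.allclose(load_field_csv(path), values)


def test_scalar_field_rejects_nan():
    with pytest.raises(ValueError):
        ScalarField([1.0, np.nan])
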