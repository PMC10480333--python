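"""Triangle-mesh data model and inner/outer wall classification.

A resected aneurysm dome is a bowl-shaped shell of vessel wall tissue.
Its lumen-facing (*inner*) surface must be distinguished from the
adventitial (*outer*) surface before the dome can be virtually inflated
back toward the preoperative lumen model.  The classification used here
is a visibility test: a vertex is *inner* if the straight segment from
the mesh center ``C`` (the arithmetic mean of all vertices) to the
vertex passes through no tissue, i.e. contains no point interior to the
watertight shell; otherwise it is *outer*.  The raw labeling is then
smoothed by iterated majority voting over edge neighbors.

All coordinates are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriangleMesh",
    "VertexLabeling",
    "ScalarField",
    "mesh_center",
    "classify_inner_outer",
    "refine_labels",
    "enclosed_volume",
    "wall_thickness",
    "label_disagreements",
]

INNER = 0
OUTER = 1


@dataclass
class TriangleMesh:
    """A triangle surface mesh (vertices in mm, faces as vertex triples)."""

    vertices: np.ndarray
    faces: np.ndarray
    _trimesh: trimesh.Trimesh | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    # -- conversions -------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        """The equivalent :class:`trimesh.Trimesh` (cached, unprocessed)."""
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces))

    # -- I/O ---------------------------------------------------------
    @classmethod
    def load(cls, path: str | Path) -> "TriangleMesh":
        """Read an STL/PLY/OBJ surface (units are taken to be mm).

        STL stores unindexed triangle soup, so coincident vertices are
        merged on load to recover shared connectivity.
        """
        loaded = trimesh.load_mesh(str(path), process=False)
        if isinstance(loaded, trimesh.Scene):
            loaded = loaded.to_mesh()
        if str(path).lower().endswith(".stl"):
            loaded.merge_vertices()
        return cls.from_trimesh(loaded)

    def save(self, path: str | Path) -> None:
        self.as_trimesh().export(str(path))

    # -- basic properties --------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def boundary_edges(self) -> np.ndarray:
        """Edges shared by fewer than two faces (empty iff watertight)."""
        tm = self.as_trimesh()
        edges = tm.edges_sorted
        unique, counts = np.unique(edges, axis=0, return_counts=True)
        return unique[counts != 2]

    def require_watertight(self, op: str) -> None:
        if not self.is_watertight:
            bad = self.boundary_edges()
            raise ValueError(
                f"{op} requires a watertight mesh; found {len(bad)} "
                f"non-manifold/boundary edges, e.g. {bad[:5].tolist()}"
            )

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Edge-adjacency: for each vertex, the indices sharing an edge."""
        tm = self.as_trimesh()
        return [np.asarray(n, dtype=np.int64) for n in tm.vertex_neighbors]

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces)


def _check_labeling(mesh: TriangleMesh, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64).ravel()
    if len(labels) != mesh.n_vertices:
        raise ValueError("labeling length does not match vertex count")
    if labels.size and not np.isin(labels, (INNER, OUTER)).all():
        raise ValueError("labels must be 0 (inner) or 1 (outer)")
    return labels


class VertexLabeling(np.ndarray):
    """Per-vertex labels: 0 = inner (lumen-facing), 1 = outer."""

    def __new__(cls, labels, mesh: TriangleMesh | None = None):
        arr = np.asarray(labels, dtype=np.int64).ravel().view(cls)
        if mesh is not None:
            _check_labeling(mesh, arr)
        if arr.size and not np.isin(arr, (INNER, OUTER)).all():
            raise ValueError("labels must be 0 or 1")
        return arr

    @property
    def inner_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self) == INNER)

    @property
    def outer_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self) == OUTER)


class ScalarField(np.ndarray):
    """One finite value per vertex (units set by the producer: Pa, mm...)."""

    def __new__(cls, values, mesh: TriangleMesh | None = None):
        arr = np.asarray(values, dtype=np.float64).ravel().view(cls)
        if mesh is not None and len(arr) != mesh.n_vertices:
            raise ValueError("field length does not match vertex count")
        if arr.size and not np.isfinite(np.asarray(arr)).all():
            raise ValueError("scalar field contains non-finite values")
        return arr


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def mesh_center(mesh: TriangleMesh) -> np.ndarray:
    """Arithmetic mean of the vertex positions (the center ``C``)."""
    if mesh.n_vertices == 0:
        raise ValueError("cannot take the center of an empty mesh")
    return mesh.vertices.mean(axis=0)


def classify_inner_outer(
    mesh: TriangleMesh, eps: float = 1e-6
) -> VertexLabeling:
    """Visibility-based inner/outer labeling of every vertex.

    Vertex ``i`` is labeled inner (0) iff the open segment from the mesh
    center ``C`` to ``v_i`` contains no point interior to the shell.
    The segment is shrunk by ``eps`` times its length at the vertex end
    so that the vertex's own incident faces never count as occluders.

    Implementation: ray-triangle intersections partition each segment
    into sub-intervals; the midpoint of every sub-interval is tested for
    containment in the watertight shell.  A vertex is outer as soon as
    one sub-interval lies inside the tissue.
    """
    from .geometry import points_inside_mesh, segment_triangle_hits

    mesh.require_watertight("classify_inner_outer")
    center = mesh_center(mesh)
    verts = mesh.vertices
    n = mesh.n_vertices

    dirs = verts - center[None, :]
    lengths = np.linalg.norm(dirs, axis=1)
    labels = np.full(n, OUTER, dtype=np.int64)
    # zero-length segments (vertex at the center) are trivially inner
    degenerate = lengths <= 1e-12
    labels[degenerate] = INNER

    live = np.flatnonzero(~degenerate)
    if live.size == 0:
        return VertexLabeling(labels, mesh)

    ray_idx, t_hits = segment_triangle_hits(
        center, dirs[live], mesh.vertices, mesh.faces,
        t_min=1e-9, t_max=1.0 - eps,
    )
    cut_params: list[list[float]] = [[] for _ in range(live.size)]
    for r, ti in zip(ray_idx, t_hits):
        cut_params[r].append(float(ti))

    probes: list[np.ndarray] = []
    probe_owner: list[int] = []
    for k, idx in enumerate(live):
        hi = 1.0 - eps
        cuts = sorted(c for c in cut_params[k] if 1e-9 < c < hi)
        bounds = [0.0, *cuts, hi]
        mids = 0.5 * (np.array(bounds[:-1]) + np.array(bounds[1:]))
        probes.append(center + mids[:, None] * dirs[idx][None, :])
        probe_owner.extend([idx] * len(mids))

    pts = np.concatenate(probes, axis=0)
    inside = points_inside_mesh(pts, mesh.vertices, mesh.faces)
    owner = np.asarray(probe_owner)
    blocked = np.zeros(n, dtype=bool)
    np.logical_or.at(blocked, owner[inside], True)
    labels[live] = np.where(blocked[live], OUTER, INNER)
    return VertexLabeling(labels, mesh)


def refine_labels(
    mesh: TriangleMesh,
    labeling: VertexLabeling,
    max_passes: int = 100,
    single_pass: bool = False,
) -> VertexLabeling:
    """Majority smoothing of a labeling over edge neighbors.

    Each vertex takes the strict majority label of its edge neighbors;
    ties (and isolated vertices) keep the current label.  Updates run
    sequentially in vertex-index order and repeat until a fixed point or
    ``max_passes``; ``single_pass`` restricts to one sweep.
    """
    labels = _check_labeling(mesh, labeling).copy()
    neighbors = mesh.vertex_neighbors()
    passes = 1 if single_pass else max_passes
    for _ in range(passes):
        changed = False
        for i in range(mesh.n_vertices):
            nbr = neighbors[i]
            if len(nbr) == 0:
                continue
            ones = int(labels[nbr].sum())
            zeros = len(nbr) - ones
            if ones > zeros and labels[i] != OUTER:
                labels[i] = OUTER
                changed = True
            elif zeros > ones and labels[i] != INNER:
                labels[i] = INNER
                changed = True
        if not changed:
            break
    return VertexLabeling(labels, mesh)


def label_disagreements(mesh: TriangleMesh, labeling) -> int:
    """Number of mesh edges whose endpoints carry different labels."""
    labels = _check_labeling(mesh, labeling)
    edges = mesh.as_trimesh().edges_unique
    return int((labels[edges[:, 0]] != labels[edges[:, 1]]).sum())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume (mm^3) enclosed by a watertight shell, via the divergence
    theorem; the sign of the orientation is discarded."""
    mesh.require_watertight("enclosed_volume")
    return float(abs(mesh.as_trimesh().volume))


def wall_thickness(mesh: TriangleMesh, labeling) -> ScalarField:
    """Per-vertex wall thickness estimate (mm): the distance from each
    vertex to the nearest vertex of the opposite class."""
    labels = _check_labeling(mesh, labeling)
    inner = np.flatnonzero(labels == INNER)
    outer = np.flatnonzero(labels == OUTER)
    if inner.size == 0 or outer.size == 0:
        raise ValueError("wall_thickness requires both inner and outer vertices")
    thickness = np.empty(mesh.n_vertices, dtype=np.float64)
    tree_inner = cKDTree(mesh.vertices[inner])
    tree_outer = cKDTree(mesh.vertices[outer])
    thickness[inner], _ = tree_outer.query(mesh.vertices[inner])
    thickness[outer], _ = tree_inner.query(mesh.vertices[outer])
    return ScalarField(thickness, mesh)


# ---------------------------------------------------------------------------
# scalar-field I/O (2-column CSV: vertex_index,value)
# ---------------------------------------------------------------------------

def save_field_csv(field_values, path: str | Path) -> None:
    arr = np.asarray(field_values, dtype=np.float64).ravel()
    out = np.column_stack([np.arange(len(arr)), arr])
    np.savetxt(path, out, fmt="%d,%.10g", header="vertex_index,value",
               comments="")


def load_field_csv(path: str | Path, mesh: TriangleMesh | None = None) -> ScalarField:
    data = np.loadtxt(path, delimiter=",", skiprows=1).reshape(-1, 2)
    order = np.argsort(data[:, 0])
    return ScalarField(data[order, 1], mesh)
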