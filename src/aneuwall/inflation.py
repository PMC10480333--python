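"""Virtual inflation of a deflated, resected aneurysm dome.

After microsurgical clipping the resected dome collapses: without blood
pressure the bowl-shaped tissue sample no longer matches the in vivo
shape seen in preoperative imaging.  Virtual inflation restores the
shape geometrically: the lumen-facing (inner) vertices are pulled, in
damped steps, toward the preoperative lumen surface, and the outer
vertices follow the average motion of their nearest inner vertices so
that the local wall thickness is preserved.  No material model is
involved; the preoperative lumen mesh acts as the ground truth for the
amount of inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import INNER, TriangleMesh, VertexLabeling, _check_labeling

__all__ = ["InflationConfig", "InflationResult", "inflate_dome"]


@dataclass(frozen=True)
class InflationConfig:
    """Parameters of the inflation iteration.

    k_target
        Number of closest target (lumen) vertices whose centroid each
        inner vertex moves toward.
    k_inner
        Number of closest inner vertices whose displacement is averaged
        to move each outer vertex.
    step_fraction
        Damping: fraction of the remaining displacement applied per
        iteration, in (0, 1].
    max_iterations, convergence_tol
        Iteration stops when the largest inner-vertex displacement of a
        step falls below ``convergence_tol`` (mm) or after
        ``max_iterations`` steps.
    """

    k_target: int = 5
    k_inner: int = 5
    step_fraction: float = 0.5
    max_iterations: int = 200
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.k_target < 1 or self.k_inner < 1:
            raise ValueError("k_target and k_inner must be >= 1")
        if not (0.0 < self.step_fraction <= 1.0):
            raise ValueError("step_fraction must be in (0, 1]")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class InflationResult:
    mesh: TriangleMesh
    n_iterations: int
    converged: bool
    #: largest inner-vertex displacement per iteration (mm)
    max_displacement: np.ndarray = field(repr=False, default=None)
    #: RMS distance of inner vertices to the nearest target vertex,
    #: recorded before the first and after every iteration (mm)
    rms_to_target: np.ndarray = field(repr=False, default=None)


def inflate_dome(
    dome: TriangleMesh,
    labeling: VertexLabeling,
    target: TriangleMesh,
    cfg: InflationConfig | None = None,
) -> InflationResult:
    """Iteratively deform ``dome`` so its inner surface follows ``target``.

    Per iteration each inner vertex moves by ``step_fraction`` of the
    way toward the centroid of its ``k_target`` nearest target vertices;
    each outer vertex moves by the average displacement of its
    ``k_inner`` nearest inner vertices (nearest in the current
    configuration).  Connectivity and vertex count are unchanged.
    """
    cfg = cfg or InflationConfig()
    labels = _check_labeling(dome, labeling)
    inner = np.flatnonzero(labels == INNER)
    outer = np.flatnonzero(labels != INNER)
    if inner.size == 0:
        raise ValueError("labeling contains no inner vertices")
    if target.n_vertices == 0:
        raise ValueError("target mesh is empty")

    verts = dome.vertices.copy()
    k_t = min(cfg.k_target, target.n_vertices)
    k_i = min(cfg.k_inner, inner.size)
    target_tree = cKDTree(target.vertices)

    def rms(points: np.ndarray) -> float:
        d, _ = target_tree.query(points)
        return float(np.sqrt(np.mean(d**2)))

    max_disp: list[float] = []
    rms_hist: list[float] = [rms(verts[inner])]
    converged = False
    n_done = 0
    for _ in range(cfg.max_iterations):
        inner_pos = verts[inner]
        _, idx = target_tree.query(inner_pos, k=k_t)
        idx = np.atleast_2d(idx.reshape(len(inner), k_t))
        goals = target.vertices[idx].mean(axis=1)
        disp = cfg.step_fraction * (goals - inner_pos)

        if outer.size:
            inner_tree = cKDTree(inner_pos)
            _, nn = inner_tree.query(verts[outer], k=k_i)
            nn = nn.reshape(len(outer), k_i)
            outer_disp = disp[nn].mean(axis=1)
            verts[outer] += outer_disp
        verts[inner] += disp

        n_done += 1
        step = float(np.linalg.norm(disp, axis=1).max())
        max_disp.append(step)
        rms_hist.append(rms(verts[inner]))
        if step < cfg.convergence_tol:
            converged = True
            break

    return InflationResult(
        mesh=TriangleMesh(verts, dome.faces.copy()),
        n_iterations=n_done,
        converged=converged,
        max_displacement=np.asarray(max_disp),
        rms_to_target=np.asarray(rms_hist),
    )
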