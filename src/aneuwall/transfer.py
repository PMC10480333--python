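"""Rigid registration and transfer of hemodynamic fields to voxels.

The resected dome mesh is co-registered to the surface extracted from
the ex vivo micro-CT by point-to-point iterative closest point (ICP);
the same rigid transform is then applied to the preoperative aneurysm
model, bringing its per-vertex hemodynamic fields (e.g. wall shear
stress in Pa) into micro-CT space.  Each micro-CT voxel is finally
assigned the value of the nearest mesh vertex, so histology,
calcification and hemodynamics can be overlaid slice by slice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .mesh import ScalarField, TriangleMesh
from .slides import _plane_basis, _require_unit

__all__ = [
    "ICPResult",
    "VoxelGrid",
    "icp_register",
    "apply_transform",
    "assign_field_to_voxels",
    "field_to_slice",
    "save_transform",
    "load_transform",
    "save_volume_tiff",
    "save_volume_nifti",
]


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

@dataclass
class ICPResult:
    transform: np.ndarray          # 4x4 rigid transform (source -> target)
    rms: float                     # final RMS closest-point distance (mm)
    rms_history: np.ndarray = field(repr=False, default=None)
    converged: bool = True


def _kabsch(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares rigid transform mapping src points onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = cd - R @ cs
    return T


def _principal_axes(points: np.ndarray) -> np.ndarray:
    cov = np.cov((points - points.mean(axis=0)).T)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    return axes


def _apply(T: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ T[:3, :3].T + T[:3, 3]


def icp_register(
    source: TriangleMesh,
    target: TriangleMesh,
    max_iterations: int = 100,
    tol: float = 1e-6,
) -> ICPResult:
    """Point-to-point ICP of the source vertex set onto the target's.

    Initialization tries the identity rotation about aligned centroids
    plus principal-axes pre-rotations (all four proper sign flips) and
    keeps the best start; iterations alternate nearest-vertex matching
    (k-d tree) with the Kabsch least-squares rigid update until the RMS
    improvement drops below ``tol`` mm.  If the final RMS exceeds the
    initial one a warning is issued and the best transform seen is
    returned.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("both meshes must be nonempty")
    src = source.vertices
    dst = target.vertices
    tree = cKDTree(dst)

    def rms_of(T: np.ndarray) -> float:
        d, _ = tree.query(_apply(T, src))
        return float(np.sqrt(np.mean(d**2)))

    # candidate initializations: centroid shift, optionally pre-rotated
    # by principal-axes alignment with the four proper sign choices
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    T_shift = np.eye(4)
    T_shift[:3, 3] = cd - cs
    candidates = [T_shift]
    A_s, A_d = _principal_axes(src), _principal_axes(dst)
    for fx, fy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        F = np.diag([fx, fy, fx * fy])
        R0 = A_d @ F @ A_s.T
        T0 = np.eye(4)
        T0[:3, :3] = R0
        T0[:3, 3] = cd - R0 @ cs
        candidates.append(T0)
    T = min(candidates, key=rms_of)

    history = [rms_of(T)]
    best_T, best_rms = T.copy(), history[0]
    for _ in range(max_iterations):
        moved = _apply(T, src)
        _, idx = tree.query(moved)
        T = _kabsch(src, dst[idx])
        r = rms_of(T)
        history.append(r)
        if r < best_rms:
            best_T, best_rms = T.copy(), r
        if abs(history[-2] - r) < tol:
            break

    converged = history[-1] <= history[0] + 1e-12
    if not converged:
        warnings.warn("ICP diverged; returning the best transform seen")
    return ICPResult(transform=best_T, rms=best_rms,
                     rms_history=np.asarray(history), converged=converged)


def apply_transform(mesh: TriangleMesh, transform: np.ndarray) -> TriangleMesh:
    """Apply a rigid 4x4 transform to all vertices (faces unchanged)."""
    T = np.asarray(transform, dtype=np.float64)
    if T.shape != (4, 4):
        raise ValueError("transform must be a 4x4 matrix")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or \
            not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("transform is not rigid (R not a proper rotation)")
    return TriangleMesh(_apply(T, mesh.vertices), mesh.faces.copy())


def save_transform(transform: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"transform": np.asarray(transform).tolist()}, indent=2))


def load_transform(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["transform"])


# ---------------------------------------------------------------------------
# voxel assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: ``origin`` (mm) is the center of voxel
    (0,0,0); ``spacing`` (mm) is isotropic or per-axis; ``shape`` is
    (nx, ny, nz)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    @classmethod
    def make(cls, origin, spacing, shape) -> "VoxelGrid":
        spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
        return cls(tuple(np.asarray(origin, float)), tuple(spacing),
                   tuple(int(s) for s in shape))

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny),
                                 np.arange(nz), indexing="ij")
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


def assign_field_to_voxels(
    mesh: TriangleMesh, field_values, grid: VoxelGrid
) -> np.ndarray:
    """Nearest-vertex transfer of a per-vertex scalar onto a voxel grid.

    Each voxel center takes the value of the Euclidean-nearest mesh
    vertex; exact distance ties resolve to the lowest vertex index.  No
    interpolation: the output range is a subset of the field values.
    """
    values = ScalarField(field_values, mesh)
    if mesh.n_vertices == 0:
        raise ValueError("mesh is empty")
    if np.prod(grid.shape) == 0:
        raise ValueError("voxel grid is empty")
    centers = grid.voxel_centers()
    tree = cKDTree(mesh.vertices)
    k = min(2, mesh.n_vertices)
    d, idx = tree.query(centers, k=k)
    if k == 2:
        d, idx = np.atleast_2d(d), np.atleast_2d(idx)
        tie = np.isclose(d[:, 0], d[:, 1], rtol=1e-12, atol=1e-12)
        nearest = np.where(tie, np.minimum(idx[:, 0], idx[:, 1]), idx[:, 0])
    else:
        nearest = np.asarray(idx).ravel()
    return np.asarray(values)[nearest].reshape(grid.shape)


def field_to_slice(
    volume: np.ndarray,
    grid: VoxelGrid,
    offset_mm: float,
    axis_direction=(0.0, 0.0, 1.0),
    px_per_mm: float | None = None,
) -> np.ndarray:
    """Nearest-voxel resampling of a planar slice through a scalar volume,
    for overlay with mapped histology."""
    d = _require_unit(axis_direction)
    vol = np.asarray(volume)
    if vol.shape != tuple(grid.shape):
        raise ValueError("volume shape does not match the grid")
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    lo = origin - 0.5 * spacing
    hi = origin + (np.asarray(grid.shape) - 0.5) * spacing
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    proj = corners @ d
    if not (proj.min() - 1e-9 <= offset_mm <= proj.max() + 1e-9):
        raise ValueError("plane lies outside the volume")

    if px_per_mm is None:
        px_per_mm = 1.0 / float(spacing.min())
    u, v = _plane_basis(d)
    pu, pv = corners @ u, corners @ v
    step = 1.0 / px_per_mm
    nu = max(2, int(np.ceil((pu.max() - pu.min()) / step)))
    nv = max(2, int(np.ceil((pv.max() - pv.min()) / step)))
    cc, rr = np.meshgrid(np.arange(nu), np.arange(nv))
    pts = (offset_mm * d + (pu.min() + cc.ravel()[:, None] * step) * u
           + (pv.min() + rr.ravel()[:, None] * step) * v)
    coords = (pts - origin) / spacing
    sampled = map_coordinates(vol.astype(np.float64), coords.T, order=0,
                              mode="nearest", cval=np.nan)
    return sampled.reshape(nv, nu)


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def save_volume_tiff(volume: np.ndarray, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF stack (pages along axis 2)."""
    vol = np.asarray(volume, dtype=np.float32)
    tifffile.imwrite(str(path), np.moveaxis(vol, 2, 0))


def save_volume_nifti(volume: np.ndarray, grid: VoxelGrid,
                      path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))
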