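"""Histologic slide-stack bookkeeping and positioning along the micro-CT axis.

Histologic sectioning removes or destroys slices (they slip away,
stainings fail), leaving gaps; a stack description records each slide's
stain, thickness and a placeholder flag for removed sections.  Summing
thicknesses and comparing with the expected tissue length detects
missing slides; cumulative mid-slice offsets place each slide along the
cutting axis of the micro-CT model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mesh import TriangleMesh

__all__ = [
    "Slide",
    "SlideStack",
    "stack_length",
    "slide_positions",
    "length_report",
    "slice_mesh_at_plane",
    "PlaneSlice",
]


@dataclass
class Slide:
    index: int
    thickness_um: float
    stain: str | None = None
    file: str | None = None
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("slide thickness must be positive")


@dataclass
class SlideStack:
    """Ordered slides in cutting order (placeholders included)."""

    slides: list[Slide] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.slides)

    def __iter__(self):
        return iter(self.slides)

    @classmethod
    def from_file(cls, path: str | Path) -> "SlideStack":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        return cls([Slide(**entry) for entry in data["slides"]])

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = {"slides": [asdict(s) for s in self.slides]}
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))


def stack_length(stack: SlideStack) -> float:
    """Total stack length in micrometres, placeholders included."""
    if len(stack) == 0:
        raise ValueError("empty slide stack")
    return float(sum(s.thickness_um for s in stack))


def _require_unit(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=np.float64).ravel()
    if d.shape != (3,) or not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
        raise ValueError("axis_direction must be a unit 3-vector")
    return d


def slide_positions(
    stack: SlideStack, axis_origin: float = 0.0,
    axis_direction=(0.0, 0.0, 1.0),
) -> np.ndarray:
    """Mid-slice plane offsets (mm) of every slide along the cutting axis:
    offset_i = origin + sum of thicknesses before slide i + half its own."""
    _require_unit(axis_direction)
    t_mm = np.array([s.thickness_um for s in stack]) / 1000.0
    if t_mm.size == 0:
        raise ValueError("empty slide stack")
    return axis_origin + np.cumsum(t_mm) - 0.5 * t_mm


def length_report(stack: SlideStack, expected_length_mm: float) -> dict:
    """Compare the stack length against the expected tissue length.

    A positive discrepancy (stack shorter than the sample) yields an
    estimate of missing slides; a negative one indicates the stack is
    longer than the measured sample, which is expected with tissue
    shrinkage during fixation.
    """
    if expected_length_mm <= 0:
        raise ValueError("expected length must be positive")
    total_mm = stack_length(stack) / 1000.0
    disc = expected_length_mm - total_mm
    median_t = float(np.median([s.thickness_um for s in stack])) / 1000.0
    missing = int(round(disc / median_t)) if disc > 0 else 0
    return {
        "stack_length_mm": total_mm,
        "expected_length_mm": float(expected_length_mm),
        "discrepancy_mm": float(disc),
        "relative_discrepancy": float(disc / expected_length_mm),
        "n_slides": len(stack),
        "n_placeholders": sum(s.placeholder for s in stack),
        "median_thickness_mm": median_t,
        "estimated_missing_slides": missing,
        "shrinkage_warning": bool(disc < 0),
    }


def stack_overview_figure(stack: SlideStack, path: str | Path,
                          expected_length_mm: float | None = None) -> None:
    """Render a static overview of the stack: one bar per slide along
    the cutting axis (placeholders hatched), optional expected length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.2))
    start = 0.0
    for s in stack:
        w = s.thickness_um / 1000.0
        ax.barh(0, w, left=start, height=0.6,
                color="lightgray" if s.placeholder else "steelblue",
                hatch="//" if s.placeholder else None,
                edgecolor="black", linewidth=0.5)
        start += w
    if expected_length_mm is not None:
        ax.axvline(expected_length_mm, color="crimson", linestyle="--",
                   label=f"expected {expected_length_mm} mm")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("position along cutting axis (mm)")
    ax.set_yticks([])
    ax.set_title(f"{len(stack)} slides, "
                 f"{stack_length(stack) / 1000.0:.3f} mm total")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# mesh cross-sections
# ---------------------------------------------------------------------------

@dataclass
class PlaneSlice:
    """A rasterized filled cross-section of a mesh.

    ``origin`` is the 3D position of pixel (row 0, col 0); ``u`` and
    ``v`` are the in-plane unit vectors of columns and rows.
    """

    mask: np.ndarray
    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    px_per_mm: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) / self.px_per_mm**2

    def pixel_points(self) -> np.ndarray:
        """3D coordinates of every pixel center, shape (H, W, 3)."""
        h, w = self.mask.shape
        cc, rr = np.meshgrid(np.arange(w), np.arange(h))
        step = 1.0 / self.px_per_mm
        return (self.origin[None, None, :]
                + cc[:, :, None] * step * self.u[None, None, :]
                + rr[:, :, None] * step * self.v[None, None, :])


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def slice_mesh_at_plane(
    mesh: TriangleMesh,
    offset_mm: float,
    axis_direction=(0.0, 0.0, 1.0),
    px_per_mm: float = 20.0,
    margin_mm: float = 0.5,
) -> PlaneSlice:
    """Filled cross-section mask of a watertight mesh at a cutting plane.

    The plane passes through ``offset_mm`` along ``axis_direction`` from
    the coordinate origin; pixels whose 3D centers are inside the mesh
    are foreground.
    """
    from .geometry import points_inside_mesh

    d = _require_unit(axis_direction)
    mesh.require_watertight("slice_mesh_at_plane")
    proj = mesh.vertices @ d
    if not (proj.min() - 1e-9 <= offset_mm <= proj.max() + 1e-9):
        raise ValueError("plane does not intersect the mesh bounding box")

    u, v = _plane_basis(d)
    pu = mesh.vertices @ u
    pv = mesh.vertices @ v
    u0, u1 = pu.min() - margin_mm, pu.max() + margin_mm
    v0, v1 = pv.min() - margin_mm, pv.max() + margin_mm
    step = 1.0 / px_per_mm
    nu = max(2, int(np.ceil((u1 - u0) / step)))
    nv = max(2, int(np.ceil((v1 - v0) / step)))
    origin = offset_mm * d + u0 * u + v0 * v

    cc, rr = np.meshgrid(np.arange(nu), np.arange(nv))
    pts = (origin[None, :]
           + cc.ravel()[:, None] * step * u[None, :]
           + rr.ravel()[:, None] * step * v[None, :])
    inside = points_inside_mesh(pts, mesh.vertices, mesh.faces).reshape(nv, nu)
    return PlaneSlice(mask=inside, origin=origin, u=u, v=v,
                      px_per_mm=px_per_mm)
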