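"""Seeded synthetic phantoms for every input the pipeline consumes.

No clinical data is required anywhere in the package: these generators
emulate the study inputs with known ground truth —

* a bowl-shaped aneurysm-dome shell (hemispherical wall plus rim) in a
  deflated pose, together with the preoperative lumen sphere it should
  inflate toward, ground-truth inner/outer labels and wall thickness;
* u-shaped stained histology patches in the four stain palettes, with
  exact tissue masks;
* smooth positive per-vertex wall-shear-stress fields;
* micro-CT slice-mask stacks of the dome wall with ellipsoidal
  calcification blobs.

All generators are deterministic under a fixed seed.

Deflation is modeled as a volume-preserving squash (axial compression
by the deflation factor, lateral dilation by its inverse square root):
collapsed tissue flattens and spreads but, being nearly incompressible,
keeps its wall volume — which is what makes the small volume change
after a thickness-preserving inflation meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter

from .histology import StainLabel, TissueMask
from .mesh import ScalarField, TriangleMesh, VertexLabeling
from .slides import slice_mesh_at_plane

__all__ = [
    "DomePhantom",
    "generate_dome_phantom",
    "generate_histology_image",
    "generate_wss_field",
    "generate_microct_stack",
    "spherical_shell",
    "STAIN_PALETTES",
]


# ---------------------------------------------------------------------------
# dome phantom
# ---------------------------------------------------------------------------

def _hemisphere_grid(radius: float, n_rings: int, n_az: int):
    """Vertex rings of an upper hemisphere: pole + n_rings rings down to
    the equator (z = 0); returns (vertices, ring index lists)."""
    verts = [np.array([[0.0, 0.0, radius]])]
    rings = []
    count = 1
    for k in range(1, n_rings + 1):
        theta = 0.5 * np.pi * k / n_rings
        phi = 2.0 * np.pi * np.arange(n_az) / n_az
        ring = np.column_stack([
            radius * np.sin(theta) * np.cos(phi),
            radius * np.sin(theta) * np.sin(phi),
            np.full(n_az, radius * np.cos(theta)),
        ])
        rings.append(np.arange(count, count + n_az))
        verts.append(ring)
        count += n_az
    return np.vstack(verts), rings


def _band_faces(ring_a: np.ndarray, ring_b: np.ndarray, flip: bool = False):
    """Triangulate the quad strip between two same-length vertex rings."""
    n = len(ring_a)
    faces = []
    for i in range(n):
        j = (i + 1) % n
        if flip:
            faces.append([ring_a[i], ring_b[i], ring_a[j]])
            faces.append([ring_a[j], ring_b[i], ring_b[j]])
        else:
            faces.append([ring_a[i], ring_a[j], ring_b[i]])
            faces.append([ring_a[j], ring_b[j], ring_b[i]])
    return faces


def _bowl_shell(outer_radius: float, thickness: float, n_rings: int,
                n_az: int):
    """Watertight bowl: outer hemisphere, inner hemisphere, flat rim.

    Returns (mesh, labels) with inner-surface vertices labeled 0.
    Inner and outer surfaces share the angular grid, so radially
    aligned vertex pairs are exactly ``thickness`` apart.
    """
    inner_radius = outer_radius - thickness
    v_out, rings_out = _hemisphere_grid(outer_radius, n_rings, n_az)
    v_in, rings_in = _hemisphere_grid(inner_radius, n_rings, n_az)
    offset = len(v_out)
    rings_in = [r + offset for r in rings_in]
    vertices = np.vstack([v_out, v_in])

    faces: list[list[int]] = []
    # outer cap: pole fan + bands, wound outward
    for i in range(n_az):
        j = (i + 1) % n_az
        faces.append([0, rings_out[0][i], rings_out[0][j]])
    for a, b in zip(rings_out[:-1], rings_out[1:]):
        faces.extend(_band_faces(a, b, flip=False))
    # inner cap: wound inward (normals toward the cavity interior)
    for i in range(n_az):
        j = (i + 1) % n_az
        faces.append([offset, rings_in[0][j], rings_in[0][i]])
    for a, b in zip(rings_in[:-1], rings_in[1:]):
        faces.extend(_band_faces(a, b, flip=True))
    # rim between the two equator rings
    faces.extend(_band_faces(rings_out[-1], rings_in[-1], flip=True))

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces),
                           process=False)
    trimesh.repair.fix_normals(mesh)
    labels = np.ones(len(vertices), dtype=np.int64)
    labels[offset:] = 0  # whole inner surface incl. its equator ring
    return TriangleMesh.from_trimesh(mesh), VertexLabeling(labels)


@dataclass
class DomePhantom:
    dome: TriangleMesh           # deflated resected-dome shell
    target: TriangleMesh         # preoperative lumen sphere
    labels: VertexLabeling       # ground-truth inner(0)/outer(1)
    thickness: ScalarField       # ground-truth wall thickness (mm)
    undeformed: TriangleMesh     # the shell before deflation


def generate_dome_phantom(
    outer_radius: float = 5.0,
    wall_thickness: float = 0.5,
    deflation_factor: float = 0.8,
    mesh_resolution: int = 20,
    seed: int = 0,
    jitter_mm: float = 0.01,
) -> DomePhantom:
    """Deflated bowl-shaped dome shell plus its inflation ground truth.

    The shell (outer radius in mm, wall thickness in mm) is squashed
    axially by ``deflation_factor`` and dilated laterally by its inverse
    square root, preserving the wall volume exactly; a small seeded
    vertex jitter breaks the perfect symmetry.  The target is the lumen
    sphere of radius ``outer_radius - wall_thickness``.
    """
    if not (0.0 < deflation_factor <= 1.0):
        raise ValueError("deflation_factor must be in (0, 1]")
    if not (0.0 < wall_thickness < outer_radius):
        raise ValueError("wall_thickness must be in (0, outer_radius)")
    rng = np.random.default_rng(seed)

    shell, labels = _bowl_shell(outer_radius, wall_thickness,
                                n_rings=mesh_resolution,
                                n_az=2 * mesh_resolution)
    f = deflation_factor
    squash = np.array([1.0 / np.sqrt(f), 1.0 / np.sqrt(f), f])
    deflated = shell.vertices * squash[None, :]
    deflated = deflated + rng.normal(0.0, jitter_mm, deflated.shape)

    target = TriangleMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions=4,
                                   radius=outer_radius - wall_thickness)
    )
    thickness = ScalarField(np.full(shell.n_vertices, wall_thickness))
    return DomePhantom(
        dome=TriangleMesh(deflated, shell.faces.copy()),
        target=target,
        labels=labels,
        thickness=thickness,
        undeformed=shell,
    )


def spherical_shell(r_inner: float, r_outer: float,
                    n_rings: int = 16, n_az: int = 32):
    """Concentric full-sphere shell with aligned grids; returns
    (mesh, labels) with the inner sphere labeled 0."""
    def sphere(radius):
        thetas = np.pi * np.arange(1, n_rings) / n_rings
        verts = [np.array([[0.0, 0.0, radius]])]
        rings = []
        idx = 1
        for th in thetas:
            phi = 2 * np.pi * np.arange(n_az) / n_az
            verts.append(np.column_stack([
                radius * np.sin(th) * np.cos(phi),
                radius * np.sin(th) * np.sin(phi),
                np.full(n_az, radius * np.cos(th)),
            ]))
            rings.append(np.arange(idx, idx + n_az))
            idx += n_az
        verts.append(np.array([[0.0, 0.0, -radius]]))
        v = np.vstack(verts)
        faces = []
        for i in range(n_az):
            j = (i + 1) % n_az
            faces.append([0, rings[0][i], rings[0][j]])
        for a, b in zip(rings[:-1], rings[1:]):
            faces.extend(_band_faces(a, b))
        last = len(v) - 1
        for i in range(n_az):
            j = (i + 1) % n_az
            faces.append([last, rings[-1][j], rings[-1][i]])
        return v, np.asarray(faces)

    vo, fo = sphere(r_outer)
    vi, fi = sphere(r_inner)
    off = len(vo)
    vertices = np.vstack([vo, vi])
    faces = np.vstack([fo, fi[:, ::-1] + off])
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    trimesh.repair.fix_normals(mesh)
    labels = np.ones(len(vertices), dtype=np.int64)
    labels[off:] = 0
    return TriangleMesh.from_trimesh(mesh), VertexLabeling(labels)


# ---------------------------------------------------------------------------
# histology phantoms
# ---------------------------------------------------------------------------

#: (background, tissue base, texture blob color) per stain, 8-bit RGB.
#: Chosen to mimic each stain's gross appearance and to be linearly
#: separable in color space.
STAIN_PALETTES: dict[StainLabel, tuple] = {
    StainLabel.HE: ((242, 238, 244), (212, 130, 170), (92, 44, 130)),
    StainLabel.MT: ((240, 242, 246), (168, 88, 98), (70, 90, 168)),
    StainLabel.ORO: ((246, 238, 232), (232, 204, 196), (198, 34, 44)),
    StainLabel.ASMA: ((244, 240, 234), (196, 152, 112), (122, 74, 34)),
}


@dataclass(frozen=True)
class UShapeParams:
    """Geometry of the u-shaped tissue band, as fractions of image size."""

    center_x: float = 0.5
    center_y: float = 0.45
    mid_radius: float = 0.30
    half_width: float = 0.085
    opening_deg: float = 100.0   # angular gap of the "u" (opens upward)


def _u_mask(size: int, params: UShapeParams) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cx, cy = params.center_x * size, params.center_y * size
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    band = np.abs(r - params.mid_radius * size) < params.half_width * size
    # image y grows downward; the gap is centered on "up" (negative y)
    ang = np.degrees(np.arctan2(-dy, dx))      # 90 = up
    gap = np.abs(((ang - 90.0 + 180.0) % 360.0) - 180.0) \
        < params.opening_deg / 2.0
    return band & ~gap


def generate_histology_image(
    stain: StainLabel | str,
    size: int = 512,
    u_shape_params: UShapeParams | None = None,
    texture_density: float = 0.5,
    seed: int = 0,
    padding_frac: float = 0.03,
) -> tuple[np.ndarray, TissueMask]:
    """A u-shaped stained-tissue patch with its exact mask.

    The tissue band carries the stain's base color plus seeded texture
    blobs in the stain's accent color (nuclei, collagen, lipid droplets
    or actin, depending on the palette); the slide background is light
    and a dark padding frame mimics the scanner border.
    """
    stain = StainLabel(stain)
    params = u_shape_params or UShapeParams()
    rng = np.random.default_rng(seed)
    bg, base, accent = (np.array(c, dtype=np.float64)
                        for c in STAIN_PALETTES[stain])

    mask = _u_mask(size, params)
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = bg[None, None, :]
    img[mask] = base[None, :]

    # texture blobs inside the band; their size scales with the image so
    # the phantom shows the same tissue at any scan resolution
    r_lo, r_hi = 0.006 * size, 0.016 * size
    mean_area = np.pi * ((r_lo + r_hi) / 2.0) ** 2
    n_blobs = int(0.35 * texture_density * mask.sum() / mean_area)
    ys, xs = np.nonzero(mask)
    if n_blobs and len(ys):
        pick = rng.integers(0, len(ys), n_blobs)
        radii = rng.uniform(r_lo, r_hi, n_blobs)
        yy, xx = np.mgrid[0:size, 0:size]
        for py, px, rad in zip(ys[pick], xs[pick], radii):
            y0, y1 = max(0, int(py - rad - 1)), min(size, int(py + rad + 2))
            x0, x1 = max(0, int(px - rad - 1)), min(size, int(px + rad + 2))
            patch = (yy[y0:y1, x0:x1] - py) ** 2 + \
                (xx[y0:y1, x0:x1] - px) ** 2 <= rad**2
            region = img[y0:y1, x0:x1]
            region[patch & mask[y0:y1, x0:x1]] = accent[None, :]

    # spatially correlated texture modulation: real tissue varies over
    # tens of micrometres, not pixel to pixel, and the mapping fidelity
    # check is only meaningful on resolvable structure
    lowpass = gaussian_filter(rng.normal(0.0, 1.0, (size, size)),
                              sigma=size / 128.0)
    lowpass /= max(lowpass.std(), 1e-9)
    img += 10.0 * lowpass[:, :, None] * np.array([1.0, 0.8, 0.9])
    img += rng.normal(0.0, 1.0, img.shape)

    pad = max(1, int(padding_frac * size))
    img[:pad], img[-pad:] = 8.0, 8.0
    img[:, :pad], img[:, -pad:] = 8.0, 8.0
    mask[:pad], mask[-pad:] = False, False
    mask[:, :pad], mask[:, -pad:] = False, False

    return np.clip(img, 0, 255).astype(np.uint8), TissueMask(mask)


# ---------------------------------------------------------------------------
# hemodynamic fields
# ---------------------------------------------------------------------------

def generate_wss_field(
    mesh: TriangleMesh,
    pattern: str = "gradient",
    seed: int = 0,
    base: float = 1.0,
    amplitude: float = 4.0,
    spot_vertex: int | None = None,
    spot_sigma_mm: float = 1.0,
) -> ScalarField:
    """Smooth positive per-vertex WSS surrogate (Pa).

    ``gradient``: monotone increase along +z from ``base`` to
    ``base + amplitude``.  ``spot``: ``base`` plus a Gaussian bump of
    height ``amplitude`` centered at ``spot_vertex`` (default: the
    topmost vertex).
    """
    rng = np.random.default_rng(seed)
    z = mesh.vertices[:, 2]
    if pattern == "gradient":
        span = np.ptp(z) or 1.0
        values = base + amplitude * (z - z.min()) / span
    elif pattern == "spot":
        if spot_vertex is None:
            spot_vertex = int(np.argmax(z))
        d = np.linalg.norm(mesh.vertices - mesh.vertices[spot_vertex], axis=1)
        values = base + amplitude * np.exp(-0.5 * (d / spot_sigma_mm) ** 2)
    else:
        raise ValueError("pattern must be 'gradient' or 'spot'")
    values = values * (1.0 + rng.normal(0.0, 0.005, len(values)))
    return ScalarField(np.maximum(values, 1e-6), mesh)


# ---------------------------------------------------------------------------
# micro-CT stacks
# ---------------------------------------------------------------------------

def generate_microct_stack(
    dome: TriangleMesh,
    n_slices: int = 8,
    px_per_mm: float = 20.0,
    calcification_spec: list[dict] | None = None,
    seed: int = 0,
    axis_direction=(0.0, 0.0, 1.0),
    wedge_deg: float = 0.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-slice wall masks of the dome plus calcification-blob masks.

    Slices are evenly spaced cross-sections along ``axis_direction``.
    ``calcification_spec`` lists ellipsoidal mineral deposits as dicts
    with ``center`` (mm, 3-vector) and ``radii`` (mm, 3-vector); blobs
    are clipped to the wall so calcification voxels are a subset of wall
    voxels.  ``wedge_deg`` removes an azimuthal sector from every slice
    mask, emulating the cut-open, u-shaped tissue sample.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    d = np.asarray(axis_direction, dtype=np.float64)
    proj = dome.vertices @ d
    span = proj.max() - proj.min()
    offsets = proj.min() + span * (np.arange(n_slices) + 0.5) / n_slices

    wall_masks: list[np.ndarray] = []
    calc_masks: list[np.ndarray] = []
    spec = calcification_spec or []
    for off in offsets:
        sl = slice_mesh_at_plane(dome, float(off), tuple(d), px_per_mm)
        mask = sl.mask.copy()
        if wedge_deg > 0:
            pts = sl.pixel_points()
            centroid = dome.vertices.mean(axis=0)
            rel = pts - centroid[None, None, :]
            ang = np.degrees(np.arctan2(rel[..., 1], rel[..., 0]))
            mask &= ~(np.abs(ang) < wedge_deg / 2.0)
        calc = np.zeros_like(mask)
        if spec:
            pts = sl.pixel_points()
            for blob in spec:
                c = np.asarray(blob["center"], float)
                radii = np.broadcast_to(np.asarray(blob["radii"], float), (3,))
                q = ((pts - c[None, None, :]) / radii[None, None, :]) ** 2
                calc |= q.sum(axis=-1) <= 1.0
            calc &= mask  # deposits live inside the wall
        wall_masks.append(mask)
        calc_masks.append(calc)
    return wall_masks, calc_masks
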