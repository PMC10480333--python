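"""Contour extraction, inner/outer splitting and overlapping sections.

This is the 2D analogue of the mesh-vertex classification: the boundary
of a u-shaped tissue slice is split into *inner* points (visible from
the contour-point centroid without crossing the polygon) and *outer*
points, and both chains are resampled into a fixed number of
overlapping sections — one inner point plus a window of outer points
each — ordered from one tip of the "u" to the other.  Matched sections
of two slices (histology and micro-CT) drive the value transfer in
:mod:`aneuwall.mapping`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.measure import label as cc_label

from .histology import TissueMask

__all__ = [
    "Contour",
    "ContourSplit",
    "SectionSet",
    "extract_contour",
    "split_contour",
    "build_sections",
    "resample_closed",
]

DEFAULT_N_SECTIONS = 5000
DEFAULT_OUTER_PER_SECTION = 50


@dataclass
class Contour:
    """Ordered, closed, simple polygon in pixel coordinates (x, y)."""

    points: np.ndarray  # (N, 2), not repeating the first point

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )


@dataclass
class ContourSplit:
    """A contour with its points partitioned into inner and outer sets."""

    contour: Contour
    center: np.ndarray          # (2,) mean of the contour points
    labels: np.ndarray          # (N,) 0 = inner, 1 = outer

    @property
    def inner_points(self) -> np.ndarray:
        return self.contour.points[self.labels == 0]

    @property
    def outer_points(self) -> np.ndarray:
        return self.contour.points[self.labels == 1]


@dataclass
class SectionSet:
    """``n_sections`` overlapping sections along a split contour.

    ``inner[i]`` is the single inner point of section ``i`` and
    ``outer[i]`` its window of ``outer_per_section`` outer points;
    section 0 and section ``n_sections - 1`` sit at the two tips of the
    u-shaped tissue.
    """

    inner: np.ndarray   # (n_sections, 2)
    outer: np.ndarray   # (n_sections, outer_per_section, 2)

    @property
    def n_sections(self) -> int:
        return len(self.inner)

    @property
    def outer_per_section(self) -> int:
        return self.outer.shape[1]


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------

def extract_contour(mask: TissueMask | np.ndarray, max_points: int = 4000) -> Contour:
    """Trace the closed boundary polygon of the largest foreground
    component, oriented counter-clockwise (signed area > 0) and
    resampled by arc length to at most ``max_points`` vertices."""
    arr = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, bool)
    if not arr.any():
        raise ValueError("cannot extract a contour from an empty mask")
    labeled, n = cc_label(arr, return_num=True)
    if n > 1:
        warnings.warn(f"mask has {n} components; keeping the largest")
        sizes = np.bincount(labeled.ravel())[1:]
        arr = labeled == (int(np.argmax(sizes)) + 1)

    padded = np.pad(arr.astype(float), 1)
    curves = measure.find_contours(padded, 0.5)
    curve = max(curves, key=len) - 1.0      # undo padding
    pts = np.column_stack([curve[:, 1], curve[:, 0]])  # (row,col) -> (x,y)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) > max_points:
        pts = resample_closed(pts, max_points)
    contour = Contour(pts)
    if contour.signed_area < 0:
        contour = Contour(pts[::-1])
    return contour


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points uniform in arc length."""
    pts = np.asarray(points, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0.0, s[-1], n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, y])


def _resample_open(points: np.ndarray, n: int) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(pts[:1], n, axis=0)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, 0]),
                            np.interp(si, s, pts[:, 1])])


# ---------------------------------------------------------------------------
# inner / outer split
# ---------------------------------------------------------------------------

def split_contour(contour: Contour, eps: float = 1e-9) -> ContourSplit:
    """Partition the contour points by visibility from their centroid.

    For each point the segment from the centroid to the point (shrunk by
    ``eps`` at the point end) is intersected with every polygon edge;
    points whose segment crosses no edge are *inner*, the rest *outer*.
    The centroid may lie outside the polygon (u-shapes) — the test still
    applies unchanged.
    """
    pts = contour.points
    n = len(pts)
    center = pts.mean(axis=0)

    p1 = pts                       # edge starts
    p2 = np.roll(pts, -1, axis=0)  # edge ends
    d_edge = p2 - p1

    labels = np.zeros(n, dtype=np.int64)
    shrink = 1.0 - 1e-7
    chunk = 512
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        targets = center + shrink * (pts[lo:hi] - center)  # (m, 2)
        d_seg = targets - center                           # (m, 2)
        if not np.any(np.linalg.norm(d_seg, axis=1) > eps):
            continue
        # segment: center + t * d_seg, t in [0,1]
        # edge:    p1 + u * d_edge,   u in [0,1]
        denom = d_seg[:, None, 0] * d_edge[None, :, 1] - \
                d_seg[:, None, 1] * d_edge[None, :, 0]     # (m, N)
        diff = p1[None, :, :] - center[None, None, :]       # (1, N, 2)
        t_num = diff[:, :, 0] * d_edge[None, :, 1] - \
                diff[:, :, 1] * d_edge[None, :, 0]
        u_num = diff[:, :, 0] * d_seg[:, None, 1] - \
                diff[:, :, 1] * d_seg[:, None, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = t_num / denom
            u = u_num / denom
        hits = (
            (np.abs(denom) > eps)
            & (t > eps) & (t < 1.0 - eps)
            & (u >= -eps) & (u <= 1.0 + eps)
        )
        # half-open edge rule: count u == 1 endpoints on the next edge only
        hits &= u < 1.0 - eps
        labels[lo:hi] = np.where(hits.any(axis=1), 1, 0)
    return ContourSplit(contour=contour, center=center, labels=labels)


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

def _circular_runs(labels: np.ndarray, value: int) -> list[np.ndarray]:
    """Maximal circular runs of indices where labels == value."""
    n = len(labels)
    idx = np.flatnonzero(labels == value)
    if idx.size == 0:
        return []
    if idx.size == n:
        return [idx]
    runs: list[list[int]] = []
    in_run = False
    # start scanning just after a non-value position so runs never wrap
    start = int(np.flatnonzero(labels != value)[0])
    order = [(start + k) % n for k in range(1, n + 1)]
    for i in order:
        if labels[i] == value:
            if not in_run:
                runs.append([])
                in_run = True
            runs[-1].append(i)
        else:
            in_run = False
    return [np.asarray(r) for r in runs]


def build_sections(
    split: ContourSplit,
    n_sections: int = DEFAULT_N_SECTIONS,
    outer_per_section: int = DEFAULT_OUTER_PER_SECTION,
) -> SectionSet:
    """Build ``n_sections`` overlapping sections from a contour split.

    The inner and outer chains (longest circular runs of each label) are
    resampled uniformly in arc length to ``n_sections`` positions; the
    chains are co-oriented so both start at the same tissue tip, and
    section ``i`` pairs inner sample ``i`` with the window of
    ``outer_per_section`` arc-length-nearest outer samples.  The first
    and last sections therefore sit at the two u-ends, where the
    inner-to-outer distance is minimal.
    """
    labels = split.labels
    inner_runs = _circular_runs(labels, 0)
    outer_runs = _circular_runs(labels, 1)
    if not inner_runs:
        raise ValueError("contour split has no inner points")
    if not outer_runs:
        raise ValueError("contour split has no outer points")
    if len(inner_runs) > 1 or len(outer_runs) > 1:
        warnings.warn(
            "fragmented inner/outer runs; using the longest of each"
        )
    inner_idx = max(inner_runs, key=len)
    outer_idx = max(outer_runs, key=len)
    if len(outer_idx) < outer_per_section:
        raise ValueError(
            f"only {len(outer_idx)} outer points, need >= {outer_per_section}"
        )

    pts = split.contour.points
    inner_chain = pts[inner_idx]
    outer_chain = pts[outer_idx]

    # co-orient the chains: both must start at the same u-end
    d_keep = np.linalg.norm(inner_chain[0] - outer_chain[0])
    d_flip = np.linalg.norm(inner_chain[0] - outer_chain[-1])
    if d_flip < d_keep:
        outer_chain = outer_chain[::-1]

    inner_s = _resample_open(inner_chain, n_sections)
    outer_s = _resample_open(outer_chain, n_sections)

    half = outer_per_section // 2
    starts = np.clip(
        np.arange(n_sections) - half, 0, max(0, n_sections - outer_per_section)
    )
    window = starts[:, None] + np.arange(outer_per_section)[None, :]
    return SectionSet(inner=inner_s, outer=outer_s[window])
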