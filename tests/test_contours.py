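"""Contour extraction, inner/outer splitting, section construction."""

import numpy as np
import pytest
import shapely.geometry as geom

from aneuwall.contours import (
    Contour,
    build_sections,
    extract_contour,
    resample_closed,
    split_contour,
)
from aneuwall.synthetic import UShapeParams, generate_histology_image


def u_polygon(n=300, r_mid=100.0, half_w=25.0, opening_deg=100.0,
              cx=0.0, cy=0.0, n_cap=8):
    """Analytic u-band polygon (outer arc, flat tip cap, inner arc, flat
    tip cap), counter-clockwise, with intermediate points on the caps
    as a pixel-traced contour would have."""
    half = np.radians(opening_deg / 2.0)
    # image-style convention: y grows downward, gap centered on "up"
    ang = np.linspace(np.pi / 2 + half, 2.5 * np.pi - half, n // 2)
    outer = np.column_stack([cx + (r_mid + half_w) * np.cos(ang),
                             cy - (r_mid + half_w) * np.sin(ang)])
    inner = np.column_stack([cx + (r_mid - half_w) * np.cos(ang[::-1]),
                             cy - (r_mid - half_w) * np.sin(ang[::-1])])
    t = np.linspace(0.0, 1.0, n_cap + 2)[1:-1, None]
    cap_b = outer[-1] + t * (inner[0] - outer[-1])
    cap_a = inner[-1] + t * (outer[0] - inner[-1])
    pts = np.vstack([outer, cap_b, inner, cap_a])
    c = Contour(pts)
    return c if c.signed_area > 0 else Contour(pts[::-1])


def split_oracle(contour):
    """Brute-force oracle with shapely: count boundary crossings of each
    center-to-point segment (the point itself excluded by shrinking)."""
    pts = contour.points
    center = pts.mean(axis=0)
    ring = geom.LinearRing(np.vstack([pts, pts[:1]]))
    labels = np.zeros(len(pts), dtype=int)
    for i, p in enumerate(pts):
        end = center + (1.0 - 1e-7) * (p - center)
        seg = geom.LineString([center, end])
        inter = seg.intersection(ring)
        if inter.is_empty:
            labels[i] = 0
        else:
            labels[i] = 1
    return labels


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_disk_contour_lies_on_the_circle():
    yy, xx = np.mgrid[0:128, 0:128]
    mask = (xx - 64) ** 2 + (yy - 64) ** 2 <= 50**2
    contour = extract_contour(mask)
    r = np.hypot(contour.points[:, 0] - 64, contour.points[:, 1] - 64)
    assert np.all(np.abs(r - 50) <= 1.5)
    assert contour.signed_area > 0


def test_u_mask_gives_single_simple_polygon(histo_mt):
    _, mask = histo_mt
    contour = extract_contour(mask)
    poly = geom.Polygon(contour.points)
    assert poly.is_valid and poly.is_simple


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        extract_contour(np.zeros((32, 32), bool))


def test_largest_component_kept_with_warning():
    mask = np.zeros((64, 64), bool)
    mask[10:40, 10:40] = True
    mask[50:54, 50:54] = True
    with pytest.warns(UserWarning, match="largest"):
        contour = extract_contour(mask)
    assert contour.points[:, 0].max() < 45


def test_resample_preserves_shape():
    circle = u_polygon(n=400)
    res = resample_closed(circle.points, 100)
    assert len(res) == 100
    # resampled points stay on the original polygon (within a step)
    poly = geom.LinearRing(np.vstack([circle.points, circle.points[:1]]))
    d = [geom.Point(p).distance(poly) for p in res]
    assert max(d) < 1.0


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_convex_contour_is_all_inner():
    ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    circle = Contour(np.column_stack([np.cos(ang), np.sin(ang)]) * 40 + 100)
    split = split_contour(circle)
    assert np.all(split.labels == 0)
    assert np.allclose(split.center, [100, 100], atol=1e-6)


def test_u_shape_split_matches_brute_force_oracle():
    contour = u_polygon(n=300)
    split = split_contour(contour)
    assert np.array_equal(split.labels, split_oracle(contour))
    # and both classes are present with the concave arc inner
    assert 0 < (split.labels == 0).sum() < len(contour)


def test_mask_derived_split_matches_oracle(histo_mt):
    _, mask = histo_mt
    contour = extract_contour(mask, max_points=500)
    split = split_contour(contour)
    assert np.mean(split.labels == split_oracle(contour)) == 1.0


def test_symmetric_u_center_on_symmetry_axis():
    contour = u_polygon(n=200, cx=77.0)
    split = split_contour(contour)
    assert split.center[0] == pytest.approx(77.0, abs=1e-6)


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

def test_default_sectioning_contract(histo_mt):
    _, mask = histo_mt
    split = split_contour(extract_contour(mask))
    sections = build_sections(split)
    assert sections.n_sections == 5000
    assert sections.inner.shape == (5000, 2)
    assert sections.outer.shape == (5000, 50, 2)


def test_first_and_last_sections_sit_at_the_u_tips():
    contour = u_polygon(n=600)
    sections = build_sections(split_contour(contour), 1000, 50)
    d = np.linalg.norm(sections.outer - sections.inner[:, None, :], axis=2)
    per_section = d.min(axis=1)
    # minimum inner-outer distance occurs at the chain ends
    assert per_section[0] <= np.percentile(per_section, 10)
    assert per_section[-1] <= np.percentile(per_section, 10)
    # consecutive sections share outer points (overlap)
    shared = {tuple(p) for p in sections.outer[10]} & \
        {tuple(p) for p in sections.outer[11]}
    assert len(shared) >= 40


def test_too_few_outer_points_rejected():
    contour = u_polygon(n=60)
    split = split_contour(contour)
    n_outer = int((split.labels == 1).sum())
    with pytest.raises(ValueError):
        build_sections(split, 100, n_outer + 1)
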