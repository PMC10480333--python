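import numpy as np
import pytest

from aneuwall.synthetic import (
    generate_dome_phantom,
    generate_histology_image,
    spherical_shell,
)


@pytest.fixture(scope="session")
def dome_phantom():
    """Standard deflated-dome phantom: 5 mm outer radius, 0.5 mm wall,
    deflation factor 0.8."""
    return generate_dome_phantom(seed=1)


@pytest.fixture(scope="session")
def small_dome_phantom():
    """Coarse phantom for brute-force oracle comparisons."""
    return generate_dome_phantom(mesh_resolution=8, seed=2)


@pytest.fixture(scope="session")
def shell_4_5():
    """Concentric spherical shell, radii 4 and 5 mm, aligned grids."""
    return spherical_shell(4.0, 5.0)


@pytest.fixture(scope="session")
def histo_mt():
    """One u-shaped MT-stained phantom slide with its exact mask."""
    return generate_histology_image("MT", size=512, seed=7)


def winding_numbers(points, vertices, faces):
    """Independent inside/outside oracle: generalized winding number via
    the van Oosterom-Strackee signed solid angle, summed per triangle.
    ~1 inside a watertight mesh, ~0 outside."""
    pts = np.atleast_2d(points)
    tri = np.asarray(vertices)[np.asarray(faces)]
    w = np.zeros(len(pts))
    chunk = 256
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("ptj,ptj->pt", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ptj,ptj->pt", a, b) * lc
            + np.einsum("ptj,ptj->pt", b, c) * la
            + np.einsum("ptj,ptj->pt", a, c) * lb
        )
        w[lo : lo + chunk] = np.arctan2(num, den).sum(axis=1) / (2 * np.pi)
    return w
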