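"""Shared fixtures and independent brute-force oracles.

The ray-sum oracles re-derive the projector's output with plain Python loops
(one pixel at a time) so that the vectorized sparse-matrix implementation is
checked against an independently written route.
"""

import math

import numpy as np
import pytest

from offsetspect import ImageGrid, make_multicylinder_phantom, make_resolution_phantom, make_sdb_phantom


def raysum_oracle(values, pixel_mm, angles_deg, n_bins, bin_mm, footprint="strip"):
    """Brute-force pixel-driven ray sums (point splat or square-pixel strip)."""
    n = values.shape[0]
    c = (n - 1) / 2.0
    cb = (n_bins - 1) / 2.0
    support_radius = ((n_bins - 1) / 2.0 - 1.0) * bin_mm
    out = np.zeros((len(angles_deg), n_bins))
    for a, ang in enumerate(angles_deg):
        th = math.radians(ang)
        cos, sin = math.cos(th), math.sin(th)
        for r in range(n):
            for col in range(n):
                v = values[r, col]
                if v == 0:
                    continue
                x = (col - c) * pixel_mm
                y = (c - r) * pixel_mm
                if x * x + y * y > support_radius**2:
                    continue
                t = x * cos + y * sin
                if footprint == "point":
                    u = t / bin_mm + cb
                    b0 = math.floor(u)
                    w1 = u - b0
                    for b, w in ((b0, 1.0 - w1), (b0 + 1, w1)):
                        if 0 <= b < n_bins:
                            out[a, b] += v * w
                else:
                    w = pixel_mm * (abs(cos) + abs(sin))
                    lo, hi = t - w / 2.0, t + w / 2.0
                    b_lo = math.floor(lo / bin_mm + cb + 0.5)
                    b_hi = math.floor(hi / bin_mm + cb + 0.5)
                    for b in range(b_lo, b_hi + 1):
                        edge_lo = (b - cb - 0.5) * bin_mm
                        edge_hi = (b - cb + 0.5) * bin_mm
                        overlap = min(hi, edge_hi) - max(lo, edge_lo)
                        if overlap > 0 and 0 <= b < n_bins:
                            out[a, b] += v * overlap / w
    return out


@pytest.fixture(scope="session")
def oracle():
    return raysum_oracle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def resolution_phantom():
    return make_resolution_phantom()


@pytest.fixture(scope="session")
def multicylinder_phantom():
    return make_multicylinder_phantom()


@pytest.fixture(scope="session")
def sdb_phantom():
    return make_sdb_phantom()


def gaussian_blob(sigma_mm, pixel_mm, size, center_mm=(0.0, 0.0), amplitude=100.0, offset=0.0):
    """Analytic isotropic Gaussian rendered on a grid (for FWHM calibration)."""
    c = (size - 1) / 2.0
    x = (np.arange(size) - c) * pixel_mm
    y = (c - np.arange(size)) * pixel_mm
    X, Y = np.meshgrid(x, y)
    g = amplitude * np.exp(-(((X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2) / (2 * sigma_mm**2)))
    return ImageGrid(g + offset, pixel_mm)


@pytest.fixture(scope="session")
def blob_factory():
    return gaussian_blob
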