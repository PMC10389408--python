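"""Shared fixtures and independent oracles for the test suite.

The geometry oracles here (fan triangulation, explicit edge summation) are
deliberately written in the most naive way possible so they stay independent
of the package's shoelace/vectorised implementations.
"""

import math

import numpy as np
import pytest


def fan_triangulation_area(vertices) -> float:
    """Polygon area as the absolute sum of signed fan-triangle areas."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(1, len(v) - 1):
        ax, ay = v[0]
        bx, by = v[i]
        cx, cy = v[i + 1]
        total += 0.5 * ((bx - ax) * (cy - ay) - (cx - ax) * (by - ay))
    return abs(total)


def edge_sum_perimeter(vertices) -> float:
    """Perimeter by explicit pairwise edge lengths, closing edge included."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(len(v)):
        j = (i + 1) % len(v)
        total += math.hypot(v[j][0] - v[i][0], v[j][1] - v[i][1])
    return total


def random_star_polygon(rng, n_min=5, n_max=40, r_min=0.5, r_max=10.0):
    """Random simple polygon: strictly increasing angles guarantee simplicity."""
    n = int(rng.integers(n_min, n_max + 1))
    # jittered regular grid: strictly increasing, every gap < pi, so the
    # polygon is star-shaped about the centre and therefore simple
    spacing = 2 * np.pi / n
    angles = spacing * (np.arange(n) + rng.uniform(-0.45, 0.45, n))
    radii = rng.uniform(r_min, r_max, n)
    center = rng.uniform(-50, 50, 2)
    return center + np.column_stack(
        [radii * np.cos(angles), radii * np.sin(angles)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def star_polygon_factory():
    return random_star_polygon
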