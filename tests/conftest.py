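"""Shared fixtures and independent geometric oracles.

The oracles here (shoelace area, all-pairs caliper, brute-force convex hull
via scipy) are deliberately independent of the shapely-based production
path so that geometry tests are genuine cross-checks.
"""

import numpy as np
import pytest
from scipy.spatial import ConvexHull


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed-area shoelace formula, returned as a magnitude."""
    x, y = vertices[:, 0], vertices[:, 1]
    return abs(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def hull_area_oracle(vertices: np.ndarray) -> float:
    """Convex-hull area via scipy's qhull (volume attribute in 2-D)."""
    return ConvexHull(vertices).volume


def depression_oracle(vertices: np.ndarray) -> float:
    """Concavity percentage computed entirely from the oracles above."""
    hull = hull_area_oracle(vertices)
    return 100.0 * (hull - shoelace_area(vertices)) / hull


def caliper_oracle(vertices: np.ndarray) -> float:
    """Maximum Feret diameter by brute-force all-pairs distance."""
    d2 = np.sum((vertices[:, None, :] - vertices[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def square_contour(side: float = 10.0, pts_per_edge: int = 20) -> np.ndarray:
    """Axis-aligned square densified to satisfy the 64-vertex minimum."""
    t = np.linspace(0.0, side, pts_per_edge, endpoint=False)
    bottom = np.column_stack([t, np.zeros_like(t)])
    right = np.column_stack([np.full_like(t, side), t])
    top = np.column_stack([side - t, np.full_like(t, side)])
    left = np.column_stack([np.zeros_like(t), side - t])
    return np.vstack([bottom, right, top, left])


def notched_square_contour(notch_area: float = 5.0) -> np.ndarray:
    """10x10 square with an inward triangular notch of known area.

    The notch has its base (width 2) on the bottom edge centred at x = 5 and
    an apex reaching up by ``notch_area`` (area = base x height / 2
    = 2 x h / 2 = h).
    """
    h = notch_area
    t = np.linspace(0.0, 10.0, 20, endpoint=False)
    right = np.column_stack([np.full_like(t, 10.0), t])
    top = np.column_stack([10.0 - t, np.full_like(t, 10.0)])
    left = np.column_stack([np.zeros_like(t), 10.0 - t])
    bottom = [
        [0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0], [4.0, 0.0],
        [5.0, h],  # notch apex
        [6.0, 0.0], [7.0, 0.0], [8.0, 0.0], [9.0, 0.0],
    ]
    return np.vstack([np.asarray(bottom), right, top, left])


@pytest.fixture()
def rng():
    # fresh generator per test: results never depend on execution order
    return np.random.default_rng(20260925)
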