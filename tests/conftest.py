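import numpy as np
import pandas as pd
import pytest

from immunogradient.hexgrid import (
    STROMA,
    TUMOR,
    TissueMap,
    assign_cells,
    build_hex_grid,
    compute_area_fractions,
)
from immunogradient.interface import classify_hexagons, detect_tumor_edge, rank_hexagons


def make_half_plane_map(n=200, pixel_size_um=4.0):
    """Left half tumor, right half stroma."""
    labels = np.full((n, n), STROMA, dtype=np.uint8)
    labels[:, : n // 2] = TUMOR
    return TissueMap(labels=labels, pixel_size_um=pixel_size_um)


def make_blob_map(rng, n=160, pixel_size_um=4.0):
    """Random star-shaped tumor blob in stroma."""
    labels = np.full((n, n), STROMA, dtype=np.uint8)
    cy = cx = n / 2.0
    base = rng.uniform(0.2, 0.32) * n
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    r = base * (1 + 0.25 * np.sin(rng.integers(2, 6) * theta + rng.uniform(0, 6)))
    yy, xx = np.mgrid[:n, :n]
    rho = np.hypot(xx - cx, yy - cy)
    ang = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    labels[rho <= np.interp(ang, theta, r, period=2 * np.pi)] = TUMOR
    return TissueMap(labels=labels, pixel_size_um=pixel_size_um)


def ranked_grid_from_map(tmap, hex_side_um=40.0):
    grid = build_hex_grid(tmap, hex_side_um)
    compute_area_fractions(grid, tmap)
    assign_cells(grid, pd.DataFrame(columns=["marker", "x_um", "y_um"]), tmap)
    return rank_hexagons(detect_tumor_edge(classify_hexagons(grid)))


@pytest.fixture
def half_plane_map():
    return make_half_plane_map()


@pytest.fixture
def half_plane_ranked(half_plane_map):
    return ranked_grid_from_map(half_plane_map)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
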