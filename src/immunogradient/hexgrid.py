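"""Hexagonal sampling lattice over a tissue-class raster.

The lattice uses axial coordinates (q, r). For the default pointy-top
orientation the center of hexagon (q, r) with side (circumradius) ``s`` is

    x = s * sqrt(3) * (q + r / 2),    y = s * 3/2 * r

and for flat-top

    x = s * 3/2 * q,                  y = s * sqrt(3) * (r + q / 2).

All coordinates are micrometres, origin at the raster top-left, x rightward,
y downward. A pixel (or cell) belongs to the hexagon whose center is nearest
in Euclidean distance — the Voronoi cell of the hexagonal lattice is exactly
the hexagon — with boundary ties broken toward the lexicographically lowest
(q, r).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .errors import (
    EmptyInputError,
    GeometryError,
    InvalidResolutionError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

# Tissue-class label codes of the input raster.
BACKGROUND, TUMOR, STROMA, FOLLICLE = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", TUMOR: "tumor", STROMA: "stroma", FOLLICLE: "follicle"}
MARKERS = ("CD8", "CD20", "CD68")

SQRT3 = np.sqrt(3.0)

# Candidate offsets for nearest-center refinement: the axially rounded
# hexagon plus its six lattice neighbours.
_NEIGHBOR_OFFSETS = ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))
AXIAL_NEIGHBORS = _NEIGHBOR_OFFSETS[1:]


@dataclass
class TissueMap:
    """Labeled tissue raster with physical pixel size.

    ``labels`` holds integer classes (0 background, 1 tumor, 2 stroma,
    3 lymphoid follicle); ``pixel_size_um`` is the side of a square pixel.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise EmptyInputError("tissue raster must be a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel_size_um must be positive")
        bad = np.setdiff1d(np.unique(self.labels), list(CLASS_NAMES))
        if bad.size:
            raise VocabularyError(f"unknown tissue labels {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the raster in micrometres."""
        h, w = self.labels.shape
        return w * self.pixel_size_um, h * self.pixel_size_um

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2

    def class_area_mm2(self, label: int) -> float:
        return int(np.count_nonzero(self.labels == label)) * self.pixel_area_mm2


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table (columns marker, x_um, y_um; case_id optional)."""
    required = {"marker", "x_um", "y_um"}
    missing = required - set(cells.columns)
    if missing:
        raise VocabularyError(f"cell table missing columns {sorted(missing)}")
    bad = cells.loc[~cells["marker"].isin(MARKERS)]
    if len(bad):
        raise VocabularyError(
            f"unknown marker values {sorted(bad['marker'].unique())} "
            f"in rows {bad.index.tolist()[:20]}"
        )
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    if not np.all(np.isfinite(xy)):
        raise VocabularyError("cell coordinates must be finite")
    return cells


def axial_to_cartesian(q, r, hex_side_um: float, orientation: str = "pointy"):
    """Closed-form hexagon-center coordinates from axial indices."""
    q = np.asarray(q, float)
    r = np.asarray(r, float)
    s = hex_side_um
    if orientation == "pointy":
        return s * SQRT3 * (q + r / 2.0), s * 1.5 * r
    return s * 1.5 * q, s * SQRT3 * (r + q / 2.0)


def _cartesian_to_fractional_axial(x, y, hex_side_um: float, orientation: str):
    s = hex_side_um
    if orientation == "pointy":
        return (SQRT3 / 3.0 * x - y / 3.0) / s, (2.0 / 3.0 * y) / s
    return (2.0 / 3.0 * x) / s, (-x / 3.0 + SQRT3 / 3.0 * y) / s


def _axial_round(qf, rf):
    """Round fractional axial coordinates to the nearest hexagon (cube rounding)."""
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)


def assign_points_to_hexagons(
    x, y, hex_side_um: float, orientation: str = "pointy"
) -> tuple[np.ndarray, np.ndarray]:
    """Map points (um) to the axial index of the nearest hexagon center.

    Cube rounding already yields the nearest center almost everywhere; the
    seven-candidate refinement makes the boundary tie-break explicit:
    smallest distance, then lowest (q, r).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    qf, rf = _cartesian_to_fractional_axial(x, y, hex_side_um, orientation)
    q0, r0 = _axial_round(qf, rf)

    tol = 1e-9 * hex_side_um**2
    best_d = np.full(x.shape, np.inf)
    best_q = np.zeros_like(q0)
    best_r = np.zeros_like(r0)
    for dq, dr in _NEIGHBOR_OFFSETS:
        q = q0 + dq
        r = r0 + dr
        cx, cy = axial_to_cartesian(q, r, hex_side_um, orientation)
        d = (x - cx) ** 2 + (y - cy) ** 2
        closer = d < best_d - tol
        tied_lower = (np.abs(d - best_d) <= tol) & (
            (q < best_q) | ((q == best_q) & (r < best_r))
        )
        take = closer | tied_lower
        best_d = np.where(take, d, best_d)
        best_q = np.where(take, q, best_q)
        best_r = np.where(take, r, best_r)
    return best_q, best_r


def hexagon_polygon(q: int, r: int, hex_side_um: float, orientation: str = "pointy"):
    """Shapely polygon of hexagon (q, r)."""
    cx, cy = axial_to_cartesian(q, r, hex_side_um, orientation)
    start = 30.0 if orientation == "pointy" else 0.0
    ang = np.deg2rad(start + 60.0 * np.arange(6))
    return shapely.Polygon(np.column_stack([cx + hex_side_um * np.cos(ang),
                                            cy + hex_side_um * np.sin(ang)]))


@dataclass
class HexGrid:
    """Hexagon lattice over a raster with per-hexagon areas and counts.

    ``table`` has one row per hexagon: axial (q, r), center coordinates, the
    four class areas in mm^2 (filled by :func:`compute_area_fractions`) and
    per-marker cell counts (filled by :func:`assign_cells`).
    """

    hex_side_um: float
    orientation: str
    table: pd.DataFrame
    raster_shape: tuple[int, int]
    pixel_size_um: float
    n_cells_dropped_out_of_bounds: int = 0
    n_cells_dropped_in_follicle: int = 0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {
            (int(q), int(r)): i
            for i, (q, r) in enumerate(zip(self.table["q"], self.table["r"]))
        }

    def __len__(self) -> int:
        return len(self.table)

    def row_of(self, q: int, r: int) -> int | None:
        return self._index.get((q, r))

    @property
    def has_areas(self) -> bool:
        return "area_tumor_mm2" in self.table.columns

    @property
    def has_counts(self) -> bool:
        return "n_cd8" in self.table.columns

    def tissue_area_mm2(self) -> np.ndarray:
        """Per-hexagon analyzed-tissue (tumor + stroma) area."""
        return (self.table["area_tumor_mm2"] + self.table["area_stroma_mm2"]).to_numpy()

    def total_tumor_area_mm2(self) -> float:
        return float(self.table["area_tumor_mm2"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_hex_grid(
    tissue_map: TissueMap, hex_side_um: float, orientation: str = "pointy"
) -> HexGrid:
    """Construct the hexagon lattice covering the raster bounding box.

    Returns every hexagon whose polygon intersects the raster rectangle.
    """
    if orientation not in ("pointy", "flat"):
        raise VocabularyError(f"unknown orientation {orientation!r}")
    if hex_side_um < 2 * tissue_map.pixel_size_um:
        raise InvalidResolutionError(
            f"hex_side_um={hex_side_um} is below twice the pixel size "
            f"({tissue_map.pixel_size_um} um)"
        )
    width, height = tissue_map.extent_um

    # Candidate axial range: axial indices of the rectangle corners +- margin.
    corners_x = np.array([0.0, width, 0.0, width])
    corners_y = np.array([0.0, 0.0, height, height])
    qf, rf = _cartesian_to_fractional_axial(corners_x, corners_y, hex_side_um, orientation)
    q_lo, q_hi = int(np.floor(qf.min())) - 2, int(np.ceil(qf.max())) + 2
    r_lo, r_hi = int(np.floor(rf.min())) - 2, int(np.ceil(rf.max())) + 2

    qq, rr = np.meshgrid(np.arange(q_lo, q_hi + 1), np.arange(r_lo, r_hi + 1), indexing="ij")
    qq = qq.ravel()
    rr = rr.ravel()
    cx, cy = axial_to_cartesian(qq, rr, hex_side_um, orientation)
    # Cheap prefilter: centers farther than the circumradius from the
    # rectangle cannot intersect it.
    dx = np.maximum(np.maximum(0.0 - cx, cx - width), 0.0)
    dy = np.maximum(np.maximum(0.0 - cy, cy - height), 0.0)
    near = dx**2 + dy**2 <= hex_side_um**2 + 1e-9
    qq, rr, cx, cy = qq[near], rr[near], cx[near], cy[near]

    box = shapely.box(0.0, 0.0, width, height)
    keep = np.fromiter(
        (
            hexagon_polygon(q, r, hex_side_um, orientation).intersects(box)
            for q, r in zip(qq, rr)
        ),
        dtype=bool,
        count=len(qq),
    )
    qq, rr, cx, cy = qq[keep], rr[keep], cx[keep], cy[keep]
    order = np.lexsort((rr, qq))
    table = pd.DataFrame(
        {
            "q": qq[order],
            "r": rr[order],
            "center_x_um": cx[order],
            "center_y_um": cy[order],
        }
    )
    return HexGrid(
        hex_side_um=hex_side_um,
        orientation=orientation,
        table=table,
        raster_shape=tissue_map.shape,
        pixel_size_um=tissue_map.pixel_size_um,
    )


def _hexagon_index_lookup(grid: HexGrid, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized (q, r) -> row index; -1 where the hexagon is not in the grid."""
    q_min, q_max = int(grid.table["q"].min()), int(grid.table["q"].max())
    r_min, r_max = int(grid.table["r"].min()), int(grid.table["r"].max())
    lut = np.full((q_max - q_min + 1, r_max - r_min + 1), -1, dtype=np.int64)
    lut[grid.table["q"].to_numpy() - q_min, grid.table["r"].to_numpy() - r_min] = np.arange(
        len(grid)
    )
    qi = q - q_min
    ri = r - r_min
    inside = (qi >= 0) & (qi < lut.shape[0]) & (ri >= 0) & (ri < lut.shape[1])
    out = np.full(q.shape, -1, dtype=np.int64)
    out[inside] = lut[qi[inside], ri[inside]]
    return out


def compute_area_fractions(grid: HexGrid, tissue_map: TissueMap) -> HexGrid:
    """Fill per-hexagon tissue-class areas by pixel counting.

    A pixel belongs to the hexagon containing its center, so class areas are
    conserved exactly: summed over hexagons they equal the raster class areas.
    """
    if grid.raster_shape != tissue_map.shape or grid.pixel_size_um != tissue_map.pixel_size_um:
        raise GeometryError("grid was built over a different raster")
    h, w = tissue_map.shape
    px = tissue_map.pixel_size_um
    # Pixel centers.
    xs = (np.arange(w) + 0.5) * px
    ys = (np.arange(h) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    q, r = assign_points_to_hexagons(gx.ravel(), gy.ravel(), grid.hex_side_um, grid.orientation)
    idx = _hexagon_index_lookup(grid, q, r)
    if np.any(idx < 0):
        raise GeometryError("pixel mapped outside the hexagon lattice")
    labels = tissue_map.labels.ravel()
    pixel_area = tissue_map.pixel_area_mm2
    for label, name in ((TUMOR, "tumor"), (STROMA, "stroma"), (FOLLICLE, "follicle"), (BACKGROUND, "background")):
        counts = np.bincount(idx[labels == label], minlength=len(grid))
        grid.table[f"area_{name}_mm2"] = counts * pixel_area
    return grid


def assign_cells(
    grid: HexGrid,
    cells: pd.DataFrame,
    tissue_map: TissueMap | None = None,
    exclude_follicle_cells: bool = True,
) -> HexGrid:
    """Count marker cells per hexagon.

    Cells outside the raster rectangle are dropped (logged). When
    ``exclude_follicle_cells`` and a tissue map are given, cells lying on
    lymphoid-follicle pixels are dropped as well, so follicular aggregates do
    not contaminate microenvironment densities.
    """
    cells = validate_cell_table(cells)
    w_um = grid.raster_shape[1] * grid.pixel_size_um
    h_um = grid.raster_shape[0] * grid.pixel_size_um
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    in_bounds = (x >= 0) & (x < w_um) & (y >= 0) & (y < h_um)
    grid.n_cells_dropped_out_of_bounds = int((~in_bounds).sum())
    if grid.n_cells_dropped_out_of_bounds:
        logger.info("dropped %d cells outside raster bounds", grid.n_cells_dropped_out_of_bounds)

    keep = in_bounds.copy()
    if exclude_follicle_cells and tissue_map is not None:
        col = np.clip((x / grid.pixel_size_um).astype(int), 0, grid.raster_shape[1] - 1)
        row = np.clip((y / grid.pixel_size_um).astype(int), 0, grid.raster_shape[0] - 1)
        in_follicle = tissue_map.labels[row, col] == FOLLICLE
        grid.n_cells_dropped_in_follicle = int((in_bounds & in_follicle).sum())
        keep &= ~in_follicle
        if grid.n_cells_dropped_in_follicle:
            logger.info(
                "dropped %d cells inside lymphoid follicles", grid.n_cells_dropped_in_follicle
            )

    q, r = assign_points_to_hexagons(x[keep], y[keep], grid.hex_side_um, grid.orientation)
    idx = _hexagon_index_lookup(grid, q, r)
    if np.any(idx < 0):
        raise GeometryError("in-bounds cell mapped outside the hexagon lattice")
    marker = cells["marker"].to_numpy()[keep]
    for m in MARKERS:
        counts = np.bincount(idx[marker == m], minlength=len(grid))
        grid.table[f"n_{m.lower()}"] = counts.astype(np.int64)
    return grid
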