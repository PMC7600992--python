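"""Tumor-edge detection, signed hexagon ranking and interface-zone extraction.

The tumor edge (TE) is the set of hexagons at the tumor/stroma transition:
mixed-content hexagons (both classes hold at least a threshold fraction of
the analyzed tissue) plus tumor hexagons with at least one stroma lattice
neighbour, so that a razor-sharp inter-hexagon boundary still yields a TE
band. Every other tissue hexagon receives a signed rank: +d for tumor
hexagons at lattice distance d from the nearest TE hexagon, -d on the
stromal side. Distance is hexagon-lattice graph distance (multi-source BFS
over the 6-neighbourhood); background hexagons block traversal by default.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoInterfaceError, ParameterError
from .hexgrid import AXIAL_NEIGHBORS, HexGrid

TUMOR_CLASS = "tumor"
STROMA_CLASS = "stroma"
EDGE_CLASS = "edge"
BACKGROUND_CLASS = "background"


@dataclass
class RankedGrid:
    """HexGrid augmented with base class, signed rank and TE membership."""

    grid: HexGrid
    table: pd.DataFrame  # grid.table + base_class, rank (float, NaN=undefined), is_te

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class InterfaceZone:
    """Band of hexagons with |rank| <= (width - 1) / 2.

    ``aspect`` is "S" (stroma side, rank < 0), "TE" (rank 0) or "T"
    (tumor side, rank > 0).
    """

    width: int
    table: pd.DataFrame  # member hexagons with an extra "aspect" column

    @property
    def ranks(self) -> np.ndarray:
        return np.sort(self.table["rank"].unique().astype(int))


def classify_hexagons(
    grid: HexGrid,
    mixed_fraction_threshold: float = 0.1,
    background_threshold: float = 0.05,
) -> RankedGrid:
    """Assign a base class to every hexagon from its tissue-area fractions.

    A hexagon is background when tumor + stroma make up less than
    ``background_threshold`` of its total area; an edge candidate when both
    tumor and stroma reach ``mixed_fraction_threshold`` of the analyzed
    tissue; otherwise it takes the majority class of the analyzed tissue
    (ties resolved to tumor).
    """
    if not 0 < mixed_fraction_threshold <= 0.5:
        raise ParameterError("mixed_fraction_threshold must lie in (0, 0.5]")
    if not grid.has_areas:
        raise ParameterError("area fractions must be computed before classification")
    t = grid.table
    tumor = t["area_tumor_mm2"].to_numpy()
    stroma = t["area_stroma_mm2"].to_numpy()
    total = (
        tumor
        + stroma
        + t["area_follicle_mm2"].to_numpy()
        + t["area_background_mm2"].to_numpy()
    )
    tissue = tumor + stroma
    with np.errstate(invalid="ignore", divide="ignore"):
        tissue_frac = np.where(total > 0, tissue / total, 0.0)
        tumor_frac = np.where(tissue > 0, tumor / tissue, 0.0)
        stroma_frac = np.where(tissue > 0, stroma / tissue, 0.0)

    base = np.where(tumor >= stroma, TUMOR_CLASS, STROMA_CLASS)
    mixed = (tumor_frac >= mixed_fraction_threshold) & (stroma_frac >= mixed_fraction_threshold)
    base = np.where(mixed, EDGE_CLASS, base)
    base = np.where(tissue_frac < background_threshold, BACKGROUND_CLASS, base)

    table = t.copy()
    table["base_class"] = base
    table["rank"] = np.nan
    table["is_te"] = False
    return RankedGrid(grid=grid, table=table)


def detect_tumor_edge(classified: RankedGrid) -> RankedGrid:
    """Mark TE hexagons: edge candidates plus tumor hexagons touching stroma."""
    table = classified.table
    base = table["base_class"].to_numpy()
    grid = classified.grid

    is_te = base == EDGE_CLASS
    # Tumor hexagons adjacent (6-neighbourhood) to a stroma hexagon.
    tumor_rows = np.flatnonzero(base == TUMOR_CLASS)
    for i in tumor_rows:
        q = int(table["q"].iat[i])
        r = int(table["r"].iat[i])
        for dq, dr in AXIAL_NEIGHBORS:
            j = grid.row_of(q + dq, r + dr)
            if j is not None and base[j] == STROMA_CLASS:
                is_te[i] = True
                break
    if not is_te.any():
        raise NoInterfaceError("no tumor-stroma interface found on this slide")
    out = table.copy()
    out["is_te"] = is_te
    out.loc[is_te, "rank"] = 0.0
    return RankedGrid(grid=grid, table=out)


def rank_hexagons(
    classified: RankedGrid, background_traversable: bool = False
) -> RankedGrid:
    """Signed lattice distance to the nearest TE hexagon via multi-source BFS.

    Hexagons unreachable from the TE keep an undefined (NaN) rank and are
    excluded downstream.
    """
    table = classified.table
    if "is_te" not in table.columns or not table["is_te"].any():
        raise NoInterfaceError("tumor edge not detected or empty")
    base = table["base_class"].to_numpy()
    is_te = table["is_te"].to_numpy()
    grid = classified.grid

    traversable = base != BACKGROUND_CLASS
    if background_traversable:
        traversable = np.ones_like(traversable)

    dist = np.full(len(table), -1, dtype=np.int64)
    sources = np.flatnonzero(is_te)
    dist[sources] = 0
    queue = deque(int(i) for i in sources)
    qs = table["q"].to_numpy()
    rs = table["r"].to_numpy()
    while queue:
        i = queue.popleft()
        d = dist[i]
        for dq, dr in AXIAL_NEIGHBORS:
            j = grid.row_of(int(qs[i]) + dq, int(rs[i]) + dr)
            if j is not None and dist[j] < 0 and traversable[j]:
                dist[j] = d + 1
                queue.append(j)

    rank = np.full(len(table), np.nan)
    reached = dist >= 0
    sign = np.where(base == STROMA_CLASS, -1.0, 1.0)  # tumor and edge are non-negative
    rank[reached] = sign[reached] * dist[reached]
    rank[base == BACKGROUND_CLASS] = np.nan
    rank[is_te] = 0.0

    out = table.copy()
    out["rank"] = rank
    return RankedGrid(grid=grid, table=out)


def extract_interface_zone(ranked: RankedGrid, width: int = 3) -> InterfaceZone:
    """Extract the interface zone of odd ``width`` ranks around the TE.

    Width w covers ranks [-(w-1)/2, (w-1)/2]; width 3 (the default used for
    colorectal tissue) covers ranks {-1, 0, +1} whose layers are the stroma
    (S), tumor edge (TE) and tumor (T) aspects.
    """
    if width < 1 or width % 2 == 0:
        raise ParameterError("interface-zone width must be an odd positive integer")
    half = (width - 1) // 2
    rank = ranked.table["rank"]
    members = ranked.table.loc[rank.notna() & (rank.abs() <= half)].copy()
    members["aspect"] = np.select(
        [members["rank"] < 0, members["rank"] > 0], ["S", "T"], default="TE"
    )
    return InterfaceZone(width=width, table=members)


def qc_case(grid: HexGrid, min_tumor_area_mm2: float = 4.5) -> tuple[bool, str]:
    """Case-level QC: total tumor area must reach the threshold (inclusive)."""
    area = grid.total_tumor_area_mm2()
    if area >= min_tumor_area_mm2:
        return True, f"tumor area {area:.3f} mm2 >= {min_tumor_area_mm2} mm2"
    return False, (
        f"tumor area {area:.3f} mm2 below the {min_tumor_area_mm2} mm2 minimum"
    )
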