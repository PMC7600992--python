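"""Immunogradient indicators: gradient profiles, Center of Mass, densities.

For each marker the per-hexagon density is the cell count divided by the
hexagon's analyzed-tissue (tumor + stroma) area in mm^2. The rank statistic
q(r) is the mean of these densities over hexagons of rank r, and the Center
of Mass

    CM = sum_i r_i * q(r_i) / sum_i q(r_i)

locates which side of the tumor edge the cell density gravitates towards:
CM > 0 means the density rises toward the tumor aspect. For the width-3
interface zone the aspect densities d_S, d_TE, d_T coincide with q(-1),
q(0) and q(+1), and CM reduces to (q(1) - q(-1)) / (q(-1) + q(0) + q(1)).

The intratumoral density INT is the pooled statistic: all marker cells lying
on tumor-class pixels divided by the slide's total tumor-class area.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import NoInterfaceError
from .hexgrid import (
    MARKERS,
    TUMOR,
    HexGrid,
    TissueMap,
    assign_cells,
    build_hex_grid,
    compute_area_fractions,
    validate_cell_table,
)
from .interface import (
    InterfaceZone,
    RankedGrid,
    classify_hexagons,
    detect_tumor_edge,
    extract_interface_zone,
    qc_case,
    rank_hexagons,
)


@dataclass
class GradientProfile:
    """Per-rank cell-density statistic q(r) for one marker."""

    marker: str
    ranks: np.ndarray  # strictly increasing integers
    q: np.ndarray  # q(r_i) >= 0, cells/mm^2
    n_hex: np.ndarray  # usable hexagons per rank
    omitted_ranks: list = field(default_factory=list)  # ranks with no usable hexagon

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, int)
        self.q = np.asarray(self.q, float)
        self.n_hex = np.asarray(self.n_hex, int)


def _hex_densities(table: pd.DataFrame, marker: str, min_area_mm2: float):
    """(rank, density) over usable hexagons; excludes tiny-tissue hexagons."""
    area = (table["area_tumor_mm2"] + table["area_stroma_mm2"]).to_numpy()
    usable = area >= min_area_mm2
    counts = table[f"n_{marker.lower()}"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(usable, counts / area, np.nan)
    return table["rank"].to_numpy()[usable], dens[usable], counts[usable], area[usable]


def gradient_profile(
    iz: InterfaceZone,
    marker: str,
    min_area_mm2: float = 1e-3,
    pooled: bool = False,
) -> GradientProfile:
    """Rank statistic q(r) across the interface zone for one marker.

    By default q(r) is the arithmetic mean of per-hexagon densities at rank
    r; with ``pooled`` it is the summed count over summed area. Rank levels
    with no usable hexagon are omitted and flagged.
    """
    ranks, dens, counts, areas = _hex_densities(iz.table, marker, min_area_mm2)
    half = (iz.width - 1) // 2
    wanted = np.arange(-half, half + 1)
    out_r, out_q, out_n, omitted = [], [], [], []
    for r in wanted:
        sel = ranks == r
        n = int(sel.sum())
        if n == 0:
            omitted.append(int(r))
            continue
        if pooled:
            out_q.append(counts[sel].sum() / areas[sel].sum())
        else:
            out_q.append(float(np.mean(dens[sel])))
        out_r.append(int(r))
        out_n.append(n)
    return GradientProfile(
        marker=marker,
        ranks=np.array(out_r, int),
        q=np.array(out_q, float),
        n_hex=np.array(out_n, int),
        omitted_ranks=omitted,
    )


def center_of_mass(profile: GradientProfile) -> float | None:
    """CM = sum r q(r) / sum q(r); None (undefined) when all q vanish."""
    if profile.q.size == 0:
        return None
    denom = float(profile.q.sum())
    if denom == 0.0:
        return None
    return float(np.dot(profile.ranks, profile.q) / denom)


def aspect_densities(
    iz: InterfaceZone,
    marker: str,
    min_area_mm2: float = 1e-3,
    pooled: bool = False,
) -> tuple[float | None, float | None, float | None]:
    """Mean marker density in the stroma (S), tumor-edge (TE) and tumor (T)
    aspects of the interface zone. Empty aspects yield None."""
    ranks, dens, counts, areas = _hex_densities(iz.table, marker, min_area_mm2)
    out = []
    for sel in (ranks < 0, ranks == 0, ranks > 0):
        if not sel.any():
            out.append(None)
        elif pooled:
            out.append(float(counts[sel].sum() / areas[sel].sum()))
        else:
            out.append(float(np.mean(dens[sel])))
    return tuple(out)


def intratumoral_density(
    tissue_map: TissueMap, cells: pd.DataFrame, marker: str
) -> float | None:
    """Pooled intratumoral density: cells on tumor-class pixels per mm^2 of
    tumor-class tissue over the whole slide. None when there is no tumor."""
    cells = validate_cell_table(cells)
    tumor_area = tissue_map.class_area_mm2(TUMOR)
    if tumor_area == 0.0:
        return None
    sub = cells.loc[cells["marker"] == marker]
    x = sub["x_um"].to_numpy(float)
    y = sub["y_um"].to_numpy(float)
    w_um, h_um = tissue_map.extent_um
    inb = (x >= 0) & (x < w_um) & (y >= 0) & (y < h_um)
    col = (x[inb] / tissue_map.pixel_size_um).astype(int)
    row = (y[inb] / tissue_map.pixel_size_um).astype(int)
    n_on_tumor = int(np.count_nonzero(tissue_map.labels[row, col] == TUMOR))
    return n_on_tumor / tumor_area


def intratumoral_density_hexmean(
    ranked: RankedGrid, marker: str, min_area_mm2: float = 1e-3
) -> float | None:
    """Alternative intratumoral statistic: mean density over tumor-classified
    hexagons (sensitivity-analysis variant of the pooled default)."""
    t = ranked.table
    sub = t.loc[t["base_class"] == "tumor"]
    area = (sub["area_tumor_mm2"] + sub["area_stroma_mm2"]).to_numpy()
    usable = area >= min_area_mm2
    if not usable.any():
        return None
    dens = sub[f"n_{marker.lower()}"].to_numpy(float)[usable] / area[usable]
    return float(np.mean(dens))


INDICATOR_COLUMNS = [
    f"{m}_{s}" for m in MARKERS for s in ("CM", "d_S", "d_TE", "d_T")
] + [f"INT_{m}" for m in MARKERS]


@dataclass
class CaseResult:
    """Per-case output: QC verdict, the 15 indicators and their flags."""

    qc_pass: bool
    qc_reason: str
    indicators: dict
    flags: dict
    grid: HexGrid | None = None
    ranked: RankedGrid | None = None
    iz: InterfaceZone | None = None

    def to_row(self) -> dict:
        row = dict(self.indicators)
        row["qc_pass"] = self.qc_pass
        row["qc_reason"] = self.qc_reason
        for k, v in self.flags.items():
            row[f"flag_{k}"] = v
        return row


def compute_indicator_set(
    tissue_map: TissueMap,
    cells: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> CaseResult:
    """Run the full per-case spatial pipeline and collect all 15 indicators
    (3 markers x {CM, d_S, d_TE, d_T, INT}).

    A slide without a tumor-stroma interface flags the interface-zone
    indicators as undefined but still reports intratumoral densities; a case
    failing tissue-area QC is computed and flagged, never dropped silently.
    """
    cfg = config or PipelineConfig()
    grid = build_hex_grid(tissue_map, cfg.hex_side_um, cfg.orientation)
    compute_area_fractions(grid, tissue_map)
    assign_cells(grid, cells, tissue_map, exclude_follicle_cells=cfg.exclude_follicle_cells)
    qc_pass, qc_reason = qc_case(grid, cfg.min_tumor_area_mm2)

    indicators: dict = {}
    flags: dict = {}
    ranked = None
    iz = None
    try:
        classified = classify_hexagons(
            grid, cfg.mixed_fraction_threshold, cfg.background_threshold
        )
        ranked = rank_hexagons(
            detect_tumor_edge(classified), cfg.background_traversable
        )
        iz = extract_interface_zone(ranked, cfg.iz_width)
    except NoInterfaceError as exc:
        for m in MARKERS:
            for s in ("CM", "d_S", "d_TE", "d_T"):
                indicators[f"{m}_{s}"] = np.nan
                flags[f"{m}_{s}"] = "no_interface"
        flags["interface"] = str(exc)
    else:
        for m in MARKERS:
            profile = gradient_profile(
                iz, m, cfg.min_hex_tissue_area_mm2, cfg.pooled_rank_statistic
            )
            cm = center_of_mass(profile)
            indicators[f"{m}_CM"] = np.nan if cm is None else cm
            if cm is None:
                flags[f"{m}_CM"] = "undefined_zero_profile"
            d_s, d_te, d_t = aspect_densities(
                iz, m, cfg.min_hex_tissue_area_mm2, cfg.pooled_rank_statistic
            )
            for name, val in (("d_S", d_s), ("d_TE", d_te), ("d_T", d_t)):
                indicators[f"{m}_{name}"] = np.nan if val is None else val
                if val is None:
                    flags[f"{m}_{name}"] = "empty_aspect"

    for m in MARKERS:
        int_d = intratumoral_density(tissue_map, cells, m)
        indicators[f"INT_{m}"] = np.nan if int_d is None else int_d
        if int_d is None:
            flags[f"INT_{m}"] = "no_tumor_area"

    return CaseResult(
        qc_pass=qc_pass,
        qc_reason=qc_reason,
        indicators=indicators,
        flags=flags,
        grid=grid,
        ranked=ranked,
        iz=iz,
    )
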