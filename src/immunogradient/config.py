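"""Run configuration for the per-case spatial pipeline.

All geometry is expressed in micrometres with the origin at the raster
top-left corner, x increasing rightward and y downward.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """Parameters of the hexagonal-grid interface-zone pipeline.

    Attributes
    ----------
    hex_side_um:
        Hexagon side (circumradius) in micrometres. The default of 65 um
        yields multi-cell hexagons at 0.5 um/px scans and an IZ of width 3
        roughly 200-400 um wide.
    orientation:
        Hexagon orientation, ``"pointy"`` (vertex up) or ``"flat"``.
    mixed_fraction_threshold:
        Minimum fraction of analyzed tissue (tumor + stroma) that *both*
        classes must reach for a hexagon to be an edge candidate.
    background_threshold:
        Hexagons whose analyzed-tissue fraction of total hexagon area falls
        below this are classified background.
    iz_width:
        Interface-zone width in hexagon ranks; must be odd. Width 3 covers
        ranks {-1, 0, +1}.
    min_hex_tissue_area_mm2:
        Hexagons with less analyzed tissue than this are excluded from
        density statistics.
    min_tumor_area_mm2:
        Case-level QC: slides with total tumor area below this are excluded
        (boundary inclusive: exactly the threshold passes).
    exclude_follicle_cells:
        Drop cells lying on lymphoid-follicle pixels before counting, so
        cell aggregates inside follicles do not inflate stromal densities.
    follicle_in_denominator:
        Count follicle area in density denominators (off by default; the
        denominator is tumor + stroma area only).
    pooled_rank_statistic:
        If True the per-rank statistic q(r) is pooled count/area instead of
        the mean of per-hexagon densities.
    background_traversable:
        Allow rank propagation through background hexagons.
    """

    hex_side_um: float = 65.0
    orientation: str = "pointy"
    mixed_fraction_threshold: float = 0.1
    background_threshold: float = 0.05
    iz_width: int = 3
    min_hex_tissue_area_mm2: float = 1e-3
    min_tumor_area_mm2: float = 4.5
    exclude_follicle_cells: bool = True
    follicle_in_denominator: bool = False
    pooled_rank_statistic: bool = False
    background_traversable: bool = False

    def __post_init__(self) -> None:
        if self.hex_side_um <= 0:
            raise ParameterError("hex_side_um must be positive")
        if self.orientation not in ("pointy", "flat"):
            raise ParameterError(f"unknown orientation {self.orientation!r}")
        if not 0 < self.mixed_fraction_threshold <= 0.5:
            raise ParameterError("mixed_fraction_threshold must lie in (0, 0.5]")
        if not 0 <= self.background_threshold < 1:
            raise ParameterError("background_threshold must lie in [0, 1)")
        if self.iz_width < 1 or self.iz_width % 2 == 0:
            raise ParameterError("iz_width must be an odd positive integer")
        if self.min_tumor_area_mm2 < 0:
            raise ParameterError("min_tumor_area_mm2 must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))
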