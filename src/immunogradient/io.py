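"""File formats: label rasters (TIFF/PNG + JSON sidecar) and CSV tables.

A tissue map is stored as a single-channel 8-bit TIFF or PNG alongside a
sidecar JSON ``<image>.json`` holding ``{"pixel_size_um": float,
"label_map": {"0": "background", ...}}``. Cell tables are CSV with the
header ``case_id,marker,x_um,y_um``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import VocabularyError
from .hexgrid import CLASS_NAMES, TissueMap, validate_cell_table


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".json")


def write_tissue_map(tissue_map: TissueMap, path) -> None:
    path = Path(path)
    arr = tissue_map.labels.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        Image.fromarray(arr, mode="L").save(path)
    else:
        raise VocabularyError(f"unsupported raster format {path.suffix!r}")
    sidecar = {
        "pixel_size_um": tissue_map.pixel_size_um,
        "label_map": {str(k): v for k, v in CLASS_NAMES.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_tissue_map(path) -> TissueMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
    else:
        raise VocabularyError(f"unsupported raster format {path.suffix!r}")
    meta = json.loads(_sidecar_path(path).read_text())
    return TissueMap(labels=arr.astype(np.uint8), pixel_size_um=float(meta["pixel_size_um"]))


def write_cell_table(cells: pd.DataFrame, path, case_id: str | None = None) -> None:
    out = cells.copy()
    if "case_id" not in out.columns:
        out.insert(0, "case_id", case_id or "")
    out[["case_id", "marker", "x_um", "y_um"]].to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    return validate_cell_table(cells)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"case_id", "OS_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise VocabularyError(f"cohort table missing columns {sorted(missing)}")
    if (df["OS_months"] < 0).any():
        raise VocabularyError("OS_months must be non-negative")
    if not df["event"].isin((0, 1)).all():
        raise VocabularyError("event must be 0/1")
    return df
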