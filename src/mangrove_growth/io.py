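"""Tabular and raster file formats.

Plot inventories and heavy-metal tables travel as plain CSV with documented
column schemas; raster layers use the ESRI ASCII grid format (plain-text
ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value header followed by
row-major values).  All parsing is locale-independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import HM_COLUMNS, validate_hm_table

__all__ = [
    "RasterLayer",
    "SchemaError",
    "read_plot_csv", "write_plot_csv",
    "read_hm_csv", "write_hm_csv",
    "read_ascii_grid", "write_ascii_grid",
    "write_run_summary",
]

PLOT_REQUIRED = ["plot_id", "age", "mean_dbh", "density", "salinity"]
PLOT_NUMERIC = ["age", "mean_dbh", "mean_height", "density", "salinity", "elevation"]


class SchemaError(ValueError):
    """A table does not match its documented column schema."""


class FormatError(ValueError):
    """A raster file violates the ASCII-grid format."""


@dataclass
class RasterLayer:
    """A single 2-D raster: values plus geometry and nodata marker."""

    values: np.ndarray
    cellsize: float = 100.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0
    kind: str = "unknown"  # elevation | salinity | root_cr | forest_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask_valid(self) -> np.ndarray:
        return self.values != self.nodata


def _check_numeric(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            continue
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise SchemaError(f"{path}: malformed value in column {c!r} at line {line}")
        df[c] = coerced


def read_plot_csv(path: str | Path) -> pd.DataFrame:
    """Read a plot-inventory CSV; unknown columns are preserved."""
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in PLOT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    _check_numeric(df, PLOT_NUMERIC, path)
    return df


def write_plot_csv(path: str | Path, plots: pd.DataFrame) -> None:
    missing = [c for c in PLOT_REQUIRED if c not in plots.columns]
    if missing:
        raise SchemaError(f"refusing to write plot table without column(s) {missing}")
    plots.to_csv(path, index=False)


def read_hm_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format heavy-metal concentration CSV."""
    df = pd.read_csv(path, dtype={"site": str})
    missing = [c for c in HM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    _check_numeric(df, ["conc"], path)
    validate_hm_table(df)
    return df


def write_hm_csv(path: str | Path, table: pd.DataFrame) -> None:
    validate_hm_table(table)
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, kind: str = "unknown") -> RasterLayer:
    """Read an ESRI ASCII grid (plain-text raster) into a RasterLayer."""
    path = Path(path)
    header: dict[str, float] = {}
    values: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    nodata = -9999.0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS:
            header[key] = float(parts[1])
        elif key == "nodata_value":
            nodata = float(parts[1])
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: missing header field(s) {missing}")
    for line in lines[i:]:
        values.extend(float(tok) for tok in line.split())
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(values) != ncols * nrows:
        raise FormatError(
            f"{path}: expected {ncols * nrows} values, found {len(values)}"
        )
    arr = np.array(values, dtype=float).reshape(nrows, ncols)
    return RasterLayer(values=arr, cellsize=header["cellsize"],
                       xllcorner=header["xllcorner"], yllcorner=header["yllcorner"],
                       nodata=nodata, kind=kind)


def write_ascii_grid(path: str | Path, layer: RasterLayer, fmt: str = "%.6g") -> None:
    nrows, ncols = layer.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {layer.xllcorner:.6g}\n")
        fh.write(f"yllcorner {layer.yllcorner:.6g}\n")
        fh.write(f"cellsize {layer.cellsize:.6g}\n")
        fh.write(f"NODATA_value {layer.nodata:.6g}\n")
        for row in layer.values:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def write_run_summary(path: str | Path, summary: dict, config: dict | None = None) -> None:
    """Write a run-summary JSON; a hash of the config is recorded for provenance."""
    doc = dict(summary)
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        doc["config_sha256"] = hashlib.sha256(blob).hexdigest()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=float)
        fh.write("\n")
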