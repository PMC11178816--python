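"""Minimal raster I/O: multiband TIFF with a JSON georeferencing sidecar.

The pipeline only needs co-registered, axis-aligned rasters on a projected
CRS, so geotransform metadata (top-left origin, square pixel size, CRS
label, band names, nodata convention) travels in a ``<file>.json`` sidecar
next to each plain multiband TIFF written with :mod:`tifffile`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_raster", "read_raster"]


def write_raster(
    path: str | Path,
    data: np.ndarray,
    *,
    band_names: list[str],
    pixel_size: float,
    x_origin: float = 0.0,
    y_origin: float = 0.0,
    crs: str = "EPSG:3005",
    nodata: str | float | None = None,
) -> None:
    """Write a (bands, rows, cols) array plus its sidecar."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(band_names):
        raise ValueError("band_names length must match the number of bands")
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack",
                     planarconfig="separate")
    meta = {
        "band_names": list(band_names),
        "pixel_size": float(pixel_size),
        "x_origin": float(x_origin),
        "y_origin": float(y_origin),
        "crs": crs,
        "nodata": nodata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multiband TIFF and its sidecar; returns (data, metadata)."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        meta = {
            "band_names": [f"band_{i}" for i in range(data.shape[0])],
            "pixel_size": 1.0,
            "x_origin": 0.0,
            "y_origin": 0.0,
            "crs": "",
            "nodata": None,
        }
    return data, meta
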