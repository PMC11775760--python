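"""File exchange: TIFF rasters with JSON geometry sidecars, CSV tables and
JSON run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec

FOOTPRINT_COLUMNS = (
    "x_m", "y_m", "h_te_best_fit", "h_te_interp", "h_mean_canopy_abs", "solar_elevation",
)


def write_raster(path: str | Path, array: np.ndarray, grid: GridSpec) -> None:
    """Single-band raster as TIFF plus a ``.json`` sidecar carrying the grid
    geometry (no GDAL dependency in this environment)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    sidecar = {
        "rows": grid.rows,
        "cols": grid.cols,
        "pixel_size": grid.pixel_size,
        "x0": grid.x0,
        "y0": grid.y0,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    import tifffile

    path = Path(path)
    array = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return array, GridSpec(**meta)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path: str | Path, manifest: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(manifest, indent=1, default=default))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def photon_table(cloud) -> pd.DataFrame:
    data = {"along_track_m": cloud.along_track, "elevation_m": cloud.elevation}
    if cloud.true_label is not None:
        data["true_label"] = cloud.true_label
    data["pred_label"] = cloud.pred_label
    return pd.DataFrame(data)
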