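"""Shared file I/O: localization/trajectory CSV, ROI GeoJSON, TIFF stacks.

Canonical table columns are ``id, frame, x_nm, y_nm, precision_nm`` (plus
``species`` for localization tables).  Common ThunderSTORM-style aliases
(``x [nm]``, ``y [nm]``, ``uncertainty [nm]``, ...) are accepted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape

COLUMN_ALIASES = {
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "uncertainty [nm]": "precision_nm",
    "uncertainty_xy [nm]": "precision_nm",
    "sigma [nm]": "precision_nm",
    "x": "x_nm",
    "y": "y_nm",
    "uncertainty": "precision_nm",
    "precision": "precision_nm",
    "track_id": "id",
    "particle": "id",
    "t": "frame",
}


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization or trajectory CSV, normalizing column names."""
    df = pd.read_csv(path)
    df = df.rename(columns={c: COLUMN_ALIASES.get(c, c) for c in df.columns})
    missing = {"x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "frame" not in df.columns:
        df["frame"] = 0
    if "precision_nm" in df.columns and (df["precision_nm"] <= 0).any():
        raise ValueError(f"{path}: localization precision must be positive")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_roi(path: str | Path) -> Polygon:
    """Read an ROI polygon from a GeoJSON file (coordinates in nm)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        gj = gj["geometry"]
    poly = shape(gj)
    if poly.geom_type != "Polygon":
        raise ValueError(f"{path}: expected a Polygon ROI, got {poly.geom_type}")
    return poly


def write_roi(polygon: Polygon, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "Feature", "geometry": mapping(polygon),
                   "properties": {}}, fh)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (multi-page) TIFF as a float array."""
    return tifffile.imread(str(path)).astype(float)


def write_stack(images: np.ndarray | list[np.ndarray], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(images, dtype=np.float32))


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
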