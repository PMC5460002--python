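"""Raster landscape and water-feature containers, with ESRI ASCII grid I/O.

All layers live on a common square grid (1-km cells by default). Water
features are stored as a patch-id raster (0 = dry land, k > 0 = patch k)
plus a registry mapping each patch to its hydrological feature class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_CLASSES = (
    "perennial_spring",
    "seasonal_spring",
    "geothermal_spring",
    "fresh_lake",
    "saline_lake",
    "wetland_perennial",
    "wetland_seasonal",
    "river_major_gt0",
    "river_major_gt5",
    "river_perennial",
    "river_seasonal",
)


@dataclass
class Landscape:
    """Terrain layers on a square grid: elevation [m], dimensionless
    roughness and slope, an optional traversal-cost layer [energy units per
    cell, >= 1 everywhere] and a per-cell lethality probability (default 0
    everywhere, which gives agents the maximum chance of dispersal)."""

    elevation: np.ndarray
    roughness: np.ndarray
    slope: np.ndarray
    cell_km: float = 1.0
    cost: np.ndarray | None = None
    lethality: np.ndarray | None = None

    def __post_init__(self) -> None:
        shp = self.elevation.shape
        for name in ("roughness", "slope", "cost", "lethality"):
            layer = getattr(self, name)
            if layer is not None and layer.shape != shp:
                raise ValueError(f"layer {name} shape {layer.shape} != {shp}")
        if self.lethality is None:
            self.lethality = np.zeros(shp)
        if np.any(self.lethality < 0) or np.any(self.lethality > 1):
            raise ValueError("lethality must be a probability")
        if self.cost is not None and np.any(self.cost < 1):
            raise ValueError("cost must be >= 1 everywhere")
        if np.any(self.roughness < 0):
            raise ValueError("roughness must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape


@dataclass
class WaterLayer:
    """Water-patch raster and per-patch feature-class registry."""

    patch_id: np.ndarray                  # int raster, 0 = no water
    registry: pd.DataFrame                # columns: patch_id, feature_class

    def __post_init__(self) -> None:
        ids = np.unique(self.patch_id)
        ids = ids[ids > 0]
        reg_ids = np.asarray(self.registry["patch_id"])
        if len(reg_ids) != len(set(reg_ids)):
            raise ValueError("duplicate patch ids in registry")
        if not set(ids) <= set(reg_ids):
            raise ValueError("raster contains patches missing from registry")
        missing = set(reg_ids) - set(ids)
        if missing:
            raise ValueError(f"registry patches with no cells: {sorted(missing)}")
        bad = set(self.registry["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")

    @property
    def patch_ids(self) -> np.ndarray:
        return np.asarray(sorted(self.registry["patch_id"]))

    @property
    def n_patches(self) -> int:
        return len(self.registry)

    def classes(self) -> dict:
        return dict(zip(self.registry["patch_id"], self.registry["feature_class"]))

    def cells(self, pid: int) -> np.ndarray:
        return np.argwhere(self.patch_id == pid)

    def subset(self, keep_ids) -> "WaterLayer":
        keep = set(int(i) for i in keep_ids)
        raster = np.where(np.isin(self.patch_id, list(keep)), self.patch_id, 0)
        reg = self.registry[self.registry["patch_id"].isin(keep)].reset_index(drop=True)
        return WaterLayer(patch_id=raster, registry=reg)


# -- ESRI ASCII grid ----------------------------------------------------------

def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII raster; returns (array, header dict)."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if arr.shape != (nrows, ncols):
        arr = arr.reshape(nrows, ncols)
    return arr, header


def write_ascii_grid(path, arr: np.ndarray, cellsize: float = 1000.0,
                     xll: float = 0.0, yll: float = 0.0,
                     nodata: float = -9999, fmt: str = "%.6g") -> None:
    arr = np.asarray(arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xll}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, arr, fmt=fmt)


def write_water_layer(dir_path, water: WaterLayer, cellsize: float = 1000.0) -> None:
    dir_path = Path(dir_path)
    write_ascii_grid(dir_path / "patches.asc", water.patch_id, cellsize,
                     fmt="%d")
    water.registry.to_csv(dir_path / "patches.csv", index=False)


def read_water_layer(dir_path) -> WaterLayer:
    dir_path = Path(dir_path)
    raster, _ = read_ascii_grid(dir_path / "patches.asc")
    registry = pd.read_csv(dir_path / "patches.csv")
    return WaterLayer(patch_id=raster.astype(int), registry=registry)
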