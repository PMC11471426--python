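"""File formats: ESRI ASCII grid rasters, occurrence CSV, GeoJSON.

Rasters use the plain-text ESRI ASCII grid format (.asc): a 6-line
header (ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value)
followed by rows north to south, which any GIS reads directly.
Jurisdictions are exchanged as GeoJSON polygons built from the cell
tiling; occurrences as CSV with columns species,x,y,year,source.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grid import CLIMATE_VARIABLES, ClimateGrid
from .synthetic import JurisdictionSet

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_climate_grid",
    "read_climate_grid",
    "write_occurrences",
    "read_occurrences",
    "jurisdictions_to_geojson",
    "write_jurisdictions",
    "read_jurisdictions",
]

NODATA = -9999.0


def write_ascii_grid(
    path, values: np.ndarray, cell_size: float, origin: tuple[float, float]
) -> None:
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {origin[0]}\n"
        f"yllcorner {origin[1]}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    body = np.where(np.isfinite(values), values, NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float]]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = values.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    values[values == hdr["nodata_value"]] = np.nan
    return values, hdr["cellsize"], (hdr["xllcorner"], hdr["yllcorner"])


def write_climate_grid(directory, grid: ClimateGrid) -> None:
    """One .asc per climate variable plus elevation, in a scenario dir."""
    d = Path(directory) / grid.scenario_id
    d.mkdir(parents=True, exist_ok=True)
    for var in CLIMATE_VARIABLES:
        write_ascii_grid(d / f"{var}.asc", grid.layers[var], grid.cell_size, grid.origin)
    write_ascii_grid(d / "elevation.asc", grid.elevation, grid.cell_size, grid.origin)


def read_climate_grid(directory, scenario_id: str) -> ClimateGrid:
    d = Path(directory) / scenario_id
    layers = {}
    cell_size, origin = 1.0, (0.0, 0.0)
    for var in CLIMATE_VARIABLES:
        layers[var], cell_size, origin = read_ascii_grid(d / f"{var}.asc")
    elev, _, _ = read_ascii_grid(d / "elevation.asc")
    return ClimateGrid(
        scenario_id=scenario_id,
        cell_size=cell_size,
        origin=origin,
        layers=layers,
        elevation=elev,
    )


def write_occurrences(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _region_polygon(jset: JurisdictionSet, idx: int):
    rows, cols = np.nonzero(jset.labels == idx)
    x0, y0 = jset.origin
    n_rows = jset.labels.shape[0]
    cs = jset.cell_size
    boxes = [
        box(
            x0 + c * cs,
            y0 + (n_rows - r - 1) * cs,
            x0 + (c + 1) * cs,
            y0 + (n_rows - r) * cs,
        )
        for r, c in zip(rows, cols)
    ]
    return unary_union(boxes)


def jurisdictions_to_geojson(jset: JurisdictionSet) -> dict:
    features = []
    for i, name in enumerate(jset.names):
        poly = _region_polygon(jset, i)
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "name": name,
                    "centroid_x": float(jset.centroids[i, 0]),
                    "centroid_y": float(jset.centroids[i, 1]),
                },
                "geometry": mapping(poly),
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_jurisdictions(path, jset: JurisdictionSet) -> None:
    with open(path, "w") as fh:
        json.dump(jurisdictions_to_geojson(jset), fh)


def read_jurisdictions(path, grid: ClimateGrid) -> JurisdictionSet:
    """Rebuild a JurisdictionSet from GeoJSON by assigning each cell
    center to the polygon containing it (boundary-sitting centers go to
    the lexicographically first jurisdiction; stray cells to the
    nearest polygon)."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = sorted(gj["features"], key=lambda f: f["properties"]["name"])
    names = [f["properties"]["name"] for f in feats]
    geoms = [shapely.geometry.shape(f["geometry"]) for f in feats]
    centroids = np.array(
        [[f["properties"]["centroid_x"], f["properties"]["centroid_y"]] for f in feats]
    )
    X, Y = grid.cell_centers()
    labels = np.full(grid.shape, -1, dtype=int)
    for i, geom in enumerate(geoms):
        free = labels < 0
        inside = shapely.contains_xy(geom, X[free], Y[free])
        idx = np.nonzero(free)
        labels[idx[0][inside], idx[1][inside]] = i
    if (labels < 0).any():  # centers exactly on shared edges
        rows, cols = np.nonzero(labels < 0)
        for r, c in zip(rows, cols):
            pt = shapely.Point(X[r, c], Y[r, c])
            labels[r, c] = int(np.argmin([g.distance(pt) for g in geoms]))
    return JurisdictionSet(
        names=names,
        seed_points=centroids.copy(),
        labels=labels,
        centroids=centroids,
        cell_size=grid.cell_size,
        origin=grid.origin,
    )
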