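"""Occurrence-record quality control.

The pipeline applies, in fixed order: year-window filter (with
missing-year removal) -> far-from-known-range filter -> polygon-centroid
proximity filter -> taxonomic grouping -> one-record-per-grid-cell
dedupe -> modelable-species gate.  Each stage flags the records it
removes, and the report conserves counts per species
(input = retained + sum of removed).

Records are plain pandas DataFrames with columns
``species, x, y, year, source`` (extra columns pass through untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .grid import ClimateGrid

__all__ = [
    "QCReport",
    "filter_year_window",
    "filter_far_from_range",
    "filter_centroid_proximity",
    "group_taxa",
    "dedupe_by_cell",
    "select_modelable",
    "run_qc",
]

FILTER_ORDER = (
    "out_of_window",
    "out_of_range",
    "centroid_proximal",
    "duplicate_cell",
)


@dataclass
class QCReport:
    """Per-stage attrition accounting for one QC run."""

    input_counts: pd.Series = None
    removed: dict[str, pd.Series] = field(default_factory=dict)
    retained_counts: pd.Series = None
    modelable: pd.Series = None  # bool per species
    min_points: int = 50

    def removed_total(self) -> pd.Series:
        if not self.removed:
            return pd.Series(dtype=int)
        return (
            pd.concat(self.removed.values(), axis=1).fillna(0).sum(axis=1).astype(int)
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"input": self.input_counts})
        for stage, counts in self.removed.items():
            out[f"removed_{stage}"] = counts
        out = out.fillna(0).astype(int)
        out["retained"] = self.retained_counts.reindex(out.index).fillna(0).astype(int)
        out["modelable"] = self.modelable.reindex(out.index).fillna(False)
        return out


def _species_counts(df: pd.DataFrame) -> pd.Series:
    return df.groupby("species").size()


def filter_year_window(
    table: pd.DataFrame, window: tuple[int, int] = (1981, 2018)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records with a missing year or a year outside ``window``
    (bounds inclusive).  Returns (kept, removed)."""
    lo, hi = window
    year = pd.to_numeric(table["year"], errors="coerce")
    ok = year.notna() & (year >= lo) & (year <= hi)
    return table[ok].copy(), table[~ok].copy()


def filter_far_from_range(
    table: pd.DataFrame,
    range_polygons: dict | None,
    max_km: float = 200.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records at distance >= ``max_km`` from the species' known-range
    polygon.  Species without a polygon are passed through untouched
    (the filter only applies where a range product is available)."""
    if not range_polygons:
        return table.copy(), table.iloc[0:0].copy()
    drop = np.zeros(len(table), dtype=bool)
    for sp, poly in range_polygons.items():
        if poly is None:
            continue
        if not poly.is_valid:
            raise ValueError(f"invalid range polygon for species {sp!r}")
        idx = np.flatnonzero((table["species"] == sp).to_numpy())
        if idx.size == 0:
            continue
        xs = table["x"].to_numpy()[idx]
        ys = table["y"].to_numpy()[idx]
        dists = np.array([poly.distance(Point(x, y)) for x, y in zip(xs, ys)])
        drop[idx[dists >= max_km]] = True
    return table[~drop].copy(), table[drop].copy()


def filter_centroid_proximity(
    table: pd.DataFrame, centroids: np.ndarray, max_m: float = 300.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records lying strictly within ``max_m`` metres of any polygon
    centroid (such coordinates are a hallmark of geocoded-to-centroid
    records, not true localities).  Coordinates are km."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.size == 0:
        raise ValueError("centroid list must be nonempty")
    max_km = max_m / 1000.0
    pts = table[["x", "y"]].to_numpy(dtype=float)
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    near = (d2 < max_km**2).any(axis=1)
    return table[~near].copy(), table[near].copy()


def group_taxa(table: pd.DataFrame, grouping: dict[str, str] | None) -> pd.DataFrame:
    """Relabel species to group ids (e.g. collapsing congeners that are
    unreliably identified into a genus-level group).

    ``grouping`` maps species -> group label, or group label -> list of
    species; species absent from the table are ignored.  A mapping that
    routes one species to two groups is rejected.
    """
    if not grouping:
        return table.copy()
    flat: dict[str, str] = {}
    for key, val in grouping.items():
        pairs = [(sp, key) for sp in val] if isinstance(val, (list, tuple, set)) else [(key, val)]
        for sp, grp in pairs:
            if sp in flat and flat[sp] != grp:
                raise ValueError(f"species {sp!r} mapped to two groups")
            flat[sp] = grp
    out = table.copy()
    out["species"] = out["species"].map(lambda s: flat.get(s, s))
    return out


def dedupe_by_cell(
    table: pd.DataFrame, grid: ClimateGrid
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Keep one record per (species, grid cell).

    Records falling outside the grid extent are flagged out-of-range and
    removed.  Within a cell the retained record is the one with the
    earliest year, breaking ties by the lexicographically smallest
    source label (then by original order), so the result is fully
    deterministic.  Returns (kept, removed_duplicates, removed_off_grid).
    """
    inside = grid.in_extent(table["x"].to_numpy(), table["y"].to_numpy())
    off = table[~inside].copy()
    t = table[inside].copy()
    if t.empty:
        return t, t.iloc[0:0].copy(), off
    t["_cell"] = grid.cell_index(t["x"].to_numpy(), t["y"].to_numpy())
    t["_order"] = np.arange(len(t))
    t = t.sort_values(["species", "_cell", "year", "source", "_order"], kind="stable")
    first = ~t.duplicated(subset=["species", "_cell"], keep="first")
    kept = t[first].sort_values("_order").drop(columns=["_cell", "_order"])
    dups = t[~first].sort_values("_order").drop(columns=["_cell", "_order"])
    return kept, dups, off


def select_modelable(table: pd.DataFrame, min_points: int = 50) -> set[str]:
    """Species with strictly more than ``min_points`` retained records."""
    counts = _species_counts(table)
    return set(counts[counts > min_points].index)


def run_qc(
    table: pd.DataFrame,
    grid: ClimateGrid,
    centroids: np.ndarray | None = None,
    range_polygons: dict | None = None,
    grouping: dict[str, str] | None = None,
    year_window: tuple[int, int] = (1981, 2018),
    max_range_km: float = 200.0,
    max_centroid_m: float = 300.0,
    min_points: int = 50,
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full QC pipeline in its fixed stage order.

    Returns the retained table and a :class:`QCReport`; the report's
    counts satisfy input = retained + sum(removed) per species.
    """
    report = QCReport(min_points=min_points)
    report.input_counts = _species_counts(table)

    kept, rm = filter_year_window(table, year_window)
    report.removed["out_of_window"] = _species_counts(rm)

    kept, rm = filter_far_from_range(kept, range_polygons, max_range_km)
    report.removed["out_of_range_polygon"] = _species_counts(rm)

    if centroids is not None and len(centroids):
        kept, rm = filter_centroid_proximity(kept, centroids, max_centroid_m)
        report.removed["centroid_proximal"] = _species_counts(rm)

    kept = group_taxa(kept, grouping)

    kept, dups, off = dedupe_by_cell(kept, grid)
    report.removed["duplicate_cell"] = _species_counts(dups)
    report.removed["off_grid"] = _species_counts(off)

    report.retained_counts = _species_counts(kept)
    counts = report.retained_counts
    report.modelable = counts > min_points
    return kept, report
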