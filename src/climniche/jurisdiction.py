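"""Jurisdiction-level (state/province) summaries.

Presence in a jurisdiction means strictly more than ``min_pixels``
suitable cells inside it.  Between two scenarios a species is
maintained (present in both), lost (recent only), gained (future only)
or absent per state.  Elevation shifts of the suitable area within a
state are called significant when the interquartile ranges
[q25, q75] of the two scenarios' suitable-cell elevations do not
overlap (a conservative box-plot criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import BinaryNicheMap
from .synthetic import JurisdictionSet

__all__ = [
    "state_presence",
    "state_turnover",
    "elevation_shift",
    "ElevationShift",
]

MIN_PIXELS = 50


def state_presence(
    bmap: BinaryNicheMap, jurisdictions: JurisdictionSet, min_pixels: int = MIN_PIXELS
) -> pd.DataFrame:
    """Suitable-pixel count and presence call per jurisdiction.

    Presence requires strictly more than ``min_pixels`` suitable cells.
    Counts over all jurisdictions sum to the map's range size, since the
    jurisdictions tile the grid.
    """
    if bmap.mask.shape != jurisdictions.labels.shape:
        raise ValueError("binary map and jurisdictions are on different grids")
    counts = np.bincount(
        jurisdictions.labels[bmap.mask], minlength=jurisdictions.n_jurisdictions
    )
    return pd.DataFrame(
        {
            "species": bmap.species_id,
            "scenario": bmap.scenario_id,
            "jurisdiction": jurisdictions.names,
            "pixels": counts,
            "present": counts > min_pixels,
        }
    )


def state_turnover(
    recent_presence: pd.DataFrame, future_presence: pd.DataFrame
) -> pd.DataFrame:
    """Gained / lost / maintained / absent status per species and state.

    Input frames are outputs of :func:`state_presence` (possibly
    concatenated over species).
    """
    key = ["species", "jurisdiction"]
    merged = recent_presence.merge(
        future_presence[key + ["present", "pixels"]],
        on=key,
        suffixes=("_recent", "_future"),
    )

    def status(row):
        r, f = row["present_recent"], row["present_future"]
        if r and f:
            return "maintained"
        if r:
            return "lost"
        if f:
            return "gained"
        return "absent"

    merged["status"] = merged.apply(status, axis=1)
    return merged[
        key + ["pixels_recent", "pixels_future", "present_recent", "present_future", "status"]
    ]


@dataclass
class ElevationShift:
    """Elevation comparison of suitable cells within one jurisdiction."""

    species_id: str
    jurisdiction: str
    q25_recent: float
    q50_recent: float
    q75_recent: float
    q25_future: float
    q50_future: float
    q75_future: float
    elevation_class: str  # increase | decrease | similar | not_comparable
    median_change: float  # m, future q50 - recent q50


def elevation_shift(
    recent_map: BinaryNicheMap,
    future_map: BinaryNicheMap,
    jurisdictions: JurisdictionSet,
    jurisdiction: str,
    elevation: np.ndarray,
) -> ElevationShift:
    """Compare suitable-cell elevation distributions between scenarios
    within one jurisdiction.

    Disjoint [q25, q75] intervals mean a significant shift (increase if
    the future interval sits higher, decrease if lower); overlapping
    intervals are 'similar'.  Quantiles use linear interpolation.  An
    empty suitable set in either scenario is flagged not comparable.
    """
    region = jurisdictions.mask(jurisdiction)
    rec = elevation[recent_map.mask & region]
    fut = elevation[future_map.mask & region]
    if rec.size == 0 or fut.size == 0:
        return ElevationShift(
            species_id=recent_map.species_id,
            jurisdiction=jurisdiction,
            q25_recent=np.nan,
            q50_recent=np.nan,
            q75_recent=np.nan,
            q25_future=np.nan,
            q50_future=np.nan,
            q75_future=np.nan,
            elevation_class="not_comparable",
            median_change=np.nan,
        )
    r25, r50, r75 = np.quantile(rec, [0.25, 0.5, 0.75])
    f25, f50, f75 = np.quantile(fut, [0.25, 0.5, 0.75])
    if f25 > r75:
        cls = "increase"
    elif f75 < r25:
        cls = "decrease"
    else:
        cls = "similar"
    return ElevationShift(
        species_id=recent_map.species_id,
        jurisdiction=jurisdiction,
        q25_recent=float(r25),
        q50_recent=float(r50),
        q75_recent=float(r75),
        q25_future=float(f25),
        q50_future=float(f50),
        q75_future=float(f75),
        elevation_class=cls,
        median_change=float(f50 - r50),
    )
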