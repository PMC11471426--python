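"""Range-change accounting between scenario pairs.

Pixel bookkeeping between two binary niche maps: loss (suitable only in
the first scenario), gain (suitable only in the second), maintain
(suitable in both).  Derived percentages follow the standard
range-size comparison table:

    percent_lost   = 100 * Loss / (Loss + Maintain)
    percent_gained = 100 * Gain / (Loss + Maintain)
    range_change   = percent_gained - percent_lost

All percentages are computed from unrounded ratios and rounded to two
decimals only when exported.  ``range_change`` equals the net percent
change in range size, since Loss + Maintain is the current range size.
Ranges are classified as expand / shift / contract / stable (with a
stable-but-moving subclass) from the net change (+/-10% band), the
turnover (percent lost, 50% cut) and the centroid displacement.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import BinaryNicheMap

__all__ = [
    "RangeChangeSummary",
    "RichnessMap",
    "compare_ranges",
    "classify_change",
    "centroid",
    "centroid_shift",
    "richness",
    "richness_change",
    "export_table",
    "load_published_range_changes",
]


@dataclass
class RangeChangeSummary:
    """Loss/gain/maintain accounting for one species and scenario pair."""

    species_id: str
    scenario_pair: tuple[str, str]
    loss: int
    gain: int
    maintain: int
    centroid_from: tuple[float, float] | None = None
    centroid_to: tuple[float, float] | None = None
    shift_km: float | None = None
    shift_bearing_deg: float | None = None

    @property
    def current_size(self) -> int:
        return self.loss + self.maintain

    @property
    def future_size(self) -> int:
        return self.gain + self.maintain

    @property
    def percent_lost(self) -> float:
        if self.current_size == 0:
            return math.nan
        return 100.0 * self.loss / self.current_size

    @property
    def percent_gained(self) -> float:
        if self.current_size == 0:
            return math.nan
        return 100.0 * self.gain / self.current_size

    @property
    def range_change(self) -> float:
        return self.percent_gained - self.percent_lost

    @property
    def net_change_pct(self) -> float:
        """Net percent change in range size; identical to range_change."""
        if self.current_size == 0:
            return math.nan
        return 100.0 * (self.future_size - self.current_size) / self.current_size

    @property
    def turnover_pct(self) -> float:
        return self.percent_lost

    @classmethod
    def from_counts(
        cls,
        loss: int,
        gain: int,
        maintain: int,
        species_id: str = "species",
        scenario_pair: tuple[str, str] = ("recent", "late85"),
    ) -> "RangeChangeSummary":
        return cls(
            species_id=species_id,
            scenario_pair=scenario_pair,
            loss=int(loss),
            gain=int(gain),
            maintain=int(maintain),
        )


def compare_ranges(
    from_map: BinaryNicheMap, to_map: BinaryNicheMap
) -> RangeChangeSummary:
    """Pixel accounting between two binary maps of one species."""
    if from_map.mask.shape != to_map.mask.shape:
        raise ValueError("binary maps are on different grids")
    if from_map.species_id != to_map.species_id:
        raise ValueError("binary maps belong to different species")
    a, b = from_map.mask, to_map.mask
    summary = RangeChangeSummary(
        species_id=from_map.species_id,
        scenario_pair=(from_map.scenario_id, to_map.scenario_id),
        loss=int((a & ~b).sum()),
        gain=int((~a & b).sum()),
        maintain=int((a & b).sum()),
    )
    c_from = centroid(from_map)
    c_to = centroid(to_map)
    summary.centroid_from = c_from
    summary.centroid_to = c_to
    if c_from is not None and c_to is not None:
        shift = centroid_shift_xy(c_from, c_to)
        summary.shift_km = shift["shift_km"]
        summary.shift_bearing_deg = shift["bearing_deg"]
    return summary


def classify_change(
    summary: RangeChangeSummary,
    net_thresh: float = 10.0,
    turnover_thresh: float = 50.0,
    centroid_thresh_km: float = 100.0,
) -> str:
    """Classify a range change as expand / shift / contract / stable /
    stable_shift.

    Rules: net change >= +net_thresh with turnover <= turnover_thresh is
    expansion; the same net growth with higher turnover is a shift; net
    change <= -net_thresh is contraction; a stable-sized range whose
    centroid moved more than ``centroid_thresh_km`` is stable_shift;
    anything else is stable.  An empty current range is unclassifiable.
    """
    if summary.current_size == 0:
        return "undefined"
    net = summary.net_change_pct
    turn = summary.turnover_pct
    if net >= net_thresh:
        return "expand" if turn <= turnover_thresh else "shift"
    if net <= -net_thresh:
        return "contract"
    shift = summary.shift_km or 0.0
    return "stable_shift" if shift > centroid_thresh_km else "stable"


def _cell_centers(mask_shape, cell_size, origin):
    n_rows, n_cols = mask_shape
    x0, y0 = origin
    x = x0 + (np.arange(n_cols) + 0.5) * cell_size
    y = y0 + (n_rows - np.arange(n_rows) - 0.5) * cell_size
    return np.meshgrid(x, y)


def centroid(bmap: BinaryNicheMap) -> tuple[float, float] | None:
    """Center of gravity of the suitable area: the unweighted mean of
    suitable cell centers, or None for an empty map."""
    if bmap.range_size == 0:
        return None
    X, Y = _cell_centers(bmap.mask.shape, bmap.cell_size, bmap.origin)
    return float(X[bmap.mask].mean()), float(Y[bmap.mask].mean())


def centroid_shift_xy(
    c_from: tuple[float, float], c_to: tuple[float, float]
) -> dict[str, float]:
    """Euclidean displacement between centroids: distance in km and
    bearing clockwise from grid north (0 = north, 90 = east)."""
    dx = c_to[0] - c_from[0]
    dy = c_to[1] - c_from[1]
    return {
        "shift_km": float(math.hypot(dx, dy)),
        "bearing_deg": float(math.degrees(math.atan2(dx, dy)) % 360.0),
    }


def centroid_shift(
    from_map: BinaryNicheMap, to_map: BinaryNicheMap
) -> dict[str, float]:
    c_from = centroid(from_map)
    c_to = centroid(to_map)
    if c_from is None or c_to is None:
        raise ValueError("centroid undefined for an empty map")
    return centroid_shift_xy(c_from, c_to)


# ---------------------------------------------------------------------------
# richness


@dataclass
class RichnessMap:
    """Per-cell count of species with suitable climate (stacked masks)."""

    scenario_id: str
    values: np.ndarray
    species: tuple[str, ...]


def richness(maps: list[BinaryNicheMap]) -> RichnessMap:
    """Stack and sum binary maps of one scenario."""
    if not maps:
        return RichnessMap(scenario_id="", values=np.zeros((0, 0), dtype=int), species=())
    shape = maps[0].mask.shape
    scenario = maps[0].scenario_id
    total = np.zeros(shape, dtype=int)
    for m in maps:
        if m.mask.shape != shape:
            raise ValueError("richness stack requires a common grid")
        total += m.mask.astype(int)
    return RichnessMap(
        scenario_id=scenario, values=total, species=tuple(m.species_id for m in maps)
    )


def richness_change(
    recent_maps: list[BinaryNicheMap],
    future_maps: list[BinaryNicheMap],
    dispersal: str = "full",
) -> np.ndarray:
    """Signed per-cell richness difference (future - recent).

    Under full dispersal every newly suitable cell counts; under no
    dispersal each species' gains outside its recent range are masked
    (it cannot colonize novel areas) while losses still count, so the
    change is nowhere positive.
    """
    if dispersal not in ("full", "none"):
        raise ValueError("dispersal must be 'full' or 'none'")
    rec = {m.species_id: m for m in recent_maps}
    fut = {m.species_id: m for m in future_maps}
    if set(rec) != set(fut):
        raise ValueError("recent and future stacks cover different species sets")
    if not rec:
        raise ValueError("empty species set")
    shape = next(iter(rec.values())).mask.shape
    change = np.zeros(shape, dtype=int)
    for sp, r in rec.items():
        f = fut[sp]
        if r.mask.shape != shape or f.mask.shape != shape:
            raise ValueError("richness stacks require a common grid")
        eff = f.mask if dispersal == "full" else (f.mask & r.mask)
        change += eff.astype(int) - r.mask.astype(int)
    return change


# ---------------------------------------------------------------------------
# reporting


TABLE_COLUMNS = [
    "species",
    "current",
    "future",
    "loss",
    "gain",
    "maintain",
    "percent_lost",
    "percent_gained",
    "range_change",
]


def export_table(summaries: list[RangeChangeSummary]) -> pd.DataFrame:
    """Range-size comparison table: one row per species, percent columns
    rounded to 2 decimals, sorted by range change ascending."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "species": s.species_id,
                "current": s.current_size,
                "future": s.future_size,
                "loss": s.loss,
                "gain": s.gain,
                "maintain": s.maintain,
                "percent_lost": round(s.percent_lost, 2),
                "percent_gained": round(s.percent_gained, 2),
                "range_change": round(s.range_change, 2),
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df.sort_values("range_change", kind="stable").reset_index(drop=True)


def load_published_range_changes() -> pd.DataFrame:
    """Published pixel-accounting reference table: the 21 western North
    American squamate species projected to contract (lose >= 10% of
    suitable climate space with > 50% turnover) between the recent and
    late-century high-emission scenarios, with printed percentages."""
    ref = importlib.resources.files("climniche.data") / "published_range_changes.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
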