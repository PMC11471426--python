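"""Synthetic study systems: climate grids, virtual species, occurrences.

Everything downstream of raw data acquisition (QC, niche modelling,
projection, range-change accounting, jurisdiction summaries) is exercised
against data generated here: spatially autocorrelated monthly climate
surfaces under six time-by-climate scenarios, an elevation model coupled
to temperature through a lapse rate, Voronoi jurisdictions, virtual
species with known bell-shaped climate responses, and occurrence samples
drawn proportionally to true suitability with controllable data defects
(duplicate cells, missing years, centroid-snapped coordinates, far
outliers).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint

from .grid import CLIMATE_VARIABLES, SCENARIOS, ClimateGrid

__all__ = [
    "GridConfig",
    "ScenarioDelta",
    "VirtualSpecies",
    "JurisdictionSet",
    "generate_climate_grids",
    "generate_jurisdictions",
    "true_suitability",
    "make_virtual_species",
    "cold_limited_species",
    "sample_occurrences",
]

YEAR_WINDOW = (1981, 2018)
SOURCES = ("museum", "agency", "community")


class ConfigurationError(ValueError):
    """Raised when a generator config is out of its valid domain."""


@dataclass(frozen=True)
class ScenarioDelta:
    """Climate delta of a scenario relative to the recent baseline."""

    temp_offset: float = 0.0  # deg C, added to every monthly temperature
    prec_multiplier: float = 1.0  # applied to every monthly precipitation


def _default_scenarios() -> dict[str, ScenarioDelta]:
    # Warming magnitudes follow the usual moderate/high-emission spread:
    # a cooler past baseline, ~+1.5-2 C by mid-century and ~+2-3 C by
    # late century, with mild drying under the high-emission pathway.
    return {
        "past": ScenarioDelta(-1.0, 1.0),
        "recent": ScenarioDelta(0.0, 1.0),
        "mid45": ScenarioDelta(1.5, 0.97),
        "mid85": ScenarioDelta(2.0, 0.95),
        "late45": ScenarioDelta(2.0, 0.95),
        "late85": ScenarioDelta(3.0, 0.90),
    }


@dataclass
class GridConfig:
    """Parameters of the synthetic climate-grid generator.

    Distances are km, temperatures deg C, precipitation mm/month,
    elevation m.  ``autocorr_length`` is the Gaussian smoothing length
    of the random fields, so neighbouring cells carry correlated
    climate, as real interpolated climate surfaces do.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    autocorr_length: float = 10.0
    mean_temp: float = 8.0
    seasonal_amplitude: float = 12.0
    lat_gradient: float = 0.05  # deg C lost per km northward
    lapse_rate: float = 6.5  # deg C lost per km of elevation
    temp_noise_sd: float = 2.0
    temp_month_noise_sd: float = 0.8
    base_prec: float = 60.0
    prec_seasonality: float = 0.5  # winter-wet annual cycle strength
    prec_noise_sd: float = 0.5
    prec_month_noise_sd: float = 0.3
    elev_base: float = 500.0
    elev_relief: float = 800.0
    elev_north_slope: float = 3.0  # m gained per km northward
    scenarios: dict[str, ScenarioDelta] = field(default_factory=_default_scenarios)

    def validate(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ConfigurationError("grid must be at least 10x10")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.autocorr_length <= 0:
            raise ConfigurationError("autocorrelation length must be positive")
        for sid, delta in self.scenarios.items():
            if sid not in SCENARIOS:
                raise ConfigurationError(f"unknown scenario {sid!r}")
            if not math.isfinite(delta.temp_offset):
                raise ConfigurationError(f"non-finite temperature offset for {sid}")
            if delta.prec_multiplier < 0:
                raise ConfigurationError(f"negative precipitation multiplier for {sid}")


def _smooth_field(shape, length_cells, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with the given smoothing length."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=length_cells, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_climate_grids(
    config: GridConfig | None = None, seed: int = 0
) -> dict[str, ClimateGrid]:
    """Generate one :class:`ClimateGrid` per scenario.

    The recent scenario is the baseline: smooth random temperature
    fields with a sinusoidal annual cycle (winter colder than summer),
    a south-to-north cooling gradient and an elevational lapse rate;
    precipitation is log-normal-smooth with a winter-wet cycle.  Every
    other scenario applies its configured constant temperature offset
    and precipitation multiplier to the baseline, so scenario contrasts
    are exact by construction.
    """
    config = config or GridConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    shape = (config.n_rows, config.n_cols)
    sigma = config.autocorr_length / config.cell_size

    elev = (
        config.elev_base
        + config.elev_relief * _smooth_field(shape, sigma, rng)
    )
    # northward rise: row 0 is the north edge
    northing = (config.n_rows - np.arange(config.n_rows) - 0.5) * config.cell_size
    elev = elev + config.elev_north_slope * northing[:, None]
    elev = np.maximum(elev, 0.0)

    t_annual = _smooth_field(shape, sigma, rng)
    p_annual = _smooth_field(shape, sigma, rng)
    t_month = [_smooth_field(shape, sigma, rng) for _ in range(12)]
    p_month = [_smooth_field(shape, sigma, rng) for _ in range(12)]

    recent: dict[str, np.ndarray] = {}
    for m in range(1, 13):
        season = -np.cos(2 * np.pi * (m - 1) / 12)  # -1 in Jan, +1 in Jul
        tmean = (
            config.mean_temp
            + config.seasonal_amplitude * season
            - config.lat_gradient * northing[:, None]
            - config.lapse_rate * elev / 1000.0
            + config.temp_noise_sd * t_annual
            + config.temp_month_noise_sd * t_month[m - 1]
        )
        prec = config.base_prec * np.exp(
            config.prec_noise_sd * p_annual
            + config.prec_month_noise_sd * p_month[m - 1]
        ) * (1.0 + config.prec_seasonality * -season)
        recent[f"tmean_{m:02d}"] = tmean
        recent[f"prec_{m:02d}"] = prec

    grids: dict[str, ClimateGrid] = {}
    for sid in SCENARIOS:
        if sid not in config.scenarios:
            continue
        delta = config.scenarios[sid]
        layers = {}
        for m in range(1, 13):
            layers[f"tmean_{m:02d}"] = recent[f"tmean_{m:02d}"] + delta.temp_offset
            layers[f"prec_{m:02d}"] = recent[f"prec_{m:02d}"] * delta.prec_multiplier
        grids[sid] = ClimateGrid(
            scenario_id=sid,
            cell_size=config.cell_size,
            origin=config.origin,
            layers=layers,
            elevation=elev.copy(),
        )
    return grids


# ---------------------------------------------------------------------------
# virtual species


@dataclass
class VirtualSpecies:
    """A species with a known climate niche.

    Suitability is the product of bell-shaped (Gaussian) responses, one
    per selected climate variable: 1 at the joint optimum, decreasing
    with distance from each optimum.  ``prevalence_target`` fixes the
    fraction of recent-scenario cells counted as truly suitable, which
    defines the ground-truth mask recovery tests compare against.
    """

    species_id: str
    responses: dict[str, tuple[float, float]]  # variable -> (optimum, breadth)
    prevalence_target: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence_target < 1:
            raise ConfigurationError("prevalence_target must be in (0, 1)")
        for var, (_, breadth) in self.responses.items():
            if breadth <= 0:
                raise ConfigurationError(f"breadth for {var} must be positive")

    def suitability(self, grid: ClimateGrid) -> np.ndarray:
        return true_suitability(self, grid)

    def suitability_threshold(self, reference: ClimateGrid) -> float:
        """Suitability cut such that ``prevalence_target`` of the
        reference grid's cells are suitable."""
        s = self.suitability(reference)
        return float(np.quantile(s, 1.0 - self.prevalence_target))

    def true_mask(
        self, grid: ClimateGrid, reference: ClimateGrid | None = None
    ) -> np.ndarray:
        thr = self.suitability_threshold(reference if reference is not None else grid)
        return self.suitability(grid) >= thr


def true_suitability(species: VirtualSpecies, grid: ClimateGrid) -> np.ndarray:
    """Ground-truth suitability in [0, 1] for every grid cell."""
    s = np.ones(grid.shape)
    for var, (opt, breadth) in species.responses.items():
        if var not in grid.layers:
            raise KeyError(f"response variable {var!r} not present in grid")
        z = (grid.layers[var] - opt) / breadth
        s = s * np.exp(-0.5 * z * z)
    return s


def make_virtual_species(
    reference: ClimateGrid,
    species_id: str = "virtualis",
    variables: tuple[str, ...] = ("tmean_01", "prec_06"),
    optimum_quantiles: tuple[float, ...] = (0.5, 0.5),
    breadth_fraction: float = 0.25,
    prevalence_target: float = 0.15,
    seed: int = 0,
) -> VirtualSpecies:
    """Build a virtual species whose optima sit at given quantiles of the
    reference grid's variable distributions (breadth = fraction of the
    variable's spatial SD)."""
    responses = {}
    for var, q in zip(variables, optimum_quantiles):
        vals = reference.layers[var]
        responses[var] = (float(np.quantile(vals, q)), float(breadth_fraction * vals.std()))
    return VirtualSpecies(
        species_id=species_id,
        responses=responses,
        prevalence_target=prevalence_target,
        seed=seed,
    )


def cold_limited_species(
    reference: ClimateGrid,
    species_id: str = "frigidicola",
    temp_variable: str = "tmean_07",
    optimum_quantile: float = 0.15,
    breadth_fraction: float = 0.25,
    prevalence_target: float = 0.15,
    seed: int = 0,
) -> VirtualSpecies:
    """A species whose optimum sits in the cold tail of a temperature
    variable; under warming its suitable space moves north and upslope."""
    return make_virtual_species(
        reference,
        species_id=species_id,
        variables=(temp_variable,),
        optimum_quantiles=(optimum_quantile,),
        breadth_fraction=breadth_fraction,
        prevalence_target=prevalence_target,
        seed=seed,
    )


def directional_recovery_config(n_rows: int = 150, n_cols: int = 100) -> GridConfig:
    """Grid config for directional range-shift experiments: a domain
    rising steadily northward (10 m/km) with modest relief noise, so a
    warming offset pushes a cold-limited species' suitable space both
    north and measurably upslope (the temperature field couples to
    elevation through the lapse rate).  Precipitation is held at the
    baseline in every scenario so the experiment isolates the warming
    signal."""
    scenarios = {
        sid: ScenarioDelta(delta.temp_offset, 1.0)
        for sid, delta in _default_scenarios().items()
    }
    return GridConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        lat_gradient=0.03,
        elev_base=300.0,
        elev_relief=100.0,
        elev_north_slope=10.0,
        scenarios=scenarios,
        # temperature here is almost fully determined by latitude and
        # topography (as in lapse-rate-interpolated climatologies), so
        # a thermal niche maps onto a narrow elevation band
        temp_noise_sd=0.8,
        temp_month_noise_sd=0.4,
    )


# ---------------------------------------------------------------------------
# jurisdictions


@dataclass
class JurisdictionSet:
    """Named, non-overlapping regions tiling the grid (Voronoi partition
    of random seed points), with one centroid per region."""

    names: list[str]
    seed_points: np.ndarray  # (k, 2) xy
    labels: np.ndarray  # (n_rows, n_cols) int index into names
    centroids: np.ndarray  # (k, 2) mean of member cell centers
    cell_size: float
    origin: tuple[float, float]

    @property
    def n_jurisdictions(self) -> int:
        return len(self.names)

    def mask(self, name_or_index) -> np.ndarray:
        idx = (
            self.names.index(name_or_index)
            if isinstance(name_or_index, str)
            else int(name_or_index)
        )
        return self.labels == idx


def generate_jurisdictions(
    grid: ClimateGrid, n_jurisdictions: int = 9, seed: int = 0
) -> JurisdictionSet:
    """Voronoi-partition the grid into irregular state-like regions."""
    if n_jurisdictions < 1:
        raise ConfigurationError("need at least one jurisdiction")
    rng = np.random.default_rng(seed)
    x0, y0 = grid.origin
    w = grid.n_cols * grid.cell_size
    h = grid.n_rows * grid.cell_size
    pts = np.column_stack(
        [x0 + rng.uniform(0, w, n_jurisdictions), y0 + rng.uniform(0, h, n_jurisdictions)]
    )
    X, Y = grid.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    d2 = ((centers[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    # drop any region that captured no cells, relabelling compactly
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    labels = np.vectorize(remap.get)(labels)
    pts = pts[used]
    names = [f"state_{i:02d}" for i in range(len(used))]
    centroids = np.array(
        [centers[labels == i].mean(axis=0) for i in range(len(used))]
    )
    return JurisdictionSet(
        names=names,
        seed_points=pts,
        labels=labels.reshape(grid.shape),
        centroids=centroids,
        cell_size=grid.cell_size,
        origin=grid.origin,
    )


# ---------------------------------------------------------------------------
# occurrence sampling

ARTIFACT_KINDS = ("duplicate", "missing_year", "centroid_snap", "far_outlier")


def sample_occurrences(
    species: VirtualSpecies,
    grid: ClimateGrid,
    n: int,
    artifact_rates: dict[str, float] | None = None,
    seed: int = 0,
    jurisdictions: JurisdictionSet | None = None,
) -> pd.DataFrame:
    """Sample occurrence records proportional to true suitability, with
    optional injected data defects.

    Returns a DataFrame with columns ``species, x, y, year, source,
    artifact`` — the ``artifact`` column carries the injected-defect
    label ('none' for clean records) so QC filters can be validated
    against known ground truth.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rates = dict.fromkeys(ARTIFACT_KINDS, 0.0)
    rates.update(artifact_rates or {})
    unknown = set(rates) - set(ARTIFACT_KINDS)
    if unknown:
        raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
    vals = np.array([rates[k] for k in ARTIFACT_KINDS])
    if np.any(vals < 0) or np.any(vals > 1) or vals.sum() > 1:
        raise ValueError("artifact rates must lie in [0,1] and sum to at most 1")
    if rates["centroid_snap"] > 0 and jurisdictions is None:
        raise ValueError("centroid_snap artifacts require a JurisdictionSet")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, np.append(vals, 1.0 - vals.sum()))
    n_dup, n_noyear, n_snap, n_far, n_clean = counts

    suit = species.suitability(grid).ravel()
    total = suit.sum()
    if total <= 0:
        raise ValueError("species has zero suitability everywhere on this grid")
    p = suit / total
    X, Y = grid.cell_centers()
    cx, cy = X.ravel(), Y.ravel()
    half = grid.cell_size / 2.0

    def _place(cells):
        jx = rng.uniform(-half, half, len(cells))
        jy = rng.uniform(-half, half, len(cells))
        return cx[cells] + jx, cy[cells] + jy

    def _years(k):
        return rng.integers(YEAR_WINDOW[0], YEAR_WINDOW[1] + 1, k).astype(float)

    def _sources(k):
        return rng.choice(SOURCES, k)

    rows = []

    clean_cells = rng.choice(grid.n_cells, size=n_clean, p=p)
    xs, ys = _place(clean_cells)
    for x, y, yr, src in zip(xs, ys, _years(n_clean), _sources(n_clean)):
        rows.append((species.species_id, x, y, yr, src, "none"))

    # duplicates share a grid cell with an existing (or fresh) clean record
    dup_base = (
        rng.choice(clean_cells, size=n_dup)
        if n_clean > 0
        else rng.choice(grid.n_cells, size=n_dup, p=p)
    )
    xs, ys = _place(dup_base)
    for x, y, yr, src in zip(xs, ys, _years(n_dup), _sources(n_dup)):
        rows.append((species.species_id, x, y, yr, src, "duplicate"))

    noyear_cells = rng.choice(grid.n_cells, size=n_noyear, p=p)
    xs, ys = _place(noyear_cells)
    for x, y, src in zip(xs, ys, _sources(n_noyear)):
        rows.append((species.species_id, x, y, np.nan, src, "missing_year"))

    if n_snap:
        which = rng.integers(0, jurisdictions.n_jurisdictions, n_snap)
        r = 0.3 * np.sqrt(rng.uniform(0, 1, n_snap))  # within 300 m, km units
        th = rng.uniform(0, 2 * np.pi, n_snap)
        xs = jurisdictions.centroids[which, 0] + r * np.cos(th)
        ys = jurisdictions.centroids[which, 1] + r * np.sin(th)
        for x, y, yr, src in zip(xs, ys, _years(n_snap), _sources(n_snap)):
            rows.append((species.species_id, x, y, yr, src, "centroid_snap"))

    if n_far:
        mask = species.true_mask(grid)
        pts = np.column_stack([X[mask], Y[mask]])
        hull = MultiPoint([tuple(pt) for pt in pts[:: max(1, len(pts) // 500)]]).convex_hull
        hc = np.array(hull.centroid.coords[0])
        radius = max(
            np.hypot(pts[:, 0] - hc[0], pts[:, 1] - hc[1]).max(), grid.cell_size
        )
        th = rng.uniform(0, 2 * np.pi, n_far)
        d = radius + 200.0 + rng.uniform(0, 100.0, n_far)
        xs = hc[0] + d * np.cos(th)
        ys = hc[1] + d * np.sin(th)
        for x, y, yr, src in zip(xs, ys, _years(n_far), _sources(n_far)):
            rows.append((species.species_id, x, y, yr, src, "far_outlier"))

    df = pd.DataFrame(rows, columns=["species", "x", "y", "year", "source", "artifact"])
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)
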