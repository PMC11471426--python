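"""Scenario projection and binarization of fitted ensembles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import CLIMATE_VARIABLES, ClimateGrid

__all__ = ["SuitabilityMap", "BinaryNicheMap", "project", "binarize"]


@dataclass
class SuitabilityMap:
    """Continuous ensemble suitability for one species on one scenario."""

    species_id: str
    scenario_id: str
    values: np.ndarray  # (n_rows, n_cols) in [0, 1]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class BinaryNicheMap:
    """Thresholded suitability: the species' climate-niche space."""

    species_id: str
    scenario_id: str
    mask: np.ndarray  # boolean
    threshold: float
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def range_size(self) -> int:
        """Count of suitable cells."""
        return int(self.mask.sum())


def project(results, grid: ClimateGrid) -> SuitabilityMap:
    """Project a fitted ensemble onto a scenario grid.

    The per-cell prediction is the TSS-weighted mean of the member
    models' suitabilities; the operation is deterministic and
    cell-order equivariant.
    """
    missing = [v for v in CLIMATE_VARIABLES if v not in grid.layers]
    if missing:
        raise ValueError(f"grid is missing climate layers: {missing}")
    values = results.predict(grid.feature_matrix()).reshape(grid.shape)
    return SuitabilityMap(
        species_id=results.species_id,
        scenario_id=grid.scenario_id,
        values=values,
        cell_size=grid.cell_size,
        origin=grid.origin,
    )


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryNicheMap:
    """Binarize at the given threshold (suitable iff value >= threshold).

    The threshold is chosen once per species, from recent-scenario
    held-out evaluation, and reused for every scenario so maps are
    comparable across time.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return BinaryNicheMap(
        species_id=smap.species_id,
        scenario_id=smap.scenario_id,
        mask=smap.values >= threshold,
        threshold=threshold,
        cell_size=smap.cell_size,
        origin=smap.origin,
    )
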