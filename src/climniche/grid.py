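"""Climate grid container.

A :class:`ClimateGrid` holds one scenario's stack of 24 monthly climate
layers (12 mean temperatures in degrees C, 12 mean precipitations in mm)
plus an elevation layer, on a common planar equal-area grid whose
coordinates are expressed in kilometres.  Row 0 is the northernmost row
(raster convention); y increases northward, x eastward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCENARIOS = ("past", "recent", "mid45", "mid85", "late45", "late85")

TEMP_VARIABLES = tuple(f"tmean_{m:02d}" for m in range(1, 13))
PREC_VARIABLES = tuple(f"prec_{m:02d}" for m in range(1, 13))
CLIMATE_VARIABLES = TEMP_VARIABLES + PREC_VARIABLES


@dataclass
class ClimateGrid:
    """One scenario's climate stack on a planar km grid.

    Parameters
    ----------
    scenario_id
        One of ``past, recent, mid45, mid85, late45, late85``.
    cell_size
        Cell edge length in km (1.0 emulates a 1-km grid).
    origin
        ``(x0, y0)`` of the grid's lower-left (south-west) corner, km.
    layers
        Mapping of the 24 variable names to ``(n_rows, n_cols)`` arrays.
    elevation
        Elevation layer in metres, same shape.
    """

    scenario_id: str
    cell_size: float
    origin: tuple[float, float]
    layers: dict[str, np.ndarray]
    elevation: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.scenario_id not in SCENARIOS:
            raise ValueError(
                f"scenario_id must be one of {SCENARIOS}, got {self.scenario_id!r}"
            )
        missing = [v for v in CLIMATE_VARIABLES if v not in self.layers]
        if missing:
            raise ValueError(f"missing climate layers: {missing}")
        shapes = {v: np.asarray(a).shape for v, a in self.layers.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError("all climate layers must share one shape")
        if self.elevation is None:
            self.elevation = np.zeros(first)
        if self.elevation.shape != first:
            raise ValueError("elevation shape does not match climate layers")
        for v in PREC_VARIABLES:
            if np.any(self.layers[v] < 0):
                raise ValueError(f"negative precipitation in layer {v}")

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[CLIMATE_VARIABLES[0]].shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` arrays of cell-center coordinates in km."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cell_size
        # row 0 is the top (north), so its center has the largest y
        y = y0 + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); points may fall off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((y - y0) / self.cell_size).astype(int)
        return row, col

    def in_extent(self, x, y) -> np.ndarray:
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_index(self, x, y) -> np.ndarray:
        """Flat cell index for point coordinates (caller checks extent)."""
        row, col = self.xy_to_rowcol(x, y)
        return row * self.n_cols + col

    # -- features -----------------------------------------------------

    def feature_matrix(self, cells: np.ndarray | None = None) -> np.ndarray:
        """Stack the 24 climate layers into an ``(n, 24)`` matrix.

        ``cells`` selects flat cell indices; ``None`` means every cell,
        in row-major order matching :meth:`cell_centers`.
        """
        flat = np.column_stack(
            [np.asarray(self.layers[v], dtype=float).ravel() for v in CLIMATE_VARIABLES]
        )
        if cells is None:
            return flat
        return flat[np.asarray(cells)]

    def layer(self, name: str) -> np.ndarray:
        if name == "elevation":
            return self.elevation
        if name not in self.layers:
            raise KeyError(f"variable {name!r} not present in grid")
        return self.layers[name]
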