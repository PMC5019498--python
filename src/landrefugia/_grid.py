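"""Regular lat/lon analysis grid shared by the synthetic generator and raster I/O.

Conventions used throughout the package:

* rasters are north-up: row 0 is the northernmost band, latitude decreases
  with row index, longitude increases with column index;
* all tables and stacks refer to cell CENTERS in WGS84 degrees;
* cell edges fall on integer multiples of ``cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DomainSpec", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a domain, rule set or scenario is internally inconsistent."""


def _is_multiple(value: float, step: float, tol: float = 1e-9) -> bool:
    r = value / step
    return abs(r - round(r)) < tol


@dataclass(frozen=True)
class DomainSpec:
    """A rectangular lat/lon domain discretized into square cells.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max
        Domain bounds in degrees; edges, not centers.
    cell_size
        Cell edge length in degrees (default 0.5).
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float = 0.5

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be positive, got {self.cell_size}")
        if self.lat_max <= self.lat_min:
            raise ConfigurationError("lat_max must exceed lat_min")
        if self.lon_max <= self.lon_min:
            raise ConfigurationError("lon_max must exceed lon_min")
        for name in ("lat_min", "lat_max", "lon_min", "lon_max"):
            if not _is_multiple(getattr(self, name), self.cell_size):
                raise ConfigurationError(
                    f"{name}={getattr(self, name)} is not aligned to cell_size={self.cell_size}"
                )

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.cell_size)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.cell_size)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south (descending)."""
        half = self.cell_size / 2.0
        return self.lat_max - half - self.cell_size * np.arange(self.n_rows)

    @property
    def lon_centers(self) -> np.ndarray:
        """Longitudes of column centers, west to east (ascending)."""
        half = self.cell_size / 2.0
        return self.lon_min + half + self.cell_size * np.arange(self.n_cols)

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) 2-D arrays of cell-center coordinates, shape ``self.shape``."""
        lat = np.repeat(self.lat_centers[:, None], self.n_cols, axis=1)
        lon = np.repeat(self.lon_centers[None, :], self.n_rows, axis=0)
        return lat, lon

    def cell_ids(self) -> np.ndarray:
        """Row-major cell identifiers, shape ``self.shape``."""
        return np.arange(self.n_cells).reshape(self.shape)

    def refine(self, k: int) -> "DomainSpec":
        """The same domain at ``k``-fold finer resolution."""
        if k < 1 or int(k) != k:
            raise ConfigurationError(f"refinement factor must be a positive integer, got {k}")
        return DomainSpec(
            self.lat_min, self.lat_max, self.lon_min, self.lon_max, self.cell_size / k
        )
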