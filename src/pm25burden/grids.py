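"""Regular lat/lon grids and scalar fields defined on them.

The exposure and burden calculations only need a horizontal surface grid
with per-cell areas.  Cells are laid out on a regular latitude/longitude
mesh; the area of a cell scales with the cosine of its centre latitude,
so areas shrink towards the poles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon grid.

    Parameters
    ----------
    n_lat, n_lon
        Number of cells along each axis (>= 1).
    lat_min, lat_max, lon_min, lon_max
        Outer edges of the grid, in degrees.
    """

    n_lat: int
    n_lon: int
    lat_min: float = 6.0
    lat_max: float = 36.0
    lon_min: float = 68.0
    lon_max: float = 98.0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one cell per axis")
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("grid bounds must be strictly ordered")
        if self.lat_min < -90 or self.lat_max > 90:
            raise ValueError("latitudes must lie in [-90, 90]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_lat

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_lon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.dlat

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.dlon

    def cell_areas(self) -> np.ndarray:
        """Cell areas in km^2, shape (n_lat, n_lon).

        Spherical-cap strip formula per latitude band; areas are strictly
        positive and decrease with |latitude|.
        """
        lat0 = np.deg2rad(self.lat_min + np.arange(self.n_lat) * self.dlat)
        lat1 = lat0 + np.deg2rad(self.dlat)
        strip = EARTH_RADIUS_KM**2 * np.deg2rad(self.dlon) * (np.sin(lat1) - np.sin(lat0))
        return np.repeat(strip[:, None], self.n_lon, axis=1)


@dataclass
class GriddedField:
    """A 2-D scalar raster (concentration in ug m^-3 or population counts).

    Values must be finite, non-negative and match the grid shape.
    """

    values: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.spec.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if np.any(self.values < 0):
            raise ValueError("field values must be non-negative")

    def copy_with(self, values: np.ndarray) -> "GriddedField":
        return GriddedField(np.asarray(values, dtype=float), self.spec)

    @property
    def shape(self) -> tuple[int, int]:
        return self.spec.shape

    def total(self) -> float:
        return float(self.values.sum())
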