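"""Regular longitude-latitude grids and spherical geometry.

All gridded products in this package live on a regular lon-lat grid with
cell-center registration: the value at index ``[row, col]`` (row = latitude,
col = longitude, 0-based) describes the cell whose center is
``(lat0 + row*dlat, lon0 + col*dlon)``.  Distances use the haversine formula
on a sphere of radius 6371 km; cell areas use the exact spherical
quadrilateral formula, so area depends on latitude but not longitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon-lat grid (cell-center registration).

    Parameters
    ----------
    lon0, lat0 : float
        Center of cell ``[0, 0]`` in decimal degrees (WGS-84).
    dlon, dlat : float
        Cell width/height in degrees; must be positive.
    nlon, nlat : int
        Number of columns (longitude) and rows (latitude); at least 8 each.
    """

    lon0: float
    lat0: float
    dlon: float
    dlat: float
    nlon: int
    nlat: int

    def __post_init__(self):
        if self.dlon <= 0 or self.dlat <= 0:
            raise ValueError("grid spacing must be positive")
        if self.nlon < 8 or self.nlat < 8:
            raise ValueError("grid must be at least 8x8 cells")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    def lons(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.nlon)

    def lats(self) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(self.nlat)

    def locate(self, lon, lat):
        """Map coordinates to (row, col) cell indices by nearest center.

        Points outside the grid get index -1 in the offending dimension.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.rint((lon - self.lon0) / self.dlon).astype(int)
        row = np.rint((lat - self.lat0) / self.dlat).astype(int)
        col = np.where((col >= 0) & (col < self.nlon), col, -1)
        row = np.where((row >= 0) & (row < self.nlat), row, -1)
        return row, col

    def contains(self, lon, lat):
        row, col = self.locate(lon, lat)
        return (row >= 0) & (col >= 0)

    def cell_center(self, row, col):
        return self.lon0 + self.dlon * np.asarray(col), self.lat0 + self.dlat * np.asarray(row)

    def cell_area_km2(self) -> np.ndarray:
        """Per-row cell area, km^2: R^2 * dlambda * (sin(phi2) - sin(phi1))."""
        lats = self.lats()
        phi1 = np.radians(lats - self.dlat / 2.0)
        phi2 = np.radians(lats + self.dlat / 2.0)
        dlam = np.radians(self.dlon)
        return EARTH_RADIUS_KM**2 * dlam * (np.sin(phi2) - np.sin(phi1))

    def area_grid_km2(self) -> np.ndarray:
        """(nlat, nlon) array of cell areas."""
        return np.repeat(self.cell_area_km2()[:, None], self.nlon, axis=1)

    def center_distance_km(self, lon: float, lat: float) -> np.ndarray:
        """Haversine distance from every cell center to (lon, lat)."""
        glon, glat = np.meshgrid(self.lons(), self.lats())
        return haversine_km(glon, glat, lon, lat)
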