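"""Gridded environmental archive: static bathymetry plus weekly ocean fields.

The archive emulates a regridded regional ocean-model product: a regular
lon-lat grid carrying static bathymetry, weekly-averaged bottom/surface
temperature and depth-integrated plankton biomasses, and a yearly Apr-Jul
mean large-phytoplankton field.  Habitat is a pure function of bathymetry
(shelf where depth <= 200 m, basin where > 200 m); a "mismatch" mask marks
cells where the model bathymetry says basin but the true sea floor is shelf,
an artifact of bathymetric smoothing in terrain-following ocean models.

Weekly calendar convention: 52 weeks per year, week 1 starting Jan 1; the
center of week ``w`` is Jan 1 + 7*(w-1) + 3.5 days.  Apr-Jul = weeks 14-30,
Jul-Oct = weeks 27-44.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

SHELF_MAX_DEPTH_M = 200.0
WEEKLY_VARS = ("temp_bottom", "temp_surface", "phl", "ncao_ncas", "eup")
BIOMASS_VARS = ("phl", "ncao_ncas", "eup", "phl_avg")
COVARIATES = ("bathymetry", "temp_bottom", "temp_surface", "phl", "phl_avg", "ncao_ncas", "eup")
STATIC_VARS = ("bathymetry",)
APR_JUL_WEEKS = tuple(range(14, 31))
JUL_OCT_WEEKS = tuple(range(27, 45))

UNITS = {
    "bathymetry": "m",
    "temp_bottom": "degC",
    "temp_surface": "degC",
    "phl": "mg C m-2",
    "phl_avg": "mg C m-2",
    "ncao_ncas": "mg C m-2",
    "eup": "mg C m-2",
}


def week_center(year, week):
    """Datetime of the center of a weekly bin (week 1 starts Jan 1)."""
    base = pd.Timestamp(int(year), 1, 1)
    return base + pd.Timedelta(days=7 * (int(week) - 1) + 3, hours=12)


def nearest_week(timestamps, n_weeks: int):
    """Nearest weekly bin (1-based) for each timestamp, within its own year.

    Ties between two bin centers resolve to the earlier bin.
    """
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)).reset_index(drop=True))
    years = ts.dt.year
    start = pd.to_datetime(dict(year=years, month=1, day=1))
    hours = (ts - start) / pd.Timedelta(hours=1)
    # bin centers (hours since Jan 1): 168*(w-1) + 84
    w = np.floor((hours.to_numpy() - 84.0) / 168.0) + 1  # last center <= t
    w = np.clip(w, 1, n_weeks)
    w_next = np.clip(w + 1, 1, n_weeks)
    d_lo = np.abs(hours.to_numpy() - (168.0 * (w - 1) + 84.0))
    d_hi = np.abs(hours.to_numpy() - (168.0 * (w_next - 1) + 84.0))
    out = np.where(d_hi < d_lo, w_next, w)  # tie -> earlier (w)
    return out.astype(int)


@dataclass
class EnvArchive:
    """Environmental archive on a regular lon-lat grid.

    Wraps an :class:`xarray.Dataset` with dims ``(year, week, lat, lon)`` for
    weekly variables, ``(lat, lon)`` for bathymetry and the mismatch mask, and
    ``(year, lat, lon)`` for the yearly Apr-Jul phytoplankton mean.
    """

    grid: GridSpec
    ds: xr.Dataset

    # -- masks -----------------------------------------------------------
    @property
    def bathymetry(self) -> np.ndarray:
        return self.ds["bathymetry"].values

    @property
    def shelf_mask(self) -> np.ndarray:
        """True where depth <= 200 m (the shelf rule)."""
        return self.bathymetry <= SHELF_MAX_DEPTH_M

    @property
    def basin_mask(self) -> np.ndarray:
        return ~self.shelf_mask

    @property
    def mismatch_mask(self) -> np.ndarray:
        """Model-says-basin but truth-says-shelf cells."""
        return self.ds["mismatch"].values.astype(bool)

    def habitat_of(self, row, col):
        """'shelf' or 'basin' per cell index (vectorized)."""
        shelf = self.shelf_mask[np.asarray(row), np.asarray(col)]
        return np.where(shelf, "shelf", "basin")

    # -- field access ----------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return self.ds["year"].values

    @property
    def weeks(self) -> np.ndarray:
        return self.ds["week"].values

    def weekly(self, var: str, year: int, week: int) -> np.ndarray:
        """(nlat, nlon) weekly field; KeyError naming the bin if absent."""
        if var not in self.ds:
            raise KeyError(f"unknown variable {var!r}")
        if int(year) not in self.ds["year"].values or int(week) not in self.ds["week"].values:
            raise KeyError(f"missing weekly bin (year={year}, week={week}) for {var!r}")
        return self.ds[var].sel(year=int(year), week=int(week)).values

    def phl_avg(self, year: int) -> np.ndarray:
        if int(year) not in self.ds["year"].values:
            raise KeyError(f"missing year {year} for 'phl_avg'")
        return self.ds["phl_avg"].sel(year=int(year)).values

    # -- I/O -------------------------------------------------------------
    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        for name, units in UNITS.items():
            if name in ds:
                ds[name].attrs["units"] = units
        ds.attrs.update(
            grid_lon0=self.grid.lon0, grid_lat0=self.grid.lat0,
            grid_dlon=self.grid.dlon, grid_dlat=self.grid.dlat,
            grid_nlon=self.grid.nlon, grid_nlat=self.grid.nlat,
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvArchive":
        ds = xr.load_dataset(path, engine="scipy")
        a = ds.attrs
        grid = GridSpec(
            lon0=float(a["grid_lon0"]), lat0=float(a["grid_lat0"]),
            dlon=float(a["grid_dlon"]), dlat=float(a["grid_dlat"]),
            nlon=int(a["grid_nlon"]), nlat=int(a["grid_nlat"]),
        )
        return cls(grid=grid, ds=ds)

    def validate(self) -> None:
        """Check archive invariants; raises ValueError on violation."""
        if (self.bathymetry < 0).any():
            raise ValueError("bathymetry must be non-negative")
        for var in BIOMASS_VARS:
            if var in self.ds and (self.ds[var].values < 0).any():
                raise ValueError(f"biomass field {var!r} has negative values")
        for var in WEEKLY_VARS:
            if var not in self.ds:
                raise ValueError(f"weekly variable {var!r} missing")
            if np.isnan(self.ds[var].values).any():
                raise ValueError(f"weekly variable {var!r} has missing bins")
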