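"""Suitability surfaces and core-habitat maps.

Weekly surfaces are ensemble-mean probabilities of occurrence per grid cell;
the shelf model predicts shelf cells (plus the bathymetric-mismatch zone),
the basin model basin cells, and predictions are averaged in the mismatch
zone.  Surfaces average across weeks/years (all, warm or cold year sets),
are cropped to an accessibility circle around the rookeries, and core
habitat is the top 25% quantile of each model's hindcast-mean surface
(mismatch cells judged against the average of the two thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .env import JUL_OCT_WEEKS, EnvArchive
from .grid import GridSpec

# Shelf-temperature regime years used for composite surfaces.
WARM_YEARS = (1993, 1998, 2001, 2002, 2003, 2004, 2005, 2014, 2015, 2016, 2018)
COLD_YEARS = (1992, 1994, 1995, 1997, 1999, 2007, 2008, 2009, 2010, 2012, 2013)


@dataclass
class SuitabilitySurface:
    """Per-cell probability of occurrence; NaN where undefined."""

    grid: GridSpec
    values: np.ndarray  # (nlat, nlon), in [0, 1] or NaN
    provenance: dict = field(default_factory=dict)

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def copy_with(self, values, **prov) -> "SuitabilitySurface":
        return SuitabilitySurface(self.grid, values, {**self.provenance, **prov})

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {"suitability": (("lat", "lon"), self.values.astype(np.float32))},
            coords={"lat": self.grid.lats(), "lon": self.grid.lons()},
        )
        ds.attrs.update({k: str(v) for k, v in self.provenance.items()})
        ds.to_netcdf(path, engine="scipy")

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = ax.pcolormesh(self.grid.lons(), self.grid.lats(), self.values,
                          vmin=0, vmax=1, **kw)
        plt.colorbar(m, ax=ax, label="P(occurrence)")
        return ax


@dataclass
class CoreHabitatMap:
    """Boolean core mask plus thresholds and spherical area."""

    grid: GridSpec
    core: np.ndarray               # (nlat, nlon) bool
    thresholds: dict               # e.g. {'shelf': tau_s, 'basin': tau_b, 'mismatch': mean}
    area_km2: float

    @classmethod
    def from_mask(cls, grid: GridSpec, core: np.ndarray, thresholds=None) -> "CoreHabitatMap":
        area = float(grid.area_grid_km2()[core].sum())
        return cls(grid=grid, core=core.astype(bool), thresholds=thresholds or {}, area_km2=area)


def _covariate_matrix(env: EnvArchive, year: int, week: int, variables, cells) -> np.ndarray:
    r, c = cells
    cols = []
    for var in variables:
        if var == "bathymetry":
            cols.append(env.bathymetry[r, c])
        elif var == "phl_avg":
            cols.append(env.phl_avg(year)[r, c])
        else:
            cols.append(env.weekly(var, year, week)[r, c])
    return np.column_stack(cols)


def predict_weekly(results, env: EnvArchive, year: int, week: int,
                   habitat: str | None = None) -> SuitabilitySurface:
    """Ensemble-mean suitability surface for one weekly bin.

    Cells outside the model's habitat are NaN.  The shelf model's domain
    includes the bathymetric-mismatch zone (truth-shelf cells), so it can be
    blended with the basin model there.
    """
    habitat = habitat or results.model.habitat
    if habitat == "shelf":
        mask = env.shelf_mask | env.mismatch_mask
    else:
        mask = env.basin_mask
    cells = np.nonzero(mask)
    X = _covariate_matrix(env, year, week, results.variables, cells)
    vals = np.full(env.grid.shape, np.nan)
    vals[cells] = results.predict(X)
    return SuitabilitySurface(env.grid, vals, {"year": year, "week": week, "habitat": habitat})


def blend_mismatch(shelf: SuitabilitySurface, basin: SuitabilitySurface,
                   mismatch: np.ndarray) -> SuitabilitySurface:
    """Combine habitat surfaces; mismatch cells get the two-model average."""
    vals = np.where(np.isnan(shelf.values), basin.values, shelf.values)
    both = mismatch & shelf.defined() & basin.defined()
    vals = np.where(both, (shelf.values + basin.values) / 2.0, vals)
    return shelf.copy_with(vals, habitat="blended")


def average_surfaces(surfaces, years: str | list = "all",
                     warm_years=WARM_YEARS, cold_years=COLD_YEARS) -> SuitabilitySurface:
    """Unweighted cellwise mean over surfaces passing the year filter.

    `years` may be 'all', 'warm', 'cold', or an explicit list of years
    (matched against each surface's provenance).
    """
    if years == "all":
        keep = list(surfaces)
    else:
        year_set = {int(y) for y in (warm_years if years == "warm"
                                     else cold_years if years == "cold" else years)}
        keep = [s for s in surfaces if int(s.provenance.get("year", -1)) in year_set]
    if not keep:
        raise ValueError("no surfaces pass the year filter")
    vals = np.mean([s.values for s in keep], axis=0)
    return keep[0].copy_with(vals, years=years, n_surfaces=len(keep))


def accessibility_crop(surface: SuitabilitySurface, center, radius_km: float = 375.0
                       ) -> SuitabilitySurface:
    """Mask cells whose center is beyond `radius_km` of `center` (lon, lat)."""
    dist = surface.grid.center_distance_km(center[0], center[1])
    vals = np.where(dist <= radius_km, surface.values, np.nan)
    return surface.copy_with(vals, crop_center=tuple(center), crop_radius_km=radius_km)


def core_threshold(surface: SuitabilitySurface, quantile: float = 0.75) -> float:
    """Quantile threshold over the surface's defined cells (linear interp)."""
    vals = surface.values[surface.defined()]
    if vals.size == 0:
        raise ValueError("surface has no defined cells")
    return float(np.quantile(vals, quantile))


def core_map(blended: SuitabilitySurface, shelf_mean: SuitabilitySurface,
             basin_mean: SuitabilitySurface, env: EnvArchive,
             quantile: float = 0.75) -> CoreHabitatMap:
    """Core habitat from per-model thresholds on the hindcast means.

    A cell is core iff its blended suitability >= its governing model's
    threshold; mismatch cells use the average of the two thresholds.
    """
    tau_s = core_threshold(shelf_mean, quantile)
    tau_b = core_threshold(basin_mean, quantile)
    tau_m = (tau_s + tau_b) / 2.0
    tau = np.where(env.shelf_mask, tau_s, tau_b)
    tau = np.where(env.mismatch_mask, tau_m, tau)
    core = blended.defined() & (blended.values >= tau)
    return CoreHabitatMap.from_mask(
        blended.grid, core, {"shelf": tau_s, "basin": tau_b, "mismatch": tau_m}
    )


def single_model_core(mean_surface: SuitabilitySurface, quantile: float = 0.75
                      ) -> CoreHabitatMap:
    """Core map for one model's mean surface (no blending)."""
    tau = core_threshold(mean_surface, quantile)
    core = mean_surface.defined() & (mean_surface.values >= tau)
    return CoreHabitatMap.from_mask(mean_surface.grid, core, {"model": tau})


def hindcast_mean(results_shelf, results_basin, env: EnvArchive, years=None,
                  weeks=JUL_OCT_WEEKS, center=None, radius_km: float = 375.0):
    """Full hindcast pipeline: weekly predictions -> blended mean -> crop.

    Returns ``(blended_mean, shelf_mean, basin_mean)``, all cropped when a
    `center` is given.  `years` defaults to every year in the archive;
    `weeks` to the Jul-Oct bins present.
    """
    years = [int(y) for y in (years if years is not None else env.years)]
    weeks = [int(w) for w in weeks if w in env.weeks]
    shelf_w, basin_w = [], []
    for y in years:
        for w in weeks:
            shelf_w.append(predict_weekly(results_shelf, env, y, w))
            basin_w.append(predict_weekly(results_basin, env, y, w))
    shelf_mean = average_surfaces(shelf_w)
    basin_mean = average_surfaces(basin_w)
    blended = blend_mismatch(shelf_mean, basin_mean, env.mismatch_mask)
    if center is not None:
        blended = accessibility_crop(blended, center, radius_km)
        shelf_mean = accessibility_crop(shelf_mean, center, radius_km)
        basin_mean = accessibility_crop(basin_mean, center, radius_km)
    return blended, shelf_mean, basin_mean
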