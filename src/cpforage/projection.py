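"""Bias-corrected projections and core-habitat change metrics.

Projected archives are corrected by weekly climatological offsets: for each
variable, cell and week-of-year, the offset is the hindcast-minus-forecast
mean over a shared historical window, added to the whole forecast series
(biomasses floored at zero afterwards).  Future suitability uses the same
prediction machinery as the hindcast with the *hindcast* core thresholds,
and change is summarized by three metrics per model: mean core suitability,
core area, and the distance from the rookery to the suitability-weighted
center of gravity of core habitat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env import APR_JUL_WEEKS, WEEKLY_VARS, EnvArchive
from .grid import haversine_km
from .prediction import (CoreHabitatMap, SuitabilitySurface, accessibility_crop,
                         average_surfaces, blend_mismatch, predict_weekly)

log = logging.getLogger(__name__)

BIOMASS_WEEKLY = ("phl", "ncao_ncas", "eup")


def bias_correct(forecast: EnvArchive, hindcast: EnvArchive, window_years,
                 floor_biomass: bool = True) -> EnvArchive:
    """Apply weekly climatological offsets from a shared historical window.

    For every variable, cell and week-of-year:
    ``offset = mean_hindcast(window) - mean_forecast(window)`` and
    ``corrected = forecast + offset`` over the forecast's full span.
    Biomass variables are floored at zero after correction (count logged);
    the yearly Apr-Jul phytoplankton mean is rebuilt from the corrected
    weekly fields.
    """
    if forecast.grid != hindcast.grid:
        raise ValueError("forecast and hindcast grids differ")
    window = [int(y) for y in window_years]
    for y in window:
        if y not in forecast.years or y not in hindcast.years:
            raise ValueError(f"historical window year {y} missing from an archive")
    ds = forecast.ds.copy(deep=True)
    for var in WEEKLY_VARS:
        clim_h = hindcast.ds[var].sel(year=window).mean("year")
        clim_f = forecast.ds[var].sel(year=window).mean("year")
        corrected = ds[var] + (clim_h - clim_f)
        if floor_biomass and var in BIOMASS_WEEKLY:
            n_neg = int((corrected.values < 0).sum())
            if n_neg:
                log.info("bias_correct: floored %d negative %s values at 0", n_neg, var)
            corrected = corrected.clip(min=0.0)
        ds[var] = corrected
    weeks = [int(w) for w in ds["week"].values]
    apr_jul = [w for w in weeks if w in APR_JUL_WEEKS] or weeks
    ds["phl_avg"] = ds["phl"].sel(week=apr_jul).mean("week")
    return EnvArchive(grid=forecast.grid, ds=ds)


def project_suitability(results_shelf, results_basin, env: EnvArchive, years, weeks,
                        center=None, radius_km: float = 375.0):
    """Mean projected surface over (years x weeks): identical machinery to the
    hindcast — weekly ensemble means, mismatch blending, optional crop."""
    shelf_w, basin_w = [], []
    for y in years:
        for w in weeks:
            if int(w) not in env.weeks:
                continue
            shelf_w.append(predict_weekly(results_shelf, env, int(y), int(w)))
            basin_w.append(predict_weekly(results_basin, env, int(y), int(w)))
    shelf_mean = average_surfaces(shelf_w)
    basin_mean = average_surfaces(basin_w)
    blended = blend_mismatch(shelf_mean, basin_mean, env.mismatch_mask)
    if center is not None:
        blended = accessibility_crop(blended, center, radius_km)
    return blended


def apply_thresholds(surface: SuitabilitySurface, thresholds: dict, env: EnvArchive
                     ) -> CoreHabitatMap:
    """Core map for a (projected) surface under previously fixed thresholds."""
    tau = np.where(env.shelf_mask, thresholds["shelf"], thresholds["basin"])
    tau = np.where(env.mismatch_mask, thresholds["mismatch"], tau)
    core = surface.defined() & (surface.values >= tau)
    return CoreHabitatMap.from_mask(surface.grid, core, dict(thresholds))


def center_of_gravity(surface: SuitabilitySurface, core: np.ndarray):
    """Suitability-weighted mean cell-center position over core cells."""
    core = np.asarray(core, dtype=bool) & surface.defined()
    if not core.any():
        raise ValueError("no core cells")
    glon, glat = np.meshgrid(surface.grid.lons(), surface.grid.lats())
    w = surface.values[core]
    return float(np.average(glon[core], weights=w)), float(np.average(glat[core], weights=w))


@dataclass
class ChangeMetrics:
    """Hindcast-vs-projection change in core-habitat characteristics."""

    scope: str
    habitat: str
    scenario: str
    mean_suit_hind: float
    mean_suit_proj: float
    area_km2_hind: float
    area_km2_proj: float
    cog_hind: tuple
    cog_proj: tuple
    dist_km_hind: float
    dist_km_proj: float

    @staticmethod
    def _pct(h, p):
        return float("nan") if h == 0 else 100.0 * (p - h) / h

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, h, p, delta in [
            ("mean_core_suitability", self.mean_suit_hind, self.mean_suit_proj, None),
            ("core_area_km2", self.area_km2_hind, self.area_km2_proj, None),
            ("cog_distance_km", self.dist_km_hind, self.dist_km_proj, None),
        ]:
            rows.append({
                "scope": self.scope, "habitat": self.habitat, "scenario": self.scenario,
                "metric": metric, "hindcast": h, "projected": p,
                "delta": p - h, "delta_pct": self._pct(h, p),
            })
        return pd.DataFrame(rows)


def change_metrics(hind_surface: SuitabilitySurface, hind_core: CoreHabitatMap,
                   proj_surface: SuitabilitySurface, proj_core: CoreHabitatMap,
                   rookery, scope: str = "all", habitat: str = "blended",
                   scenario: str = "projection") -> ChangeMetrics:
    """Three change metrics between a hindcast and a projected core product."""
    mean_h = float(np.nanmean(hind_surface.values[hind_core.core]))
    mean_p = float(np.nanmean(proj_surface.values[proj_core.core]))
    cog_h = center_of_gravity(hind_surface, hind_core.core)
    cog_p = center_of_gravity(proj_surface, proj_core.core)
    d_h = float(haversine_km(cog_h[0], cog_h[1], rookery[0], rookery[1]))
    d_p = float(haversine_km(cog_p[0], cog_p[1], rookery[0], rookery[1]))
    return ChangeMetrics(
        scope=scope, habitat=habitat, scenario=scenario,
        mean_suit_hind=mean_h, mean_suit_proj=mean_p,
        area_km2_hind=hind_core.area_km2, area_km2_proj=proj_core.area_km2,
        cog_hind=cog_h, cog_proj=cog_p, dist_km_hind=d_h, dist_km_proj=d_p,
    )
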