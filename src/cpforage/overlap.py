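"""Spatial overlap between core habitat and coarse-gridded fishery catches.

Fine-grid core indicators (core for at least one complex = 1) are regridded
to the coarse catch grid by averaging the indicators of fine cells whose
centers fall inside each coarse cell.  Overlap summaries report the
proportion of total catch taken in coarse cells containing any core habitat
and the share of core-habitat area lying in fished cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec
from .synth import CatchGrid


def union_core(core_masks) -> np.ndarray:
    """Cellwise OR over per-complex core masks."""
    masks = [np.asarray(m, dtype=bool) for m in core_masks]
    out = masks[0].copy()
    for m in masks[1:]:
        out |= m
    return out


def coarse_index_of(fine: GridSpec, coarse: GridSpec):
    """(row, col) coarse indices of every fine cell center (-1 = outside)."""
    glon, glat = np.meshgrid(fine.lons(), fine.lats())
    return coarse.locate(glon.ravel(), glat.ravel())


def regrid_core(fine_mask: np.ndarray, fine: GridSpec, coarse: GridSpec) -> np.ndarray:
    """Coarse-cell mean of fine core indicators; NaN where no fine centers."""
    rr, cc = coarse_index_of(fine, coarse)
    vals = np.asarray(fine_mask, dtype=float).ravel()
    inside = (rr >= 0) & (cc >= 0)
    total = np.zeros(coarse.shape)
    count = np.zeros(coarse.shape)
    np.add.at(total, (rr[inside], cc[inside]), vals[inside])
    np.add.at(count, (rr[inside], cc[inside]), 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / count, np.nan)


@dataclass
class OverlapResult:
    """Core/catch overlap on the coarse grid, with summary percentages."""

    coarse: GridSpec
    core_value: np.ndarray      # coarse per-cell mean core indicator in [0, 1]
    catch_t: np.ndarray
    pct_catch_in_core: float    # % of total catch in cells with core value > 0
    pct_core_area_fished: float  # % of core area in cells with catch > 0
    total_catch_t: float
    catch_in_core_t: float
    core_area_km2: float

    def to_dict(self) -> dict:
        return {
            "pct_catch_in_core": self.pct_catch_in_core,
            "pct_core_area_fished": self.pct_core_area_fished,
            "total_catch_t": self.total_catch_t,
            "catch_in_core_t": self.catch_in_core_t,
            "core_area_km2": self.core_area_km2,
        }


def overlap_stats(fine_core: np.ndarray, fine: GridSpec, catch: CatchGrid,
                  extent_mask: np.ndarray | None = None) -> OverlapResult:
    """Overlap summary between a fine binary core map and a catch grid.

    `extent_mask` (fine grid) limits the analysis extent, e.g. to the
    accessibility circle; catch in coarse cells containing no in-extent fine
    centers is excluded from the totals.  Zero total catch leaves the catch
    proportion NaN.
    """
    fine_core = np.asarray(fine_core, dtype=bool)
    if extent_mask is not None:
        fine_core = fine_core & np.asarray(extent_mask, dtype=bool)
    core_val = regrid_core(fine_core, fine, catch.grid)
    if extent_mask is not None:
        in_extent = regrid_core(extent_mask, fine, catch.grid)
        analysis = ~np.isnan(in_extent) & (in_extent > 0)
    else:
        analysis = ~np.isnan(core_val)

    total_catch = float(catch.catch_t[analysis].sum())
    in_core = analysis & (np.nan_to_num(core_val) > 0)
    catch_in_core = float(catch.catch_t[in_core].sum())
    pct_catch = 100.0 * catch_in_core / total_catch if total_catch > 0 else float("nan")

    # core-area share in fished coarse cells, from fine-cell areas
    rr, cc = coarse_index_of(fine, catch.grid)
    areas = fine.area_grid_km2().ravel()
    corev = fine_core.ravel()
    inside = (rr >= 0) & (cc >= 0)
    fished = np.zeros(len(corev), dtype=bool)
    fished[inside] = catch.catch_t[rr[inside], cc[inside]] > 0
    core_area = float(areas[corev].sum())
    core_area_fished = float(areas[corev & fished].sum())
    pct_area = 100.0 * core_area_fished / core_area if core_area > 0 else float("nan")

    return OverlapResult(
        coarse=catch.grid, core_value=core_val, catch_t=catch.catch_t,
        pct_catch_in_core=pct_catch, pct_core_area_fished=pct_area,
        total_catch_t=total_catch, catch_in_core_t=catch_in_core,
        core_area_km2=core_area,
    )
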