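"""Turn raw trips into covariate-annotated candidate presence points.

Trip ends are trimmed (transit to/from the rookery), each fix is assigned to
its containing grid cell and habitat, fixes in bathymetric-mismatch cells or
outside the grid are removed, and weekly covariates are extracted from the
bin whose center is nearest in time (ties to the earlier bin).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .env import COVARIATES, EnvArchive, nearest_week

log = logging.getLogger(__name__)


def trim_trip_ends(trip: pd.DataFrame, hours: int = 12) -> pd.DataFrame:
    """Drop fixes within `hours` of trip start or end.

    Trips no longer than ``2*hours`` cannot contain interior fixes and are
    dropped entirely (empty frame, ``attrs['dropped'] = 'short'``).
    """
    ts = pd.to_datetime(trip["timestamp"])
    start, end = ts.min(), ts.max()
    if hours > 0 and (end - start) <= pd.Timedelta(hours=2 * hours):
        out = trip.iloc[0:0].copy()
        out.attrs["dropped"] = "short"
        return out
    keep = (ts >= start + pd.Timedelta(hours=hours)) & (ts <= end - pd.Timedelta(hours=hours))
    return trip.loc[keep].reset_index(drop=True)


def assign_points(trip: pd.DataFrame, env: EnvArchive) -> pd.DataFrame:
    """Map fixes to cells; drop out-of-grid and mismatch-cell fixes.

    Adds columns row, col, habitat, date, year.  Counts of removed fixes are
    logged; an all-outside trip yields an empty frame with a warning.
    """
    if len(trip) == 0:
        return trip.assign(row=[], col=[], habitat=[], date=[], year=[])
    row, col = env.grid.locate(trip["lon"].to_numpy(), trip["lat"].to_numpy())
    inside = (row >= 0) & (col >= 0)
    n_out = int((~inside).sum())
    if n_out:
        log.info("assign_points: %d fixes outside grid removed", n_out)
    if not inside.any():
        log.warning("assign_points: all fixes outside grid")
    out = trip.loc[inside].copy()
    row, col = row[inside], col[inside]
    mism = env.mismatch_mask[row, col]
    n_mism = int(mism.sum())
    if n_mism:
        log.info("assign_points: %d fixes in mismatch cells removed", n_mism)
    out = out.loc[~mism].copy()
    row, col = row[~mism], col[~mism]
    out["row"], out["col"] = row, col
    out["habitat"] = env.habitat_of(row, col)
    ts = pd.to_datetime(out["timestamp"])
    out["date"] = ts.dt.normalize()
    out["year"] = ts.dt.year
    return out.reset_index(drop=True)


def extract_covariates(points: pd.DataFrame, env: EnvArchive) -> pd.DataFrame:
    """Attach all model covariates to located points.

    Weekly variables come from the weekly bin whose center is nearest the
    point's timestamp (tie -> earlier bin); bathymetry from the static field;
    the yearly Apr-Jul phytoplankton mean from the point's year.  A missing
    (year, week) bin raises ``KeyError`` naming the bin.
    """
    if len(points) == 0:
        return points.assign(**{v: [] for v in COVARIATES})
    out = points.copy().reset_index(drop=True)
    week = nearest_week(out["timestamp"], len(env.weeks))
    out["week"] = week
    r = out["row"].to_numpy()
    c = out["col"].to_numpy()
    out["bathymetry"] = env.bathymetry[r, c]
    years = out["year"].to_numpy()
    for var in ("temp_bottom", "temp_surface", "phl", "ncao_ncas", "eup"):
        vals = np.empty(len(out))
        for (y, w), idx in out.groupby(["year", "week"]).groups.items():
            fld = env.weekly(var, int(y), int(w))
            ii = np.asarray(idx)
            vals[ii] = fld[r[ii], c[ii]]
        out[var] = vals
    vals = np.empty(len(out))
    for y in np.unique(years):
        fld = env.phl_avg(int(y))
        ii = years == y
        vals[ii] = fld[r[ii], c[ii]]
    out["phl_avg"] = vals
    return out


def majority_habitat(points: pd.DataFrame) -> str:
    """Habitat holding a strict majority of the trip's points, else 'mixed'."""
    if len(points) == 0:
        return "mixed"
    frac_shelf = (points["habitat"] == "shelf").mean()
    if frac_shelf > 0.5:
        return "shelf"
    if frac_shelf < 0.5:
        return "basin"
    return "mixed"
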