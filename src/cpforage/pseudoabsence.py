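"""Null-track pseudo-absences and replicate dataset assembly.

For presence-only telemetry, absences must represent where an animal *could*
have gone.  Each observed trip gets a first-order vector-autoregressive (VAR)
model fitted to its hourly step vectors; 100 candidate tracks are simulated
from that model with the trip's own start and end points (the rookery)
enforced by uniform closure-drift subtraction.  Candidate positions falling
in the same or an adjacent grid cell as any presence within a six-day window
are struck (the archive is weekly-binned, so a six-day exclusion prevents
label contamination).  Each trip is then paired with one surviving candidate,
both are down-sampled to one location per day, unmatched days are dropped
from both sides, and the result is a per-habitat dataset with an exact 1:1
presence:absence ratio.  Ten replicate datasets differ in the daily draws and
in the partner candidate chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rand import substream
from .env import EnvArchive
from .grid import GridSpec, haversine_km
from .preprocess import assign_points, extract_covariates, trim_trip_ends

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VAR fit and simulation
# ---------------------------------------------------------------------------

@dataclass
class VARParams:
    """First-order VAR on hourly step vectors, in degrees/h.

    Model: ``s_t - mu = A (s_{t-1} - mu) + eps_t``, ``eps_t ~ N(0, Sigma)``.
    """

    mu: np.ndarray          # (2,)
    A: np.ndarray           # (2, 2), spectral radius < 1
    Sigma: np.ndarray       # (2, 2) symmetric PSD
    flags: list = field(default_factory=list)


def fit_var(trip: pd.DataFrame) -> VARParams:
    """Least-squares VAR(1) fit to a trip's hourly step vectors."""
    xy = trip[["lon", "lat"]].to_numpy(dtype=float)
    steps = np.diff(xy, axis=0)
    if len(steps) < 8:
        raise ValueError("trip must have at least 8 hourly steps")
    mu = steps.mean(axis=0)
    z = steps - mu
    z0, z1 = z[:-1], z[1:]
    flags = []
    if np.allclose(z, 0.0):
        A = np.zeros((2, 2))
        resid = z1
        flags.append("degenerate-steps")
    else:
        At, *_ = np.linalg.lstsq(z0, z1, rcond=None)
        A = At.T
        resid = z1 - z0 @ At
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho >= 1.0:
        A = A * (0.99 / rho)
        flags.append("stabilized")
    n = len(resid)
    Sigma = (resid.T @ resid) / max(n - 1, 1)
    Sigma = (Sigma + Sigma.T) / 2.0
    if np.linalg.eigvalsh(Sigma).min() < 1e-12:
        Sigma = Sigma + 1e-12 * np.eye(2)
        if "degenerate-steps" not in flags:
            flags.append("sigma-floored")
        log.warning("fit_var: innovation covariance floored at 1e-12")
    return VARParams(mu=mu, A=A, Sigma=Sigma, flags=flags)


@dataclass
class SimulatedTracks:
    """``n`` candidate tracks sharing one trip's timestamps.

    ``lon``/``lat`` have shape (n, T+1); position 0 and T match the trip's
    own endpoints exactly.
    """

    lon: np.ndarray
    lat: np.ndarray
    timestamps: pd.DatetimeIndex
    flags: list

    @property
    def n(self) -> int:
        return self.lon.shape[0]


def simulate_candidates(
    params: VARParams, trip: pd.DataFrame, n: int = 100, seed: int = 0, max_retries: int = 20
) -> SimulatedTracks:
    """Simulate `n` endpoint-pinned candidate tracks from a fitted VAR.

    Each candidate has the trip's timestamps, starts at the trip's first
    position and is forced to its last position by subtracting the closure
    error uniformly from every step.  Candidates whose mean speed falls
    outside [0.5, 2] times the real trip's are re-simulated (up to
    `max_retries`); a survivor outside that band is flagged 'speed-mismatch'.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, "candidates")
    xy = trip[["lon", "lat"]].to_numpy(dtype=float)
    ts = pd.DatetimeIndex(pd.to_datetime(trip["timestamp"]))
    T = len(xy) - 1
    start, end = xy[0], xy[-1]
    need = end - start
    real_speed = _mean_step_km(xy[:, 0], xy[:, 1])
    L = np.linalg.cholesky(params.Sigma + 1e-15 * np.eye(2))
    flags = [None] * n
    lon = np.empty((n, T + 1))
    lat = np.empty((n, T + 1))

    def one(rng):
        eps = rng.standard_normal((T, 2)) @ L.T
        s = np.empty((T, 2))
        prev = np.zeros(2)  # start at the stationary mean
        for t in range(T):
            prev = params.A @ prev + eps[t]
            s[t] = prev + params.mu
        s = s + (need - s.sum(axis=0)) / T
        pos = start + np.vstack([[0.0, 0.0], np.cumsum(s, axis=0)])
        pos[-1] = end
        return pos

    for i in range(n):
        pos = one(rng)
        tries = 0
        while tries < max_retries:
            speed = _mean_step_km(pos[:, 0], pos[:, 1])
            if real_speed == 0 or 0.5 * real_speed <= speed <= 2.0 * real_speed:
                break
            pos = one(rng)
            tries += 1
        else:
            flags[i] = "speed-mismatch"
        lon[i], lat[i] = pos[:, 0], pos[:, 1]
    return SimulatedTracks(lon=lon, lat=lat, timestamps=ts, flags=flags)


def _mean_step_km(lon, lat) -> float:
    return float(np.mean(haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))


# ---------------------------------------------------------------------------
# spatiotemporal exclusion filter
# ---------------------------------------------------------------------------

def _exclusion_volume(presences: pd.DataFrame, grid: GridSpec, window_days: int):
    """Boolean (nlat, nlon, ndays) volume: True = excluded.

    A cell-day is excluded iff some presence lies in the same or one of the
    8 neighbouring cells with |date difference| <= window_days.
    """
    days = pd.to_datetime(presences["date"]).map(pd.Timestamp.toordinal).to_numpy()
    # pad by the window so candidates just outside the presence date range
    # are still checked
    d0, d1 = int(days.min()) - window_days, int(days.max()) + window_days
    vol = np.zeros((grid.nlat, grid.nlon, d1 - d0 + 1), dtype=bool)
    vol[presences["row"].to_numpy(), presences["col"].to_numpy(), days - d0] = True
    vol = ndimage.maximum_filter(
        vol, size=(3, 3, 2 * window_days + 1), mode="constant", cval=False
    )
    return vol, d0, d1


def filter_candidates(
    candidates: SimulatedTracks,
    presences: pd.DataFrame,
    grid: GridSpec,
    window_days: int = 6,
) -> np.ndarray:
    """Keep-mask (n, T+1) for candidate positions vs. the presence sample.

    A position is struck iff a presence occupies its cell or one of the 8
    neighbours within ``|delta date| <= window_days``.  Out-of-grid positions
    are left for downstream removal, not struck here.
    """
    n, m = candidates.lon.shape
    keep = np.ones((n, m), dtype=bool)
    if len(presences) == 0:
        return keep
    vol, d0, d1 = _exclusion_volume(presences, grid, window_days)
    days = np.array([pd.Timestamp(t).normalize().toordinal() for t in candidates.timestamps])
    rr, cc = grid.locate(candidates.lon.ravel(), candidates.lat.ravel())
    rr = rr.reshape(n, m)
    cc = cc.reshape(n, m)
    dd = np.broadcast_to(days, (n, m)) - d0
    valid = (rr >= 0) & (cc >= 0) & (dd >= 0) & (dd <= d1 - d0)
    excl = np.zeros((n, m), dtype=bool)
    excl[valid] = vol[rr[valid], cc[valid], dd[valid]]
    keep &= ~excl
    return keep


# ---------------------------------------------------------------------------
# partner selection and replicate assembly
# ---------------------------------------------------------------------------

def rank_candidates(day_counts) -> list:
    """Candidate indices with >= 1 surviving day, most days first, ties by index."""
    idx = [i for i, d in enumerate(day_counts) if d > 0]
    return sorted(idx, key=lambda i: (-day_counts[i], i))


def select_partner(day_counts, replicate: int, rng: np.random.Generator):
    """Partner candidate index for one replicate, or None if all filtered out.

    Replicate 1 takes the top-ranked candidate (most distinct surviving days,
    ties to the lowest index); later replicates walk a seeded permutation of
    the remaining eligible candidates, wrapping if fewer candidates than
    replicates survive.
    """
    ranked = rank_candidates(day_counts)
    if not ranked:
        return None
    rest = list(rng.permutation(ranked[1:])) if len(ranked) > 1 else []
    order = [ranked[0]] + [int(i) for i in rest]
    return order[(replicate - 1) % len(order)]


def build_replicates(
    trips,
    env: EnvArchive,
    n_replicates: int = 10,
    seed: int = 0,
    n_candidates: int = 100,
    window_days: int = 6,
    trim_hours: int = 12,
) -> dict:
    """Assemble per-habitat replicate presence/absence datasets.

    Returns ``{habitat: [DataFrame, ...]}`` with one frame per replicate.
    Rows carry label ('presence'/'absence'), the pairing trip_id, habitat,
    date, year, lon/lat and all covariates.  Within each habitat every
    replicate is exactly 1:1 balanced: a trip-day enters only when both the
    sampled presence point and the sampled partner point fall in that
    habitat on that calendar date.
    """
    prepared = {}  # trip_id -> dict with presence points & candidate survivors
    all_presences = []
    meta = {}
    for trip_id, trip in trips.trips():
        trimmed = trim_trip_ends(trip, hours=trim_hours)
        if len(trimmed) < 9:  # need >= 8 steps for the VAR fit
            log.info("trip %s dropped (%s)", trip_id, trimmed.attrs.get("dropped", "too-short"))
            continue
        pts = assign_points(trimmed, env)
        if len(pts) == 0:
            continue
        prepared[trip_id] = {"trip": trimmed, "presence": pts}
        meta[trip_id] = dict(
            animal_id=trip["animal_id"].iloc[0], complex=trip["complex"].iloc[0]
        )
        all_presences.append(pts)
    if not prepared:
        return {}
    # The exclusion filter compares candidates against the presence data as
    # they enter the models: one location per trip-day (a fixed seeded draw
    # shared by all replicates), over every trip in the pool.
    pool_rng = substream(seed, "filter-pool")
    presence_pool = pd.concat(
        [_daily_downsample(p, pool_rng) for p in all_presences], ignore_index=True
    )

    # simulate + filter + locate candidates once per trip (shared by replicates)
    for trip_id, d in prepared.items():
        params = fit_var(d["trip"])
        cands = simulate_candidates(
            params, d["trip"], n=n_candidates,
            seed=substream(seed, "partner-sim", trip_id).integers(2**31 - 1),
        )
        keep = filter_candidates(cands, presence_pool, env.grid, window_days)
        d["cand_points"] = _candidate_points(cands, keep, env)
        d["day_counts"] = [len(p["date"].unique()) if p is not None else 0 for p in d["cand_points"]]

    habitats = ("shelf", "basin")
    out = {h: [] for h in habitats}
    for r in range(1, n_replicates + 1):
        frames = {h: [] for h in habitats}
        for trip_id, d in prepared.items():
            rng_partner = substream(seed, "partner-pick", trip_id)
            pi = select_partner(d["day_counts"], r, rng_partner)
            if pi is None:
                log.info("trip %s: all candidates filtered out; excluded", trip_id)
                continue
            partner = d["cand_points"][pi]
            rng_day = substream(seed, "daily", trip_id, r)
            pres = _daily_downsample(d["presence"], rng_day)
            absn = _daily_downsample(partner, rng_day)
            for h in habitats:
                p_h = pres[pres["habitat"] == h]
                a_h = absn[absn["habitat"] == h]
                days = np.intersect1d(p_h["date"].to_numpy(), a_h["date"].to_numpy())
                if len(days) == 0:
                    continue
                p_h = p_h[p_h["date"].isin(days)].assign(label="presence")
                a_h = a_h[a_h["date"].isin(days)].assign(label="absence")
                both = pd.concat([p_h, a_h], ignore_index=True)
                both["trip_id"] = trip_id
                both["animal_id"] = meta[trip_id]["animal_id"]
                both["complex"] = meta[trip_id]["complex"]
                both["replicate"] = r
                frames[h].append(both)
        for h in habitats:
            if frames[h]:
                df = pd.concat(frames[h], ignore_index=True)
                df = extract_covariates(df, env)
                out[h].append(df)
    return {h: reps for h, reps in out.items() if reps}


def _candidate_points(cands: SimulatedTracks, keep: np.ndarray, env: EnvArchive):
    """Per-candidate located point tables (mismatch/out-of-grid removed)."""
    out = []
    ts = cands.timestamps
    for i in range(cands.n):
        sel = keep[i]
        if not sel.any():
            out.append(None)
            continue
        df = pd.DataFrame({
            "timestamp": ts[sel], "lon": cands.lon[i, sel], "lat": cands.lat[i, sel],
        })
        pts = assign_points(df, env)
        out.append(pts if len(pts) else None)
    return out


def _daily_downsample(points: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One uniformly chosen point per calendar date."""
    picks = []
    for _, g in points.groupby("date", sort=True):
        picks.append(g.index[rng.integers(len(g))])
    return points.loc[picks].reset_index(drop=True)
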