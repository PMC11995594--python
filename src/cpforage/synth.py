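"""Synthetic study system: ocean archive, foraging tracks, and a catch grid.

Everything downstream of this module treats these products exactly like real
inputs (NetCDF archive, telemetry CSV, catch CSV).  The generator's value is
that its statistical structure is known: covariate fields are smooth base
gradients plus kernel-smoothed spatial noise, and animal movement is an AR(1)
step process with an optional, explicitly parameterized habitat-selection
function — so selection strength 0 makes presences statistically identical to
the null tracks used for pseudo-absences, and recovery of an imposed
preference can be verified.

Default movement parameters reflect lactating otariid females on
central-place foraging trips: mean trip duration 6.6 d (sd 2.4 d, truncated
at 1 d), hourly locations, trips departing and returning to the rookery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from ._rand import substream
from .env import APR_JUL_WEEKS, SHELF_MAX_DEPTH_M, WEEKLY_VARS, EnvArchive
from .grid import GridSpec

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

# Base spatial-noise standard deviations per weekly variable (field units).
NOISE_SD = {"temp_bottom": 0.7, "temp_surface": 0.9, "phl": 120.0, "ncao_ncas": 90.0, "eup": 90.0}
# Interannual (year-level) offset scales.
YEAR_SD = {"temp_bottom": 0.5, "temp_surface": 0.8, "phl": 35.0, "ncao_ncas": 25.0, "eup": 18.0}


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def _bathymetry_profile(nlon: int, shallow=20.0, deep=3000.0) -> np.ndarray:
    """Monotone west->east depth profile: basin (col 0) to shelf (last col)."""
    f = np.arange(nlon) / (nlon - 1)
    return shallow + (deep - shallow) * (1.0 - f) ** 3


def _base_field(var: str, bathy: np.ndarray, week: int, cold_pool_mask=None) -> np.ndarray:
    """Smooth deterministic base field for one weekly variable."""
    d = np.maximum(bathy, 1.0)
    if var == "temp_bottom":
        # Shelf bottom water is set by winter ice history and latitude, not
        # depth; the basin profile cools with depth.  Blending near the shelf
        # break keeps the two regimes continuous, and makes bathymetry and
        # bottom temperature strongly correlated only in the basin.
        rows = np.arange(bathy.shape[0])[:, None] / max(bathy.shape[0] - 1, 1)
        shelf_part = 6.5 - 3.0 * rows + 0.0 * d
        basin_part = 11.5 - 1.3 * np.log(d)
        w = np.clip((d - 120.0) / 160.0, 0.0, 1.0)
        base = (1.0 - w) * shelf_part + w * basin_part
        if cold_pool_mask is not None:
            base = np.where(cold_pool_mask, 0.8, base)
        return base
    if var == "temp_surface":
        seasonal = 3.0 * np.sin(2.0 * np.pi * (week - 14) / 52.0)
        rows = np.arange(bathy.shape[0])[:, None] / max(bathy.shape[0] - 1, 1)
        return 7.5 + seasonal - 2.0 * rows + 0.0 * d
    if var == "phl":
        # spring bloom sits on the mid-shelf; summer production shifts to
        # the outer shelf/slope, so the Apr-Jul mean and the late-summer
        # weekly fields carry different spatial patterns
        spring = 120.0 + 140.0 * np.exp(-0.5 * ((d - 55.0) / 60.0) ** 2)
        summer = 120.0 + 260.0 * np.exp(-d / 150.0)
        m = np.clip((week - 26.0) / 6.0, 0.0, 1.0)
        return (1.0 - m) * spring + m * summer
    if var == "ncao_ncas":
        return 80.0 + 160.0 * np.exp(-d / 300.0)
    if var == "eup":
        # krill standing stock is swarm-dominated: a weak shelf-break bump
        # under strong patchy noise
        return 70.0 + 60.0 * np.exp(-0.5 * (np.log(d / 200.0) ** 2) / 0.6)
    raise KeyError(var)


def _smooth_noise(rng: np.random.Generator, shape, sd: float, length_cells: float = 3.0) -> np.ndarray:
    """Kernel-smoothed white noise rescaled to standard deviation `sd`."""
    white = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(white, sigma=length_cells, mode="nearest")
    s = sm.std()
    if s == 0:
        return np.zeros(shape)
    return sm * (sd / s)


def _cold_pool_mask(grid: GridSpec, bathy: np.ndarray) -> np.ndarray:
    """Contiguous mid-shelf patch (middle latitudes, 40-100 m depths)."""
    rows = np.arange(grid.nlat)[:, None]
    mid = (rows >= grid.nlat // 3) & (rows < 2 * grid.nlat // 3)
    return mid & (bathy >= 40.0) & (bathy <= 100.0)


def make_environment(
    spec: GridSpec,
    years,
    weeks_per_year: int = 52,
    cold_pool: bool = True,
    seed: int = 0,
    noise: float = 1.0,
    mismatch_cols: int = 2,
) -> EnvArchive:
    """Generate a synthetic weekly ocean archive on `spec`.

    Parameters
    ----------
    years : sequence of int
        Years to simulate (nonempty).
    weeks_per_year : int
        Weekly bins per year (week 1 starts Jan 1).
    cold_pool : bool
        Impose a < 2 degC bottom-temperature patch on the mid-shelf.
    noise : float
        Multiplier on the per-variable spatial-noise standard deviations;
        0 gives exactly the deterministic base fields.
    mismatch_cols : int
        Width (columns) by which the "true" shelf is wider than the model
        shelf; the difference becomes the bathymetric-mismatch mask.

    Noise fields are keyed by (seed, variable, year, week), so two archives
    built with the same seed agree bit-for-bit on shared (year, week) bins.
    """
    years = [int(y) for y in years]
    if not years:
        raise ValueError("years must be nonempty")
    weeks = list(range(1, int(weeks_per_year) + 1))
    if not weeks:
        raise ValueError("weeks_per_year must be positive")

    profile = _bathymetry_profile(spec.nlon)
    bathy = np.tile(profile, (spec.nlat, 1))
    # "true" bathymetry has a wider shelf: model shelf edge shifted east.
    true_profile = np.concatenate([profile[mismatch_cols:], np.repeat(profile[-1], mismatch_cols)])
    true_bathy = np.tile(true_profile, (spec.nlat, 1))
    mismatch = (bathy > SHELF_MAX_DEPTH_M) & (true_bathy <= SHELF_MAX_DEPTH_M)

    cp_mask = _cold_pool_mask(spec, bathy) if cold_pool else None

    coords = {"year": years, "week": weeks, "lat": spec.lats(), "lon": spec.lons()}
    data = {}
    shape = (len(years), len(weeks), spec.nlat, spec.nlon)
    for var in WEEKLY_VARS:
        arr = np.empty(shape)
        for iy, y in enumerate(years):
            y_off = substream(seed, "env-year", var, y).normal(0.0, YEAR_SD[var]) if noise > 0 else 0.0
            for iw, w in enumerate(weeks):
                base = _base_field(var, bathy, w, cp_mask)
                fld = base + y_off * noise
                if noise > 0:
                    rng = substream(seed, "env-noise", var, y, w)
                    fld = fld + _smooth_noise(rng, spec.shape, NOISE_SD[var] * noise)
                arr[iy, iw] = fld
        if var in ("phl", "ncao_ncas", "eup"):
            arr = np.maximum(arr, 0.0)
        data[var] = (("year", "week", "lat", "lon"), arr)

    # yearly Apr-Jul mean of large phytoplankton, from the weekly fields
    apr_jul = [w for w in weeks if w in APR_JUL_WEEKS] or weeks
    idx = [weeks.index(w) for w in apr_jul]
    phl_avg = data["phl"][1][:, idx].mean(axis=1)
    data["phl_avg"] = (("year", "lat", "lon"), phl_avg)

    data["bathymetry"] = (("lat", "lon"), bathy)
    data["mismatch"] = (("lat", "lon"), mismatch.astype(np.int8))

    ds = xr.Dataset(data, coords=coords)
    ds.attrs.update(
        gen_seed=int(seed), gen_noise=float(noise), gen_cold_pool=int(bool(cold_pool)),
        gen_weeks_per_year=int(weeks_per_year), gen_mismatch_cols=int(mismatch_cols),
    )
    env = EnvArchive(grid=spec, ds=ds)
    env.validate()
    return env


def make_projection_archive(
    env: EnvArchive,
    drift: dict,
    historical_years,
    future_years,
    esm_bias: dict,
    seed: int = 0,
) -> EnvArchive:
    """Build a projected archive sharing the hindcast's spatial structure.

    Fields are regenerated (noise keyed by `seed`) over
    ``historical_years + future_years`` and then shifted by a constant
    per-variable ESM bias plus a linear trend of ``drift[var]`` units per
    decade counted from the first historical year.  Passing the hindcast's
    own seed with zero bias and drift reproduces the hindcast fields on the
    shared years exactly.
    """
    a = env.ds.attrs
    years = [int(y) for y in historical_years] + [int(y) for y in future_years]
    proj = make_environment(
        env.grid, years,
        weeks_per_year=int(a.get("gen_weeks_per_year", len(env.weeks))),
        cold_pool=bool(a.get("gen_cold_pool", 1)),
        seed=seed,
        noise=float(a.get("gen_noise", 1.0)),
        mismatch_cols=int(a.get("gen_mismatch_cols", 2)),
    )
    y0 = int(historical_years[0])
    for var in WEEKLY_VARS:
        bias = float(esm_bias.get(var, 0.0))
        dr = float(drift.get(var, 0.0))
        shift = bias + dr * (np.array(years, dtype=float) - y0) / 10.0
        proj.ds[var] = proj.ds[var] + xr.DataArray(shift, coords={"year": years}, dims=("year",))
        if var in ("phl", "ncao_ncas", "eup"):
            proj.ds[var] = proj.ds[var].clip(min=0.0)
    # rebuild the derived yearly mean from the shifted weekly fields
    weeks = list(proj.weeks)
    apr_jul = [w for w in weeks if w in APR_JUL_WEEKS] or weeks
    proj.ds["phl_avg"] = proj.ds["phl"].sel(week=apr_jul).mean("week")
    return proj


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class SelectionSpec:
    """Ground-truth habitat preference used by the track simulator.

    ``preferences`` maps covariate name -> piecewise-linear preference
    ``(breakpoints, weights)`` with weights >= 0, evaluated by linear
    interpolation (flat beyond the end breakpoints).  The sampling weight of
    a candidate position is ``prod_v pref_v(value)`` raised to ``strength``;
    strength 0 disables selection entirely.
    """

    preferences: dict = field(default_factory=dict)
    strength: float = 0.0

    def weight(self, values: dict) -> np.ndarray:
        """Selection weight for arrays of covariate values (same shape)."""
        if self.strength == 0 or not self.preferences:
            first = next(iter(values.values())) if values else np.array(1.0)
            return np.ones_like(np.asarray(first, dtype=float))
        w = None
        for var, (xs, ys) in self.preferences.items():
            v = np.interp(np.asarray(values[var], dtype=float), xs, ys)
            w = v if w is None else w * v
        w = np.maximum(w, 0.0)
        return np.power(w, self.strength)


def depth_temperature_selection(
    depth_lo: float = 75.0, depth_hi: float = 200.0,
    temp_max: float = 6.0, strength: float = 3.0,
) -> SelectionSpec:
    """Preference for a mid/outer-shelf depth band and cool bottom water.

    The canonical recovery scenario: selection *for* bathymetry in
    [depth_lo, depth_hi] m and *against* bottom temperatures above
    `temp_max` degC, mirroring the band-and-cool-water selection reported
    for shelf-foraging otariids.
    """
    return SelectionSpec(
        preferences={
            "bathymetry": (
                [0.0, depth_lo - 25.0, depth_lo, depth_hi, depth_hi + 50.0, 3000.0],
                [0.02, 0.05, 1.0, 1.0, 0.05, 0.02],
            ),
            "temp_bottom": (
                [-2.0, 2.0, temp_max, temp_max + 1.0, 15.0],
                [1.0, 1.0, 0.25, 0.04, 0.015],
            ),
        },
        strength=strength,
    )


@dataclass
class StepParams:
    """AR(1) step-process parameters (isotropic, in km/h)."""

    mean_step_km: float = 5.5
    ar_coef: float = 0.90
    innovation_sd_km: float | None = None  # default derived from mean step

    def sigma(self) -> float:
        if self.innovation_sd_km is not None:
            return float(self.innovation_sd_km)
        # stationary component sd such that E|s| (Rayleigh) = mean_step_km
        comp_sd = self.mean_step_km * np.sqrt(2.0 / np.pi)
        return comp_sd * np.sqrt(1.0 - self.ar_coef**2)


@dataclass
class TripSet:
    """Telemetry trips: one row per hourly fix.

    Columns: animal_id, complex, rookery_lon, rookery_lat, trip_id,
    timestamp (UTC), lon, lat.
    """

    df: pd.DataFrame

    def trips(self):
        for trip_id, g in self.df.groupby("trip_id", sort=True):
            yield trip_id, g.sort_values("timestamp").reset_index(drop=True)

    @property
    def trip_ids(self):
        return sorted(self.df["trip_id"].unique())

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TripSet":
        df = pd.read_csv(path)
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
        return cls(df=df)


def _km_to_deg(lat0: float):
    return 1.0 / (KM_PER_DEG_LON_EQ * np.cos(np.radians(lat0))), 1.0 / KM_PER_DEG_LAT


def default_rookery(env: EnvArchive, target_depth_m: float = 75.0):
    """A rookery cell on the shelf: middle row, depth nearest `target_depth_m`."""
    row = env.grid.nlat // 2
    col = int(np.argmin(np.abs(env.bathymetry[row] - target_depth_m)))
    lon, lat = env.grid.cell_center(row, col)
    return float(lon), float(lat)


def _free_ar1(rng, n_steps: int, a: float, sigma: float) -> np.ndarray:
    """(n_steps, 2) free AR(1) step vectors in km, stationary start."""
    eps = rng.normal(0.0, sigma, size=(n_steps, 2))
    s = np.empty((n_steps, 2))
    prev = rng.normal(0.0, sigma / np.sqrt(1.0 - a**2), size=2)
    for t in range(n_steps):
        prev = a * prev + eps[t]
        s[t] = prev
    return s


def simulate_tracks(
    env: EnvArchive,
    animals: int,
    trips_per_animal: int,
    selection: SelectionSpec | None = None,
    step_params: StepParams | None = None,
    seed: int = 0,
    rookery=None,
    complex_label: str = "A",
    duration_mean_d: float = 6.6,
    duration_sd_d: float = 2.4,
    n_candidates: int = 12,
    season_start=(7, 1),
    season_spread_days: int = 75,
) -> TripSet:
    """Simulate hourly central-place foraging trips over the archive.

    Each trip starts and ends exactly at the rookery.  With selection
    strength 0 the steps are a free AR(1) process closed by uniform drift
    subtraction — exactly the null model used for pseudo-absence tracks.
    With positive strength, each hourly step is chosen among
    ``n_candidates`` AR(1) proposals (augmented with a homing drift
    ``(rookery - x)/steps_remaining`` so the bridge closes) with probability
    proportional to the selection weight at the proposed position; the small
    residual closure error is then removed by drift subtraction.
    """
    selection = selection or SelectionSpec()
    sp = step_params or StepParams()
    if abs(sp.ar_coef) >= 1:
        raise ValueError("AR coefficient magnitude must be < 1")
    if rookery is None:
        rookery = default_rookery(env)
    r_lon, r_lat = float(rookery[0]), float(rookery[1])
    if not env.grid.contains(r_lon, r_lat):
        raise ValueError("rookery outside grid")
    dx_deg, dy_deg = _km_to_deg(r_lat)
    sigma = sp.sigma()
    a = sp.ar_coef
    years = [int(y) for y in env.years]
    n_weeks = len(env.weeks)

    sel_vars = list(selection.preferences) if selection.strength > 0 else []
    rows_out = []
    trip_counter = 0
    for ai in range(animals):
        animal_id = f"A{ai:03d}"
        year = years[ai % len(years)]
        rng = substream(seed, "tracks", ai)
        # first departure within the season window; later trips follow the
        # previous return after 0.5-2.5 d ashore nursing
        t0 = (pd.Timestamp(year, season_start[0], season_start[1])
              + pd.Timedelta(hours=float(rng.uniform(0, 24 * season_spread_days)))).floor("h")
        for ti in range(trips_per_animal):
            trip_counter += 1
            trip_id = f"{animal_id}_T{ti:02d}"
            dur_d = -1.0
            while dur_d < 1.0:
                dur_d = rng.normal(duration_mean_d, duration_sd_d)
            n_steps = max(24, int(round(dur_d * 24)))

            if selection.strength == 0:
                steps = _free_ar1(rng, n_steps, a, sigma)
            else:
                steps = _selective_walk(
                    rng, env, selection, sel_vars, n_steps, a, sigma,
                    r_lon, r_lat, dx_deg, dy_deg, t0, n_weeks, n_candidates,
                )
            # close the loop: remove residual drift uniformly from all steps
            steps = steps - steps.sum(axis=0) / n_steps
            pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            pos[-1] = 0.0  # exact (guards accumulated round-off)
            lons = r_lon + pos[:, 0] * dx_deg
            lats = r_lat + pos[:, 1] * dy_deg
            ts = t0 + pd.to_timedelta(np.arange(n_steps + 1), unit="h")
            rows_out.append(pd.DataFrame({
                "animal_id": animal_id, "complex": complex_label,
                "rookery_lon": r_lon, "rookery_lat": r_lat,
                "trip_id": trip_id, "timestamp": ts, "lon": lons, "lat": lats,
            }))
            ashore_h = float(rng.uniform(12.0, 60.0))
            t0 = (ts[-1] + pd.Timedelta(hours=ashore_h)).floor("h")
    return TripSet(df=pd.concat(rows_out, ignore_index=True))


def _selective_walk(rng, env, selection, sel_vars, n_steps, a, sigma,
                    r_lon, r_lat, dx_deg, dy_deg, t0, n_weeks, k):
    """Sequential AR(1) walk with selection-weighted candidate steps (km)."""
    from .env import nearest_week  # local import to avoid cycle at module load

    ts = t0 + pd.to_timedelta(np.arange(1, n_steps + 1), unit="h")
    weeks = nearest_week(ts, n_weeks)
    year = int(t0.year)
    fields = {}
    for var in sel_vars:
        if var == "bathymetry":
            fields[var] = {0: env.bathymetry}
        else:
            fields[var] = {int(w): env.weekly(var, year, int(w)) for w in np.unique(weeks)}

    steps = np.empty((n_steps, 2))
    x = np.zeros(2)
    prev = rng.normal(0.0, sigma / np.sqrt(1.0 - a**2), size=2)
    for t in range(n_steps):
        remaining = n_steps - t
        homing = -x / remaining
        eps = rng.normal(0.0, sigma, size=(k, 2))
        cand = a * prev + eps + homing
        # Half the proposals keep their speed but redraw the heading: the
        # AR innovation alone spreads proposals by ~2 km against ~11 km
        # cells, far too little for covariate-based selection to act on.
        n_exp = k // 2
        speed = np.hypot(cand[:n_exp, 0], cand[:n_exp, 1])
        theta = rng.uniform(0.0, 2.0 * np.pi, n_exp)
        cand[:n_exp, 0] = speed * np.cos(theta)
        cand[:n_exp, 1] = speed * np.sin(theta)
        pos = x + cand
        lons = r_lon + pos[:, 0] * dx_deg
        lats = r_lat + pos[:, 1] * dy_deg
        rr, cc = env.grid.locate(lons, lats)
        inside = (rr >= 0) & (cc >= 0)
        vals = {}
        for var in sel_vars:
            fld = fields[var][0] if var == "bathymetry" else fields[var][int(weeks[t])]
            v = np.zeros(k)
            v[inside] = fld[rr[inside], cc[inside]]
            vals[var] = v
        w = selection.weight(vals)
        w = np.where(inside, w, 0.0)
        total = w.sum()
        p = np.full(k, 1.0 / k) if total <= 0 else w / total
        i = rng.choice(k, p=p)
        steps[t] = cand[i]
        prev = cand[i]
        x = pos[i]
    return steps


# ---------------------------------------------------------------------------
# catch grid
# ---------------------------------------------------------------------------

@dataclass
class CatchGrid:
    """Coarse fishery-catch grid: mean catch (tonnes) per 0.25-degree cell."""

    grid: GridSpec
    catch_t: np.ndarray  # (nlat, nlon), >= 0

    def to_csv(self, path) -> None:
        glon, glat = np.meshgrid(self.grid.lons(), self.grid.lats())
        pd.DataFrame({
            "lon": glon.ravel(), "lat": glat.ravel(), "catch_t": self.catch_t.ravel(),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CatchGrid":
        df = pd.read_csv(path)
        lons = np.sort(df["lon"].unique())
        lats = np.sort(df["lat"].unique())
        grid = GridSpec(
            lon0=float(lons[0]), lat0=float(lats[0]),
            dlon=float(lons[1] - lons[0]), dlat=float(lats[1] - lats[0]),
            nlon=len(lons), nlat=len(lats),
        )
        arr = np.zeros(grid.shape)
        r, c = grid.locate(df["lon"].to_numpy(), df["lat"].to_numpy())
        arr[r, c] = df["catch_t"].to_numpy()
        return cls(grid=grid, catch_t=arr)


def coarse_grid_for(env: EnvArchive, res_deg: float = 0.25) -> GridSpec:
    """0.25-degree grid covering the archive's bounding box."""
    g = env.grid
    lon_min = g.lon0 - g.dlon / 2
    lat_min = g.lat0 - g.dlat / 2
    lon_max = g.lon0 + g.dlon * (g.nlon - 0.5)
    lat_max = g.lat0 + g.dlat * (g.nlat - 0.5)
    nlon = max(8, int(np.ceil((lon_max - lon_min) / res_deg)))
    nlat = max(8, int(np.ceil((lat_max - lat_min) / res_deg)))
    return GridSpec(
        lon0=lon_min + res_deg / 2, lat0=lat_min + res_deg / 2,
        dlon=res_deg, dlat=res_deg, nlon=nlon, nlat=nlat,
    )


def make_catch_grid(
    env: EnvArchive,
    mode: str = "shelf-weighted",
    seed: int = 0,
    total_t: float = 750_968.0,
    res_deg: float = 0.25,
    mask_cells=None,
) -> CatchGrid:
    """Synthetic coarse catch grid.

    Modes: ``uniform`` (iid weights everywhere), ``shelf-weighted`` (weights
    proportional to the shelf fine-cell count under each coarse cell; basin
    cells get zero), ``from-mask`` (all catch spread uniformly over the
    supplied coarse (row, col) cells; empty mask -> all-zero grid).  The grid
    totals `total_t` tonnes exactly (unless empty).
    """
    coarse = coarse_grid_for(env, res_deg)
    rng = substream(seed, "catch", mode)
    weights = np.zeros(coarse.shape)
    if mode == "uniform":
        weights = rng.uniform(0.2, 1.0, size=coarse.shape)
    elif mode == "shelf-weighted":
        glon, glat = np.meshgrid(env.grid.lons(), env.grid.lats())
        rr, cc = coarse.locate(glon.ravel(), glat.ravel())
        shelf = env.shelf_mask.ravel()
        np.add.at(weights, (rr[shelf], cc[shelf]), 1.0)
        weights *= rng.uniform(0.2, 1.0, size=coarse.shape)
    elif mode == "from-mask":
        for r, c in (mask_cells or []):
            weights[r, c] = 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total_w = weights.sum()
    catch = weights * (total_t / total_w) if total_w > 0 else weights
    return CatchGrid(grid=coarse, catch_t=catch)
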