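import numpy as np
import pandas as pd
import pytest

import cpforage as cp
from cpforage.pseudoabsence import (SimulatedTracks, VARParams, fit_var,
                                    filter_candidates, rank_candidates,
                                    select_partner, simulate_candidates)


def trip_from_steps(steps, start="2015-07-10", lon0=-167.0, lat0=56.5):
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    ts = pd.date_range(start, periods=len(pos), freq="h")
    return pd.DataFrame({"timestamp": ts, "lon": lon0 + pos[:, 0], "lat": lat0 + pos[:, 1]})


def simulate_var(mu, A, Sigma, n, rng):
    L = np.linalg.cholesky(Sigma)
    s = np.empty((n, 2))
    prev = np.zeros(2)
    for t in range(n):
        prev = A @ prev + L @ rng.standard_normal(2)
        s[t] = prev + mu
    return s


class TestFitVar:
    def test_parameter_recovery_from_known_process(self, rng):
        """LS estimates converge to the generating (mu, A, Sigma) at n=5000."""
        mu = np.array([0.01, -0.005])
        A = np.array([[0.6, 0.1], [-0.05, 0.5]])
        Sigma = np.array([[4e-4, 1e-4], [1e-4, 3e-4]])
        steps = simulate_var(mu, A, Sigma, 5000, rng)
        params = fit_var(trip_from_steps(steps))
        assert np.linalg.norm(params.A - A) / np.linalg.norm(A) < 0.05
        assert np.linalg.norm(params.Sigma - Sigma) / np.linalg.norm(Sigma) < 0.05
        assert np.allclose(params.mu, mu, atol=2e-3)

    def test_constant_steps_give_zero_A(self):
        steps = np.tile([0.02, 0.01], (20, 1))
        params = fit_var(trip_from_steps(steps))
        assert np.allclose(params.A, 0.0)
        assert np.allclose(params.mu, [0.02, 0.01])
        assert "degenerate-steps" in params.flags

    def test_white_noise_steps_estimate_near_zero_A(self, rng):
        steps = rng.normal(0, 0.02, size=(2000, 2))
        params = fit_var(trip_from_steps(steps))
        assert np.abs(params.A).max() < 0.1

    def test_rejects_short_trips(self):
        with pytest.raises(ValueError):
            fit_var(trip_from_steps(np.zeros((5, 2))))

    def test_spectral_radius_below_one(self, rng):
        steps = simulate_var(np.zeros(2), 0.9 * np.eye(2), 1e-4 * np.eye(2), 300, rng)
        params = fit_var(trip_from_steps(steps))
        assert np.max(np.abs(np.linalg.eigvals(params.A))) < 1.0


@pytest.fixture(scope="module")
def trip_and_params():
    rng = np.random.default_rng(5)
    steps = simulate_var(np.zeros(2), 0.5 * np.eye(2), 2e-3 * np.eye(2), 120, rng)
    trip = trip_from_steps(steps)
    return trip, fit_var(trip)


class TestSimulateCandidates:
    def test_endpoints_pinned_exactly(self, trip_and_params):
        trip, params = trip_and_params
        cands = simulate_candidates(params, trip, n=20, seed=1)
        assert np.allclose(cands.lon[:, 0], trip["lon"].iloc[0])
        assert np.allclose(cands.lat[:, 0], trip["lat"].iloc[0])
        assert np.allclose(cands.lon[:, -1], trip["lon"].iloc[-1])
        assert np.allclose(cands.lat[:, -1], trip["lat"].iloc[-1])

    def test_n_tracks_with_trip_timestamps(self, trip_and_params):
        trip, params = trip_and_params
        cands = simulate_candidates(params, trip, n=100, seed=2)
        assert cands.n == 100
        assert (cands.timestamps == pd.DatetimeIndex(trip["timestamp"])).all()
        assert cands.lon.shape == (100, len(trip))

    def test_speed_resemblance(self, trip_and_params):
        """Median candidate mean-step length is within 25% of the trip's."""
        trip, params = trip_and_params
        cands = simulate_candidates(params, trip, n=100, seed=3)
        xy = trip[["lon", "lat"]].to_numpy()
        real = np.mean(cp.haversine_km(xy[:-1, 0], xy[:-1, 1], xy[1:, 0], xy[1:, 1]))
        sim = [np.mean(cp.haversine_km(cands.lon[i, :-1], cands.lat[i, :-1],
                                       cands.lon[i, 1:], cands.lat[i, 1:]))
               for i in range(cands.n)]
        assert abs(np.median(sim) - real) / real < 0.25

    def test_determinism(self, trip_and_params):
        trip, params = trip_and_params
        a = simulate_candidates(params, trip, n=10, seed=9)
        b = simulate_candidates(params, trip, n=10, seed=9)
        assert np.array_equal(a.lon, b.lon) and np.array_equal(a.lat, b.lat)


def brute_force_filter(cands, presences, grid, window_days):
    """O(n^2) reference: same/adjacent cell within the day window."""
    n, m = cands.lon.shape
    keep = np.ones((n, m), dtype=bool)
    pres = [(int(r), int(c), pd.Timestamp(d).toordinal())
            for r, c, d in zip(presences["row"], presences["col"], presences["date"])]
    days = [pd.Timestamp(t).normalize().toordinal() for t in cands.timestamps]
    for i in range(n):
        for j in range(m):
            r, c = grid.locate(cands.lon[i, j], cands.lat[i, j])
            if r < 0 or c < 0:
                continue
            for pr, pc, pdy in pres:
                if abs(int(r) - pr) <= 1 and abs(int(c) - pc) <= 1 and abs(days[j] - pdy) <= window_days:
                    keep[i, j] = False
                    break
    return keep


class TestFilterCandidates:
    def make_instance(self, grid, rng, n_cand=4, n_pos=40, n_pres=40):
        lon = rng.uniform(grid.lon0, grid.lon0 + grid.dlon * (grid.nlon - 1), (n_cand, n_pos))
        lat = rng.uniform(grid.lat0, grid.lat0 + grid.dlat * (grid.nlat - 1), (n_cand, n_pos))
        ts = pd.date_range("2015-07-01", periods=n_pos, freq="6h")
        cands = SimulatedTracks(lon=lon, lat=lat, timestamps=pd.DatetimeIndex(ts),
                                flags=[None] * n_cand)
        pr = rng.integers(0, grid.nlat, n_pres)
        pc = rng.integers(0, grid.nlon, n_pres)
        pdates = pd.to_datetime(rng.integers(0, 12, n_pres), unit="D",
                                origin="2015-07-01")
        presences = pd.DataFrame({"row": pr, "col": pc, "date": pdates})
        return cands, presences

    def test_same_cell_same_day_removed(self, small_grid):
        lon, lat = small_grid.cell_center(3, 3)
        ts = pd.DatetimeIndex([pd.Timestamp("2015-07-05 10:00")])
        cands = SimulatedTracks(lon=np.array([[lon]]), lat=np.array([[lat]]),
                                timestamps=ts, flags=[None])
        pres = pd.DataFrame({"row": [3], "col": [3],
                             "date": [pd.Timestamp("2015-07-05")]})
        keep = filter_candidates(cands, pres, small_grid, window_days=6)
        assert not keep[0, 0]

    def test_diagonal_neighbour_window_boundary(self, small_grid):
        """Diagonal neighbour 6 days apart removed; 7 days apart kept."""
        lon, lat = small_grid.cell_center(4, 4)
        ts = pd.DatetimeIndex([pd.Timestamp("2015-07-10 00:00")])
        cands = SimulatedTracks(lon=np.array([[lon]]), lat=np.array([[lat]]),
                                timestamps=ts, flags=[None])
        for gap, expected_kept in [(6, False), (7, True)]:
            pres = pd.DataFrame({"row": [5], "col": [5],
                                 "date": [pd.Timestamp("2015-07-10") + pd.Timedelta(days=gap)]})
            keep = filter_candidates(cands, pres, small_grid, window_days=6)
            assert keep[0, 0] == expected_kept

    def test_matches_brute_force_on_random_instances(self, small_grid):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cands, pres = self.make_instance(small_grid, rng)
            fast = filter_candidates(cands, pres, small_grid, window_days=6)
            slow = brute_force_filter(cands, pres, small_grid, window_days=6)
            assert np.array_equal(fast, slow)

    def test_empty_presences_keep_everything(self, small_grid, rng):
        cands, _ = self.make_instance(small_grid, rng)
        keep = filter_candidates(cands, cands_empty_presences(), small_grid)
        assert keep.all()


def cands_empty_presences():
    return pd.DataFrame({"row": [], "col": [], "date": []})


class TestSelectPartner:
    def test_most_days_lowest_index_for_replicate_one(self):
        rng = np.random.default_rng(0)
        assert select_partner([9, 12, 12, 7], 1, rng) == 1

    def test_all_filtered_returns_none(self):
        rng = np.random.default_rng(0)
        assert select_partner([0, 0, 0], 1, rng) is None

    def test_second_replicate_differs_when_possible(self):
        assert (select_partner([5, 8, 3], 2, np.random.default_rng(1))
                != select_partner([5, 8, 3], 1, np.random.default_rng(1)))

    def test_ranking_order(self):
        assert rank_candidates([0, 4, 9, 9, 1]) == [2, 3, 1, 4]


class TestBuildReplicates:
    def test_exact_label_balance_every_replicate(self, small_reps):
        for habitat, reps in small_reps.items():
            for df in reps:
                n_p = (df["label"] == "presence").sum()
                n_a = (df["label"] == "absence").sum()
                assert n_p == n_a > 0

    def test_paired_days_match_within_trip(self, small_reps):
        """Within each trip, presence and absence days match one-to-one."""
        for reps in small_reps.values():
            for df in reps:
                for _, g in df.groupby("trip_id"):
                    p_days = sorted(g.loc[g["label"] == "presence", "date"])
                    a_days = sorted(g.loc[g["label"] == "absence", "date"])
                    assert p_days == a_days

    def test_at_most_one_presence_per_trip_day(self, small_reps):
        for reps in small_reps.values():
            for df in reps:
                pres = df[df["label"] == "presence"]
                assert pres.groupby(["trip_id", "date"]).size().max() == 1

    def test_replicates_differ_but_are_deterministic(self, small_trips, small_env,
                                                     small_reps):
        again = cp.build_replicates(small_trips, small_env, n_replicates=3, seed=7,
                                    n_candidates=15)
        for habitat in small_reps:
            for a, b in zip(small_reps[habitat], again[habitat]):
                pd.testing.assert_frame_equal(a, b)
        shelf = small_reps["shelf"]
        if len(shelf) >= 2 and len(shelf[0]) and len(shelf[1]):
            assert not shelf[0].equals(shelf[1])

    def test_rows_carry_covariates_and_metadata(self, small_reps):
        for reps in small_reps.values():
            for df in reps:
                for col in ("bathymetry", "temp_bottom", "phl_avg", "eup",
                            "trip_id", "animal_id", "habitat", "year", "replicate"):
                    assert col in df.columns
                assert not df[list(cp.COVARIATES)].isna().any().any()
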