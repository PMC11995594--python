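import numpy as np
import pandas as pd
import pytest

from cpforage.sdm import (HabitatModel, auc, collinearity_screen,
                          importance_scaled, loess_smooth, make_trip_folds,
                          make_year_folds, partial_dependence, predict_proba,
                          tune_and_fit)


def brute_force_auc(labels, scores):
    """O(n^2) pairwise-comparison reference, ties counted 0.5."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0

    def test_all_equal_scores_give_half(self):
        assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        """Rank-based AUC equals the O(n^2) pairwise oracle exactly."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            s = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
            assert np.isclose(auc(y, s), brute_force_auc(y, s), atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.5, 0.6])


class TestCollinearityScreen:
    def make_df(self, rng, r_pair=0.0):
        n = 300
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "bathymetry": base,
            "temp_bottom": r_pair * base + np.sqrt(max(1 - r_pair**2, 0)) * rng.normal(size=n),
            "temp_surface": rng.normal(size=n),
            "phl": rng.normal(size=n),
        })
        return df

    def test_static_variable_loses_to_dynamic(self, rng):
        df = self.make_df(rng, r_pair=0.95)
        kept, flagged = collinearity_screen(df, df.columns, threshold=0.7)
        assert "bathymetry" not in kept
        assert "temp_bottom" in kept
        assert any({a, b} == {"bathymetry", "temp_bottom"} for a, b, _ in flagged)

    def test_no_flagged_pairs_is_identity(self, rng):
        df = self.make_df(rng, r_pair=0.1)
        kept, flagged = collinearity_screen(df, df.columns, threshold=0.7)
        assert kept == list(df.columns)
        assert flagged == []

    def test_exact_linear_dependence_detected(self, rng):
        df = self.make_df(rng)
        df["temp_bottom"] = 2.0 * df["bathymetry"] + 1.0
        kept, flagged = collinearity_screen(df, df.columns, threshold=0.7)
        rs = [r for a, b, r in flagged if {a, b} == {"bathymetry", "temp_bottom"}]
        assert rs and np.isclose(abs(rs[0]), 1.0)


def toy_dataset(rng, n_trips=10, rows_per_trip=12, n_years=3, separable=False,
                permuted=False):
    rows = []
    for t in range(n_trips):
        year = 2015 + t % n_years
        for i in range(rows_per_trip):
            label = "presence" if i % 2 == 0 else "absence"
            x = rng.normal(loc=1.0 if (label == "presence" and separable) else 0.0)
            rows.append({
                "trip_id": f"T{t:02d}", "year": year, "label": label,
                "v1": (3.0 if label == "presence" else -3.0) if separable else rng.normal(),
                "v2": x, "v3": rng.normal(), "v4": rng.normal(),
            })
    df = pd.DataFrame(rows)
    if permuted:
        df["label"] = rng.permutation(df["label"].to_numpy())
    return df


class TestTripFolds:
    def test_ten_equal_trips_one_per_fold(self, rng):
        df = toy_dataset(rng, n_trips=10)
        folds = make_trip_folds(df, k=10, seed=0)
        per_trip = df.assign(fold=folds).groupby("trip_id")["fold"].nunique()
        assert (per_trip == 1).all()
        assert len(np.unique(folds)) == 10

    def test_no_trip_split_across_folds(self, rng):
        df = toy_dataset(rng, n_trips=7, rows_per_trip=9)
        folds = make_trip_folds(df, k=4, seed=1)
        assert (df.assign(fold=folds).groupby("trip_id")["fold"].nunique() == 1).all()

    def test_greedy_balance_bound(self, rng):
        """max fold size - min fold size <= largest trip size (greedy bin packing)."""
        sizes = [40, 25, 25, 10, 8, 8, 5, 3]
        rows = []
        for t, s in enumerate(sizes):
            rows += [{"trip_id": f"T{t}", "year": 2015, "label": "presence"}] * s
        df = pd.DataFrame(rows)
        folds = make_trip_folds(df, k=3, seed=2)
        counts = pd.Series(folds).value_counts()
        assert counts.max() - counts.min() <= max(sizes)

    def test_fewer_trips_than_k_reduces_folds(self, rng):
        df = toy_dataset(rng, n_trips=3)
        folds = make_trip_folds(df, k=10, seed=0)
        assert len(np.unique(folds)) == 3

    def test_year_folds_single_year_flagged(self, rng):
        df = toy_dataset(rng, n_years=1)
        assert make_year_folds(df, k=10, seed=0) is None

    def test_year_folds_never_split_years(self, rng):
        df = toy_dataset(rng, n_trips=12, n_years=3)
        folds = make_year_folds(df, k=10, seed=0)
        assert (df.assign(fold=folds).groupby("year")["fold"].nunique() == 1).all()


class TestTuneAndFit:
    def test_separable_dataset_reaches_high_auc(self, rng):
        df = toy_dataset(rng, separable=True)
        folds = make_trip_folds(df, k=5, seed=0)
        _, _, a, _ = tune_and_fit(df, ["v1", "v2", "v3", "v4"], folds, seed=0,
                                  n_trees=100)
        assert a >= 0.99

    def test_permuted_labels_near_half(self, rng):
        df = toy_dataset(rng, n_trips=20, rows_per_trip=20, permuted=True)
        folds = make_trip_folds(df, k=10, seed=0)
        _, _, a, _ = tune_and_fit(df, ["v1", "v2", "v3", "v4"], folds, seed=0,
                                  n_trees=100)
        assert 0.4 <= a <= 0.6

    def test_choice_reproducible(self, rng):
        df = toy_dataset(rng)
        folds = make_trip_folds(df, k=5, seed=3)
        m1 = tune_and_fit(df, ["v1", "v2", "v3", "v4"], folds, seed=3, n_trees=50)[1]
        m2 = tune_and_fit(df, ["v1", "v2", "v3", "v4"], folds, seed=3, n_trees=50)[1]
        assert m1 == m2

    def test_single_label_rejected(self, rng):
        df = toy_dataset(rng)
        df["label"] = "presence"
        with pytest.raises(ValueError):
            tune_and_fit(df, ["v1"], np.zeros(len(df)), seed=0)

    def test_no_leakage_across_folds(self, rng):
        """Out-of-fold scores for fold f do not depend on other held-out folds."""
        from cpforage.sdm import _oof_scores
        df = toy_dataset(rng, n_trips=6, rows_per_trip=10, separable=True)
        folds = make_trip_folds(df, k=3, seed=0)
        X = df[["v1", "v2", "v3", "v4"]].to_numpy()
        y = (df["label"] == "presence").astype(int).to_numpy()
        full = _oof_scores(X, y, folds, 2, 50, 1, 7)
        # refit fold 0's model manually with the same seed: identical scores
        from cpforage.sdm import _rf
        clf = _rf(2, 50, 1, 7)
        tr = folds != 0
        clf.fit(X[tr], y[tr])
        manual = clf.predict_proba(X[~tr])[:, list(clf.classes_).index(1)]
        assert np.allclose(full[~tr], manual)


class TestImportanceScaled:
    class FakeModel:
        def __init__(self, imp):
            self.feature_importances_ = np.asarray(imp, dtype=float)

    def test_linear_map(self):
        out = importance_scaled(self.FakeModel([2, 5, 8]))
        assert np.allclose(out, [0, 50, 100])

    def test_equal_importances_all_fifty(self):
        out = importance_scaled(self.FakeModel([3, 3, 3]))
        assert np.allclose(out, [50, 50, 50])


class TestPartialDependence:
    def test_ignored_variable_gives_flat_curve(self, rng):
        df = toy_dataset(rng, n_trips=12, rows_per_trip=16, separable=True)
        folds = make_trip_folds(df, k=5, seed=0)
        model, *_ = tune_and_fit(df, ["v1", "v3"], folds, seed=0, n_trees=200)
        grid, curve = partial_dependence(model, df, ["v1", "v3"], "v3")
        assert curve.max() - curve.min() < 0.04

    def test_pd_values_are_probabilities(self, rng):
        df = toy_dataset(rng)
        folds = make_trip_folds(df, k=5, seed=0)
        model, *_ = tune_and_fit(df, ["v1", "v2"], folds, seed=0, n_trees=50)
        _, curve = partial_dependence(model, df, ["v1", "v2"], "v1")
        assert ((curve >= 0) & (curve <= 1)).all()

    def test_loess_preserves_linear_trend(self):
        x = np.linspace(0, 1, 50)
        y = 2 * x + 1
        assert np.allclose(loess_smooth(x, y), y, atol=1e-6)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    reps = [toy_dataset(rng, n_trips=8, rows_per_trip=10, separable=True)
            for _ in range(3)]
    for df in reps:
        df["animal_id"] = df["trip_id"]
        df["replicate"] = 1
    model = HabitatModel(reps, habitat="shelf", covariates=("v1", "v2", "v3", "v4"),
                         n_trees=100, cv_folds=5)
    return model.fit(seed=4, temporal=False)


class TestHabitatModelObject:
    def test_summary_row(self, fitted):
        s = fitted.summary().iloc[0]
        assert s["habitat"] == "shelf"
        assert 0 <= s["auc_cv_mean"] <= 1
        assert s["mtry_mode"] in (2, 3, 4)

    def test_predict_bounds_and_shape(self, fitted, rng):
        X = rng.normal(size=(20, 4))
        p = fitted.predict(X)
        assert p.shape == (20,) and (p >= 0).all() and (p <= 1).all()

    def test_informative_variable_ranks_first(self, fitted):
        imp = fitted.importance()
        assert imp.iloc[0]["variable"] == "v1"
        assert imp.set_index("variable").loc["v3", "importance"] < 20

    def test_spatial_transfer_on_same_distribution(self, fitted):
        rng = np.random.default_rng(33)
        other = toy_dataset(rng, n_trips=8, rows_per_trip=10, separable=True)
        a = fitted.spatial_transfer(other)
        assert a > 0.9  # same generating process, near-resubstitution skill

    def test_spatial_transfer_opposite_preference_below_half(self, fitted):
        rng = np.random.default_rng(34)
        other = toy_dataset(rng, n_trips=8, rows_per_trip=10, separable=True)
        flipped = other.assign(label=other["label"].map(
            {"presence": "absence", "absence": "presence"}))
        assert fitted.spatial_transfer(flipped) < 0.5
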