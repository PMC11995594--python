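"""Habitat-selection classifier ensembles.

The modelling unit is a :class:`HabitatModel`: ten replicate
presence/pseudo-absence datasets for one habitat (shelf or basin) and one
scope (all complexes pooled, or a single complex).  ``fit()`` trains one
random forest per replicate — 500 trees, minimum node size 1, mtry tuned
over {2, 3, 4} by trip-grouped 10-fold cross-validated AUC — and returns a
:class:`HabitatModelResults` carrying the fitted forests, cross-validated
and temporal-transfer AUCs, scaled Gini importances and partial-dependence
curves, with a ``summary()`` table.

AUC here is the Mann-Whitney statistic: the probability that a random
presence outscores a random absence, ties counted half.  Cross-validation
folds never split a trip (a presence and its paired pseudo-absence share a
trip id), so the metric measures transfer to unseen trips, not
autocorrelated interpolation.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from ._rand import derive_seed
from .env import COVARIATES, STATIC_VARS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metric and fold helpers
# ---------------------------------------------------------------------------

def auc(labels, scores) -> float:
    """Rank-based AUC (Mann-Whitney U / (n_pos * n_neg)); ties count 0.5."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc needs both classes")
    r = rankdata(s)
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def collinearity_screen(dataset: pd.DataFrame, covariates=COVARIATES, threshold: float = 0.7,
                        static_vars=STATIC_VARS):
    """Drop one of each |Pearson r| > threshold covariate pair.

    The loser is the static variable when a static/dynamic pair is flagged
    (dynamic variables carry forecast skill; e.g. bathymetry loses to bottom
    temperature in the basin), otherwise the later variable in `covariates`.
    Returns ``(retained, flagged)`` where flagged is a list of
    ``(var_a, var_b, r)`` tuples for every pair over the threshold.
    """
    covariates = [c for c in covariates if c in dataset.columns]
    corr = dataset[covariates].corr(method="pearson")
    flagged = []
    dropped = set()
    order = {c: i for i, c in enumerate(covariates)}
    pairs = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(covariates) for b in covariates[i + 1:]
        if abs(corr.loc[a, b]) > threshold
    ]
    for a, b, r in sorted(pairs, key=lambda p: -abs(p[2])):
        flagged.append((a, b, r))
        if a in dropped or b in dropped:
            continue
        if a in static_vars and b not in static_vars:
            dropped.add(a)
        elif b in static_vars and a not in static_vars:
            dropped.add(b)
        else:
            dropped.add(b if order[b] > order[a] else a)
    retained = [c for c in covariates if c not in dropped]
    return retained, flagged


def _greedy_folds(groups: dict, k: int, rng: np.random.Generator) -> dict:
    """Greedy balanced grouping: largest group first into the smallest fold."""
    k = min(k, len(groups))
    names = list(groups)
    rng.shuffle(names)  # seeded tie-break among equal-sized groups
    names.sort(key=lambda g: -groups[g])
    sizes = np.zeros(k)
    assign = {}
    for g in names:
        f = int(np.argmin(sizes))
        assign[g] = f
        sizes[f] += groups[g]
    return assign


def make_trip_folds(dataset: pd.DataFrame, k: int = 10, seed: int = 0) -> np.ndarray:
    """Per-row fold ids; whole trips (presence + paired absence) per fold."""
    counts = dataset.groupby("trip_id").size().to_dict()
    assign = _greedy_folds(counts, k, np.random.default_rng(seed))
    return dataset["trip_id"].map(assign).to_numpy()


def make_year_folds(dataset: pd.DataFrame, k: int = 10, seed: int = 0):
    """Fold ids grouping whole years; None if only a single year exists."""
    counts = dataset.groupby("year").size().to_dict()
    if len(counts) < 2:
        return None
    assign = _greedy_folds(counts, k, np.random.default_rng(seed))
    return dataset["year"].map(assign).to_numpy()


def _rf(mtry: int, n_trees: int, min_node: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, min_samples_leaf=min_node,
        random_state=seed, n_jobs=1,
    )


def _oof_scores(X, y, folds, mtry, n_trees, min_node, seed) -> np.ndarray:
    scores = np.empty(len(y))
    for f in np.unique(folds):
        tr = folds != f
        clf = _rf(mtry, n_trees, min_node, seed)
        clf.fit(X[tr], y[tr])
        scores[~tr] = clf.predict_proba(X[~tr])[:, list(clf.classes_).index(1)]
    return scores


def tune_and_fit(dataset: pd.DataFrame, variables, folds, mtry_grid=(2, 3, 4),
                 n_trees: int = 500, min_node: int = 1, seed: int = 0):
    """Tune mtry by pooled out-of-fold AUC; refit on the full dataset.

    Returns ``(model, chosen_mtry, auc_cv, oof_scores)``.  Ties in AUC go to
    the smaller mtry.
    """
    y = (dataset["label"] == "presence").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both presence and absence rows")
    if dataset["trip_id"].nunique() < 2:
        raise ValueError("need at least 2 trips")
    X = dataset[list(variables)].to_numpy(dtype=float)
    best = None
    for mtry in sorted(mtry_grid):
        m = min(mtry, len(variables))
        oof = _oof_scores(X, y, folds, m, n_trees, min_node, seed)
        a = auc(y, oof)
        if best is None or a > best[1]:
            best = (mtry, a, oof)
    mtry, auc_cv, oof = best
    model = _rf(min(mtry, len(variables)), n_trees, min_node, seed)
    model.fit(X, y)
    return model, mtry, auc_cv, oof


def predict_proba(model, X) -> np.ndarray:
    """P(presence) from a fitted forest (class-order safe)."""
    return model.predict_proba(np.asarray(X, dtype=float))[:, list(model.classes_).index(1)]


def importance_scaled(model) -> np.ndarray:
    """Gini importances linearly rescaled so max -> 100, min -> 0.

    Degenerate all-equal importances map to 50 for every variable.
    """
    raw = np.asarray(model.feature_importances_, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 50.0)
    return 100.0 * (raw - lo) / (hi - lo)


def partial_dependence(model, dataset: pd.DataFrame, variables, var: str, n_grid: int = 50):
    """Marginal-effect curve: mean P(presence) with `var` pinned to each grid value.

    Grid values are quantile-spaced over the dataset's observed values.
    Returns ``(grid, pd_values)``.
    """
    X = dataset[list(variables)].to_numpy(dtype=float).copy()
    j = list(variables).index(var)
    grid = np.quantile(dataset[var].to_numpy(dtype=float), np.linspace(0.0, 1.0, n_grid))
    out = np.empty(n_grid)
    for i, v in enumerate(grid):
        X[:, j] = v
        out[i] = predict_proba(model, X).mean()
    return grid, out


def loess_smooth(x, y, span: float = 0.75):
    """Lowess-smoothed curve on (x, y), returned on the same x."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm = lowess(y, x, frac=span, return_sorted=True)
    return np.interp(x, sm[:, 0], sm[:, 1])


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class HabitatModel:
    """Replicate random-forest ensemble for one habitat and scope.

    Parameters
    ----------
    replicates : list of DataFrame
        Replicate presence/pseudo-absence datasets (label, trip_id, year and
        covariate columns), as produced by
        :func:`cpforage.pseudoabsence.build_replicates`.
    habitat : str
        'shelf' or 'basin' (metadata only).
    scope : str
        'all' for the pooled model or a rookery-complex label.
    """

    def __init__(self, replicates, habitat: str = "shelf", scope: str = "all",
                 covariates=COVARIATES, mtry_grid=(2, 3, 4), n_trees: int = 500,
                 min_node_size: int = 1, cv_folds: int = 10,
                 collinearity_threshold: float = 0.7):
        if not replicates:
            raise ValueError("no replicate datasets supplied")
        self.replicates = list(replicates)
        self.habitat = habitat
        self.scope = scope
        self.covariates = [c for c in covariates if c in self.replicates[0].columns]
        self.mtry_grid = tuple(mtry_grid)
        self.n_trees = n_trees
        self.min_node_size = min_node_size
        self.cv_folds = cv_folds
        self.collinearity_threshold = collinearity_threshold

    @classmethod
    def from_replicates(cls, replicates_by_habitat: dict, habitat: str, **kw) -> "HabitatModel":
        if habitat not in replicates_by_habitat:
            raise KeyError(f"no datasets for habitat {habitat!r}")
        return cls(replicates_by_habitat[habitat], habitat=habitat, **kw)

    def fit(self, seed: int = 0, temporal: bool = True) -> "HabitatModelResults":
        # screen collinearity once, on the pooled replicates, so every
        # replicate model shares one variable list
        pooled = pd.concat(self.replicates, ignore_index=True)
        variables, flagged = collinearity_screen(
            pooled, self.covariates, self.collinearity_threshold
        )
        for a, b, r in flagged:
            log.info("collinearity (%s): |r|=%.2f between %s and %s", self.habitat, abs(r), a, b)
        models, mtrys, auc_cv, auc_time, oofs = [], [], [], [], []
        for i, ds in enumerate(self.replicates):
            rep_seed = derive_seed(seed, "rf", self.habitat, self.scope, i)
            folds = make_trip_folds(ds, self.cv_folds, seed=rep_seed)
            model, mtry, a_cv, oof = tune_and_fit(
                ds, variables, folds, self.mtry_grid, self.n_trees, self.min_node_size, rep_seed
            )
            models.append(model)
            mtrys.append(mtry)
            auc_cv.append(a_cv)
            oofs.append(oof)
            yfolds = make_year_folds(ds, self.cv_folds, seed=rep_seed) if temporal else None
            if yfolds is None:
                auc_time.append(np.nan)
            else:
                y = (ds["label"] == "presence").astype(int).to_numpy()
                X = ds[variables].to_numpy(dtype=float)
                scores = _oof_scores(X, y, yfolds, min(mtry, len(variables)),
                                     self.n_trees, self.min_node_size, rep_seed)
                auc_time.append(auc(y, scores))
        return HabitatModelResults(
            model=self, variables=variables, flagged_pairs=flagged,
            replicate_models=models, mtry=mtrys,
            auc_cv=np.array(auc_cv), auc_time=np.array(auc_time),
            oof_scores=oofs, seed=seed,
        )


@dataclass
class HabitatModelResults:
    """Fitted ensemble: models, metrics, importances, marginal effects."""

    model: HabitatModel
    variables: list
    flagged_pairs: list
    replicate_models: list
    mtry: list
    auc_cv: np.ndarray
    auc_time: np.ndarray
    oof_scores: list
    seed: int
    _importance: np.ndarray = field(default=None, repr=False)

    # -- metrics ---------------------------------------------------------
    @property
    def auc_cv_mean(self) -> float:
        return float(np.mean(self.auc_cv))

    @property
    def auc_cv_sd(self) -> float:
        return float(np.std(self.auc_cv, ddof=1)) if len(self.auc_cv) > 1 else 0.0

    @property
    def auc_time_mean(self) -> float:
        vals = self.auc_time[~np.isnan(self.auc_time)]
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def auc_time_sd(self) -> float:
        vals = self.auc_time[~np.isnan(self.auc_time)]
        return float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")

    # -- importance ------------------------------------------------------
    def importance(self) -> pd.DataFrame:
        """Per-variable scaled importances: replicate mean, sd, and rank."""
        per_rep = np.vstack([importance_scaled(m) for m in self.replicate_models])
        mean = per_rep.mean(axis=0)
        sd = per_rep.std(axis=0, ddof=1) if per_rep.shape[0] > 1 else np.zeros(per_rep.shape[1])
        out = pd.DataFrame({"variable": self.variables, "importance": mean, "sd": sd})
        return out.sort_values("importance", ascending=False).reset_index(drop=True)

    # -- marginal effects ------------------------------------------------
    def partial_dependence(self, var: str, n_grid: int = 50, span: float = 0.75):
        """Per-replicate PD curves plus a lowess-smoothed ensemble curve.

        Returns ``(grid, curves (n_rep, n_grid), smoothed ensemble curve)``.
        """
        grids, curves = [], []
        for m, ds in zip(self.replicate_models, self.model.replicates):
            g, c = partial_dependence(m, ds, self.variables, var, n_grid)
            grids.append(g)
            curves.append(c)
        grid = np.mean(grids, axis=0)
        curves = np.vstack([np.interp(grid, g, c) for g, c in zip(grids, curves)])
        ens = loess_smooth(grid, curves.mean(axis=0), span=span)
        return grid, curves, ens

    # -- prediction ------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Ensemble-mean P(presence) for rows of covariate values.

        `X` may be a DataFrame (columns selected by name) or an array already
        ordered like ``self.variables``.
        """
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(dtype=float)
        preds = [predict_proba(m, X) for m in self.replicate_models]
        return np.mean(preds, axis=0)

    def predict_replicates(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(dtype=float)
        return np.vstack([predict_proba(m, X) for m in self.replicate_models])

    # -- transfer --------------------------------------------------------
    def spatial_transfer(self, other_dataset: pd.DataFrame) -> float:
        """Mean replicate AUC predicting another scope's labelled rows."""
        y = (other_dataset["label"] == "presence").astype(int).to_numpy()
        X = other_dataset[self.variables].to_numpy(dtype=float)
        return float(np.mean([auc(y, predict_proba(m, X)) for m in self.replicate_models]))

    # -- reporting -------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """One-row metrics table (scope, habitat, sample sizes, AUCs)."""
        ds = self.model.replicates
        pooled = pd.concat(ds, ignore_index=True)
        row = {
            "scope": self.model.scope,
            "habitat": self.model.habitat,
            "n_seal": pooled.groupby("replicate")["animal_id"].nunique().mean(),
            "n_trip": pooled.groupby("replicate")["trip_id"].nunique().mean(),
            "n_year": pooled.groupby("replicate")["year"].nunique().mean(),
            "auc_cv_mean": self.auc_cv_mean,
            "auc_cv_sd": self.auc_cv_sd,
            "auc_time_mean": self.auc_time_mean,
            "auc_time_sd": self.auc_time_sd,
            "mtry_mode": int(pd.Series(self.mtry).mode().iloc[0]),
        }
        return pd.DataFrame([row])

    def __str__(self) -> str:
        s = self.summary().iloc[0]
        lines = [
            f"Habitat selection ensemble  [{s['scope']} / {s['habitat']}]",
            f"  replicates: {len(self.replicate_models)}   trees: {self.model.n_trees}"
            f"   mtry: {sorted(set(self.mtry))}",
            f"  AUC_cv:   {s['auc_cv_mean']:.3f} +/- {s['auc_cv_sd']:.3f}",
            f"  AUC_time: {s['auc_time_mean']:.3f}",
            "  variables: " + ", ".join(self.variables),
        ]
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------
    def plot_partial_dependence(self, var: str, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid, curves, ens = self.partial_dependence(var, **kw)
        for c in curves:
            ax.plot(grid, c, color="0.7", lw=0.7)
        ax.plot(grid, ens, color="k", lw=2)
        ax.set_xlabel(var)
        ax.set_ylabel("P(presence)")
        return ax

    # -- persistence -----------------------------------------------------
    def save(self, path_prefix: str) -> None:
        """Pickle the fitted models with a JSON metadata sidecar."""
        with open(f"{path_prefix}.pkl", "wb") as f:
            pickle.dump(self.replicate_models, f)
        meta = {
            "habitat": self.model.habitat, "scope": self.model.scope,
            "mtry": list(map(int, self.mtry)), "seed": int(self.seed),
            "variables": list(self.variables),
            "auc_cv": [float(a) for a in self.auc_cv],
            "auc_time": [None if np.isnan(a) else float(a) for a in self.auc_time],
        }
        with open(f"{path_prefix}.json", "w") as f:
            json.dump(meta, f, indent=2)
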