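"""Extrapolation detection (ExDet): analogue / univariate / combinatorial.

Given a reference covariate sample (here, the pooled Jul-Oct hindcast
conditions the models were trained under) and target conditions (projected
cells/weeks), each target is classified:

* **univariate** — outside the range of at least one reference variable;
  NT1 < 0 sums the (range-scaled) exceedances over variables.
* **combinatorial** — inside all univariate ranges but a novel combination:
  NT2 > 1, where NT2 is the target's Mahalanobis distance (squared) to the
  reference mean divided by the maximum reference Mahalanobis distance.
* **analogue** — inside the ranges with NT2 <= 1.

The most-influential covariate (MIC) is the variable with the most negative
NT1 term (univariate) or whose removal most reduces the Mahalanobis distance
(combinatorial, leave-one-variable-out recomputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ANALOGUE, UNIVARIATE, COMBINATORIAL = "analogue", "univariate", "combinatorial"


@dataclass
class ExDetResult:
    """Per-target novelty diagnostics."""

    nt1: np.ndarray          # <= 0; 0 = inside all univariate ranges
    nt2: np.ndarray          # >= 0; > 1 = outside the reference cloud
    classes: np.ndarray      # str array
    mic: np.ndarray          # most-influential covariate name ('' for analogue)
    variables: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "NT1": self.nt1, "NT2": self.nt2, "class": self.classes, "MIC": self.mic,
        })


def _mahalanobis_sq(X, mu, VI):
    d = X - mu
    return np.einsum("ij,jk,ik->i", d, VI, d)


def _inv_cov(ref):
    """Inverse reference covariance, ridge-regularized if singular."""
    V = np.cov(ref, rowvar=False)
    V = np.atleast_2d(V)
    try:
        return np.linalg.inv(V)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(V) / V.shape[0]
        log.info("exdet: singular reference covariance; ridge eps=%g", eps)
        return np.linalg.inv(V + eps * np.eye(V.shape[0]))


def exdet(reference, targets, variables=None) -> ExDetResult:
    """Classify target covariate rows against a reference sample.

    `reference` (n, p) and `targets` (m, p) are numeric matrices over the
    same `variables` (defaults to x0..x{p-1}).  Requires n > p + 1.
    Constant reference columns contribute an NT1 term of 0 where the target
    equals the constant and -inf otherwise (class univariate), and are
    excluded from the Mahalanobis computation.
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.atleast_2d(np.asarray(targets, dtype=float))
    n, p = ref.shape
    if tgt.shape[1] != p:
        raise ValueError("reference and targets must share columns")
    if n <= p + 1:
        raise ValueError("need more reference rows than variables + 1")
    variables = list(variables) if variables is not None else [f"x{j}" for j in range(p)]

    mins, maxs = ref.min(axis=0), ref.max(axis=0)
    rng = maxs - mins
    const = rng == 0
    if const.any():
        log.info("exdet: constant reference column(s): %s",
                 [variables[j] for j in np.nonzero(const)[0]])
    terms = np.zeros_like(tgt)
    ok = ~const
    terms[:, ok] = np.minimum(0.0, np.minimum(tgt[:, ok] - mins[ok], maxs[ok] - tgt[:, ok])) / rng[ok]
    if const.any():
        off = tgt[:, const] != mins[const]
        terms[:, const] = np.where(off, -np.inf, 0.0)
    nt1 = terms.sum(axis=1)

    # Mahalanobis novelty on the non-constant columns
    refm = ref[:, ok]
    mu = refm.mean(axis=0)
    VI = _inv_cov(refm)
    d2_ref = _mahalanobis_sq(refm, mu, VI)
    d2_max = float(d2_ref.max())
    d2_tgt = _mahalanobis_sq(tgt[:, ok], mu, VI)
    nt2 = d2_tgt / d2_max if d2_max > 0 else np.zeros(len(tgt))

    univ = nt1 < 0
    comb = ~univ & (nt2 > 1)
    classes = np.where(univ, UNIVARIATE, np.where(comb, COMBINATORIAL, ANALOGUE))

    mic = np.full(len(tgt), "", dtype=object)
    if univ.any():
        j = np.argmin(terms[univ], axis=1)
        mic[univ] = np.array(variables, dtype=object)[j]
    if comb.any():
        ok_idx = np.nonzero(ok)[0]
        reductions = np.zeros((int(comb.sum()), len(ok_idx)))
        rows = tgt[comb][:, ok]
        for jj in range(len(ok_idx)):
            keep = np.arange(len(ok_idx)) != jj
            sub = refm[:, keep]
            VI_j = _inv_cov(sub)
            d2_j = _mahalanobis_sq(rows[:, keep], sub.mean(axis=0), VI_j)
            reductions[:, jj] = d2_tgt[comb] - d2_j
        j = np.argmax(reductions, axis=1)
        mic[comb] = np.array([variables[ok_idx[x]] for x in j], dtype=object)
    return ExDetResult(nt1=nt1, nt2=nt2, classes=classes, mic=mic.astype(str),
                       variables=variables)


def exdet_summary(results: ExDetResult, scenario: str = "", exclude_vars=()) -> pd.DataFrame:
    """Class fractions and MIC frequencies over all target instances.

    Univariate instances driven purely by an excluded variable (e.g. biomass
    novelty arising from near-zero bias-corrected values) are counted as
    analogue, mirroring a summary that sets artifact-prone variables aside.
    """
    classes = results.classes.copy()
    if exclude_vars:
        excl = np.isin(results.mic, list(exclude_vars)) & (classes == UNIVARIATE)
        classes = np.where(excl, ANALOGUE, classes)
    n = len(classes)
    rows = []
    for cls in (ANALOGUE, UNIVARIATE, COMBINATORIAL):
        mask = classes == cls
        mic_counts = pd.Series(results.mic[mask]).value_counts().to_dict() if mask.any() else {}
        rows.append({
            "scenario": scenario, "class": cls,
            "fraction": float(mask.sum()) / n if n else float("nan"),
            "n": int(mask.sum()), "mic_counts": mic_counts,
        })
    return pd.DataFrame(rows)
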