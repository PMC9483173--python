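"""Three-step random-forest variable selection (VSURF-style).

The selector runs on the training partition only and proceeds in three
stages, each consuming the output of the previous one:

1. *Thresholding* — rank features by mean out-of-bag (OOB) permutation
   importance over several independently seeded forests; discard features
   whose mean importance falls below the minimum of a CART (piecewise
   constant) fit of the importance standard deviation against rank.  Noise
   features have importances fluctuating around zero, so this data-driven
   threshold removes them without a hand-set cutoff.
2. *Interpretation* — fit nested forests on the top-k ranked survivors for
   k = 1..K and keep the smallest k whose mean OOB error is within one
   standard deviation of the minimum.
3. *Prediction* — a parsimonious forward pass over the interpretation set in
   rank order: a feature enters the final set only if it lowers the OOB
   error by more than the mean absolute OOB jitter measured on noise-only
   additions (features ranked below the interpretation set).

The three stages are nested by construction:
prediction set <= interpretation set <= threshold set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Outcome of the three-step selection, with full provenance."""

    ranked_features: list[tuple[str, float, float]]  # (name, mean VI, sd VI)
    threshold_kept: list[str]
    interpretation_kept: list[str]
    prediction_kept: list[str]
    seed: Optional[int]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.prediction_kept) <= set(self.interpretation_kept) <= set(self.threshold_kept):
            raise ValueError("selection stages must be nested")


# ---------------------------------------------------------------------------
# forest primitives: hand-rolled bagging so every tree's OOB set is explicit


def _fit_forest(X, y, n_trees, rng, max_features="sqrt"):
    n = len(y)
    trees = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), np.unique(idx))
        t = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        t.fit(X[idx], y[idx])
        trees.append((t, oob))
    return trees


def _forest_oob_error(X, y, n_trees, rng):
    """OOB error of one forest by majority vote over each sample's OOB trees."""
    trees = _fit_forest(X, y, n_trees, rng)
    classes = np.unique(y)
    votes = np.zeros((len(y), len(classes)))
    for t, oob in trees:
        if len(oob) == 0:
            continue
        pred = t.predict(X[oob])
        for ci, c in enumerate(classes):
            votes[oob[pred == c], ci] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        raise SelectionError("no OOB coverage; increase the number of trees")
    call = classes[np.argmax(votes[covered], axis=1)]
    return float(np.mean(call != np.asarray(y)[covered]))


def _forest_importance(X, y, n_trees, rng):
    """Per-feature mean OOB permutation importance of one forest."""
    trees = _fit_forest(X, y, n_trees, rng)
    p = X.shape[1]
    vi = np.zeros(p)
    n_used = 0
    y = np.asarray(y)
    for t, oob in trees:
        if len(oob) < 2:
            continue
        n_used += 1
        Xo, yo = X[oob], y[oob]
        base_err = np.mean(t.predict(Xo) != yo)
        perm = rng.permutation(len(oob))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            vi[j] += np.mean(t.predict(Xp) != yo) - base_err
    if n_used == 0:
        raise SelectionError("no tree had an OOB sample")
    return vi / n_used


# ---------------------------------------------------------------------------
# the three steps


def importance_ranking(
    X: np.ndarray,
    y: Sequence,
    names: Sequence[str],
    n_runs: int = 12,
    n_trees: int = 150,
    seed: Optional[int] = None,
) -> list[tuple[str, float, float]]:
    """Mean and sd of OOB permutation importance over ``n_runs`` forests.

    Returns (name, mean, sd) triples sorted by descending mean importance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SelectionError("y must contain both classes")
    if X.shape[1] != len(names):
        raise SelectionError("names must match the number of columns")
    rng = np.random.default_rng(seed)
    runs = np.vstack([_forest_importance(X, y, n_trees, rng) for _ in range(n_runs)])
    mean = runs.mean(axis=0)
    sd = runs.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(X.shape[1])
    order = np.argsort(-mean, kind="stable")
    return [(str(names[i]), float(mean[i]), float(sd[i])) for i in order]


def threshold_step(ranking: Sequence[tuple[str, float, float]]) -> list[str]:
    """Drop features whose mean importance falls below the sd-based threshold.

    The threshold is the minimum of a CART regression of sd(importance) on
    rank — a piecewise-constant smoothing whose floor estimates the jitter
    of pure-noise importances.
    """
    if len(ranking) == 0:
        raise SelectionError("empty ranking")
    if len(ranking) == 1:
        return [ranking[0][0]]
    sds = np.array([sd for _, _, sd in ranking])
    ranks = np.arange(len(ranking)).reshape(-1, 1)
    cart = DecisionTreeRegressor(min_samples_leaf=max(2, len(ranking) // 10), random_state=0)
    cart.fit(ranks, sds)
    thr = float(cart.predict(ranks).min())
    kept = [name for name, m, _ in ranking if m >= thr]
    return kept if kept else [ranking[0][0]]


def interpretation_step(
    retained: Sequence[str],
    X: np.ndarray,
    y: Sequence,
    names: Sequence[str],
    n_trees: int = 100,
    n_rep: int = 3,
    seed: Optional[int] = None,
) -> list[str]:
    """Smallest nested prefix whose OOB error is within 1 sd of the minimum."""
    if len(retained) == 0:
        raise SelectionError("retained set is empty")
    if len(retained) == 1:
        return list(retained)
    X = np.asarray(X, dtype=float)
    col = {n: i for i, n in enumerate(names)}
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for k in range(1, len(retained) + 1):
        idx = [col[n] for n in retained[:k]]
        errs = [_forest_oob_error(X[:, idx], y, n_trees, rng) for _ in range(n_rep)]
        means.append(float(np.mean(errs)))
        sds.append(float(np.std(errs, ddof=1)) if n_rep > 1 else 0.0)
    kmin = int(np.argmin(means))
    bound = means[kmin] + sds[kmin]
    for k in range(len(retained)):
        if means[k] <= bound:
            return list(retained[: k + 1])
    return list(retained[: kmin + 1])


def prediction_step(
    interp_set: Sequence[str],
    retained: Sequence[str],
    X: np.ndarray,
    y: Sequence,
    names: Sequence[str],
    n_trees: int = 100,
    seed: Optional[int] = None,
) -> list[str]:
    """Greedy forward pass keeping only features that beat the noise jump.

    The jump threshold is the mean absolute OOB-error difference between
    successive models that add features ranked *below* the interpretation
    set (noise-only additions); with no such features the threshold is 0.
    """
    if not set(interp_set) <= set(retained):
        raise SelectionError("interpretation set must be a subset of the retained set")
    if len(interp_set) == 0:
        raise SelectionError("interpretation set is empty")
    X = np.asarray(X, dtype=float)
    col = {n: i for i, n in enumerate(names)}
    rng = np.random.default_rng(seed)

    noise_feats = [n for n in retained if n not in set(interp_set)]
    jump = 0.0
    if noise_feats:
        base_cols = [col[n] for n in interp_set]
        errs = [_forest_oob_error(X[:, base_cols], y, n_trees, rng)]
        cols = list(base_cols)
        for n in noise_feats:
            cols.append(col[n])
            errs.append(_forest_oob_error(X[:, cols], y, n_trees, rng))
        jump = float(np.mean(np.abs(np.diff(errs))))

    final: list[str] = [interp_set[0]]
    last_err = _forest_oob_error(X[:, [col[interp_set[0]]]], y, n_trees, rng)
    for n in interp_set[1:]:
        cand = final + [n]
        err = _forest_oob_error(X[:, [col[c] for c in cand]], y, n_trees, rng)
        if last_err - err > jump:
            final = cand
            last_err = err
    return final


def select_features(
    X: np.ndarray,
    y: Sequence,
    names: Sequence[str],
    seed: Optional[int] = None,
    n_runs: int = 12,
    n_trees_rank: int = 150,
    n_trees_nested: int = 100,
    n_rep: int = 3,
) -> SelectionResult:
    """Run the full three-step selection on training data only."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(rng.integers(2**31 - 1)) for _ in range(3))
    ranking = importance_ranking(X, y, names, n_runs=n_runs, n_trees=n_trees_rank, seed=s1)
    thr_kept = threshold_step(ranking)
    interp = interpretation_step(thr_kept, X, y, names, n_trees=n_trees_nested, n_rep=n_rep, seed=s2)
    pred = prediction_step(interp, thr_kept, X, y, names, n_trees=n_trees_nested, seed=s3)
    return SelectionResult(
        ranked_features=ranking,
        threshold_kept=thr_kept,
        interpretation_kept=interp,
        prediction_kept=pred,
        seed=seed,
        params={
            "n_runs": n_runs,
            "n_trees_rank": n_trees_rank,
            "n_trees_nested": n_trees_nested,
            "n_rep": n_rep,
        },
    )
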