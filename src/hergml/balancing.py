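"""Class-imbalance handling: SMOTE oversampling and balanced bootstraps.

SMOTE interpolates synthetic minority samples between a minority compound and
one of its k nearest minority neighbors in the normalized descriptor space,
until the two classes are exactly 1:1.  It is applied to the training
partition only; validation and external sets stay unbalanced so that
performance reflects the real class distribution.

The balanced bootstrap draws, for each tree of a balanced random forest, an
equal number of samples (the minority count) with replacement from each
class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


class BalancingError(ValueError):
    pass


@dataclass
class AugmentedTrainingSet:
    """Original training rows plus SMOTE rows.

    ``parent_pairs[i]`` gives, for the i-th synthetic row, the indices (into
    the original X) of the minority sample and its chosen neighbor, and the
    interpolation weight u in [0, 1].
    """

    X: np.ndarray
    y: np.ndarray
    synthetic_mask: np.ndarray
    parent_pairs: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) == 2 and counts[0] != counts[1]:
            raise ValueError("augmented set must be exactly 1:1 balanced")


def smote(
    X_train: np.ndarray,
    y_train: Sequence,
    k: int = 5,
    seed: Optional[int] = None,
) -> AugmentedTrainingSet:
    """Oversample the minority class to an exact 1:1 ratio.

    Each synthetic row is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1),
    where x_nn is one of the k nearest minority neighbors of minority row
    x_i (Euclidean metric).  Each minority row is used floor(need/n_min)
    times; the remainder is drawn uniformly at random.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise BalancingError(f"need exactly 2 classes, got {list(classes)}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    need = int(n_maj - n_min)
    if need == 0:
        return AugmentedTrainingSet(
            X=X.copy(), y=y.copy(), synthetic_mask=np.zeros(len(y), bool), parent_pairs=[]
        )
    if n_min < 2:
        raise BalancingError("minority class has a single sample; no neighbor to interpolate")
    if k >= n_min:
        logger.warning("k=%d >= minority size %d; clamping to %d", k, n_min, n_min - 1)
        k = int(n_min - 1)

    rng = np.random.default_rng(seed)
    min_idx = np.where(y == minority)[0]
    X_min = X[min_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    # first neighbor is the point itself
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    base = np.repeat(np.arange(n_min), need // n_min)
    extra = rng.choice(n_min, size=need - len(base), replace=False if need - len(base) <= n_min else True)
    picks = np.concatenate([base, extra]).astype(int)

    synth_rows = np.empty((need, X.shape[1]))
    pairs: list[tuple[int, int, float]] = []
    for row, i in enumerate(picks):
        j = neighbors[i, rng.integers(k)]
        u = float(rng.random())
        synth_rows[row] = X_min[i] + u * (X_min[j] - X_min[i])
        pairs.append((int(min_idx[i]), int(min_idx[j]), u))

    X_aug = np.vstack([X, synth_rows])
    y_aug = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    mask = np.concatenate([np.zeros(len(y), bool), np.ones(need, bool)])
    return AugmentedTrainingSet(X=X_aug, y=y_aug, synthetic_mask=mask, parent_pairs=pairs)


def balanced_bootstrap(
    y_train: Sequence,
    n_trees: int,
    seed: Optional[int] = None,
) -> list[np.ndarray]:
    """Equal-size per-class bootstrap index samples for each tree.

    Every tree receives n_min draws with replacement from each class, where
    n_min is the minority count — the sampling scheme of a balanced random
    forest.
    """
    y = np.asarray(y_train)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise BalancingError("balanced bootstrap needs both classes present")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    samples: list[np.ndarray] = []
    for _ in range(n_trees):
        parts = [rng.choice(np.where(y == c)[0], size=n_min, replace=True) for c in classes]
        samples.append(np.concatenate(parts))
    return samples
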