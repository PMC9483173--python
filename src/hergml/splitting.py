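"""Rational train/validation partitioning by per-class MaxMin diversity picking.

Morgan fingerprints (radius 2, 2048 bits) and Tanimoto distance drive a
greedy MaxMin selection run separately within each activity class, so the
nonblocker:blocker ratio of the parent dataset is preserved in both halves.
A PCA coverage check verifies that the two halves (and any external set)
occupy the same region of property space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.decomposition import PCA


class SplitError(ValueError):
    pass


@dataclass
class DatasetSplit:
    train_ids: list[str]
    valid_ids: list[str]
    fraction: float
    per_class: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.valid_ids)
        if overlap:
            raise ValueError(f"train/valid overlap: {sorted(overlap)[:3]}")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")


def morgan_fingerprint(smiles: str, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """Binary Morgan (ECFP-style) fingerprint as a uint8 vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SplitError(f"unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; two all-zero vectors are identical (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise SplitError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def maxmin_pick(
    fps: Sequence[np.ndarray],
    n_pick: int,
    ids: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> list[int]:
    """Greedy MaxMin selection of ``n_pick`` diverse items.

    Start: by default the item with maximal popcount (ties broken
    lexicographically by id, then by index); with ``seed`` given, a
    seed-randomized start.  Then repeatedly add the item whose minimum
    Tanimoto distance to the already-picked set is largest (ties by lowest
    index).  Output is invariant to input order given a fixed start.
    """
    n = len(fps)
    if not 0 < n_pick <= n:
        raise SplitError(f"cannot pick {n_pick} from {n} items")
    F = np.asarray(fps, dtype=bool)
    if seed is not None:
        start = int(np.random.default_rng(seed).integers(n))
    else:
        pop = F.sum(axis=1)
        best = np.where(pop == pop.max())[0]
        if ids is not None and len(best) > 1:
            start = int(min(best, key=lambda i: (str(ids[i]), i)))
        else:
            start = int(best[0])
    picked = [start]
    if n_pick == 1:
        return picked
    # min distance from every item to the picked set, updated incrementally
    min_dist = _distances_to(F, start)
    min_dist[start] = -1.0
    for _ in range(n_pick - 1):
        best = np.flatnonzero(min_dist == min_dist.max())
        if ids is not None and len(best) > 1:
            # ties broken by id so the selected set is input-order invariant
            nxt = int(min(best, key=lambda i: (str(ids[i]), i)))
        else:
            nxt = int(best[0])
        picked.append(nxt)
        d = _distances_to(F, nxt)
        min_dist = np.minimum(min_dist, d)
        min_dist[nxt] = -1.0
    return picked


def _distances_to(F: np.ndarray, i: int) -> np.ndarray:
    """1 - Tanimoto from item i to all items, vectorized."""
    inter = np.logical_and(F, F[i]).sum(axis=1).astype(float)
    union = np.logical_or(F, F[i]).sum(axis=1).astype(float)
    sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return 1.0 - sim


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def maxmin_split(
    smiles: Sequence[str],
    labels: Sequence[str],
    fraction: float = 0.8,
    seed: Optional[int] = None,
    radius: int = 2,
    nbits: int = 2048,
) -> DatasetSplit:
    """Per-class MaxMin diversity split preserving the class ratio.

    Within each class independently, round(fraction * n_class) of the most
    diverse compounds (greedy MaxMin on Tanimoto distance over Morgan
    fingerprints) form the training side; the remainder is validation.
    """
    if len(smiles) != len(labels):
        raise SplitError("smiles and labels must have equal length")
    train: list[str] = []
    valid: list[str] = []
    for cls in sorted(set(labels)):
        members = [s for s, l in zip(smiles, labels) if l == cls]
        if len(members) < 2:
            raise SplitError(f"class {cls!r} has fewer than 2 compounds")
        fps = [morgan_fingerprint(s, radius, nbits) for s in members]
        n_pick = _round_half_up(fraction * len(members))
        n_pick = min(max(n_pick, 1), len(members) - 1)
        picked = set(maxmin_pick(fps, n_pick, ids=members, seed=seed))
        train.extend(members[i] for i in sorted(picked))
        valid.extend(members[i] for i in range(len(members)) if i not in picked)
    return DatasetSplit(train_ids=train, valid_ids=valid, fraction=fraction, per_class=True)


def pca_coverage_check(
    train: np.ndarray,
    valid: np.ndarray,
    external: Optional[np.ndarray] = None,
) -> dict:
    """PCA on the pooled property block; report PC1+PC2 variance and score boxes.

    Returns ``variance_explained_pc1_2`` (cumulative fraction) and, per set,
    the bounding box (min, max) of its scores on the first two components.
    Used to confirm the split covers the model space uniformly.
    """
    blocks = {"train": np.asarray(train, float), "valid": np.asarray(valid, float)}
    if external is not None:
        blocks["external"] = np.asarray(external, float)
    p = blocks["train"].shape[1]
    if p < 2:
        raise SplitError("PCA coverage check needs at least 2 descriptors")
    if any(b.shape[1] != p for b in blocks.values()):
        raise SplitError("matrices must share descriptor columns")
    pooled = np.vstack(list(blocks.values()))
    pca = PCA(n_components=2)
    pca.fit(pooled)
    report = {
        "variance_explained_pc1_2": float(pca.explained_variance_ratio_.sum()),
        "score_ranges": {},
    }
    for name, block in blocks.items():
        scores = pca.transform(block)
        report["score_ranges"][name] = {
            "pc1": (float(scores[:, 0].min()), float(scores[:, 0].max())),
            "pc2": (float(scores[:, 1].min()), float(scores[:, 1].max())),
        }
    return report
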