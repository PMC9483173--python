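"""2D molecular descriptors: computation, pruning, and z-normalization.

The default backend is the RDKit 2D descriptor list.  The pipeline is
descriptor-agnostic: a precomputed matrix (e.g. an export from commercial
descriptor software) can be loaded from CSV and passed through the same
pruning and normalization stages.

Pruning removes, in order: descriptors with any missing value, near-constant
descriptors (sd < 0.01), and, for each pair with |Pearson r| > 0.95, the
later descriptor in name-sorted order (a deterministic greedy scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

SD_MIN = 0.01
CORR_MAX = 0.95


class DescriptorError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Compounds x named continuous descriptors, with optional norm stats.

    ``norm_stats`` is a DataFrame indexed by descriptor name with columns
    ``mean`` and ``sd``; present only after :func:`normalize`.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    norm_stats: Optional[pd.DataFrame] = None
    backend: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.descriptor_names)} descriptors"
            )
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.descriptor_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, backend: str = "") -> "DescriptorMatrix":
        return cls(
            compound_ids=[str(i) for i in df.index],
            descriptor_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            backend=backend,
        )

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "compound_id"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path, backend: str = "csv") -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df, backend=backend)

    def subset(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Restrict to the given descriptors, preserving the given order."""
        missing = [n for n in names if n not in self.descriptor_names]
        if missing:
            raise DescriptorError(f"unknown descriptors: {missing}")
        idx = [self.descriptor_names.index(n) for n in names]
        stats = self.norm_stats.loc[list(names)] if self.norm_stats is not None else None
        return DescriptorMatrix(
            compound_ids=list(self.compound_ids),
            descriptor_names=list(names),
            values=self.values[:, idx],
            norm_stats=stats,
            backend=self.backend,
        )

    def take_rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DescriptorError(f"unknown compound ids: {missing[:5]}")
        idx = [pos[i] for i in ids]
        return DescriptorMatrix(
            compound_ids=list(ids),
            descriptor_names=list(self.descriptor_names),
            values=self.values[idx],
            norm_stats=self.norm_stats,
            backend=self.backend,
        )


def _rdkit_descriptor_names() -> list[str]:
    return [name for name, _ in Descriptors.descList]


def compute_descriptors(
    smiles_list: Sequence[str], backend: str = "rdkit"
) -> tuple[DescriptorMatrix, list[str]]:
    """Compute 2D descriptors for standardized SMILES.

    Returns the matrix and the list of dropped compounds (descriptor
    computation failed).  Duplicated input SMILES yield identical rows.
    """
    if backend != "rdkit":
        raise DescriptorError(f"unknown backend {backend!r}; available: 'rdkit'")
    names = _rdkit_descriptor_names()
    rows: list[np.ndarray] = []
    kept_ids: list[str] = []
    dropped: list[str] = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            dropped.append(smi)
            continue
        try:
            d = Descriptors.CalcMolDescriptors(mol)
            rows.append(np.array([d[n] for n in names], dtype=float))
            kept_ids.append(smi)
        except Exception:
            dropped.append(smi)
    if not rows:
        raise DescriptorError("descriptor computation failed for every compound")
    values = np.vstack(rows)
    # infinities behave like missing values downstream
    values[~np.isfinite(values)] = np.nan
    return (
        DescriptorMatrix(compound_ids=kept_ids, descriptor_names=names, values=values, backend=backend),
        dropped,
    )


def prune_descriptors(
    m: DescriptorMatrix,
) -> tuple[DescriptorMatrix, list[tuple[str, str]]]:
    """Remove uninformative and redundant descriptors.

    Order: (1) any missing value; (2) sd < 0.01; (3) |Pearson r| > 0.95,
    dropping the later member of each pair in name-sorted order.  Returns the
    pruned matrix (original column order preserved) and (name, reason) pairs.
    """
    removed: list[tuple[str, str]] = []
    names = np.array(m.descriptor_names)
    X = m.values

    has_missing = np.isnan(X).any(axis=0)
    for n in names[has_missing]:
        removed.append((str(n), "missing"))
    keep = ~has_missing

    sd = np.full(len(names), np.nan)
    sd[keep] = np.std(X[:, keep], axis=0, ddof=1) if X.shape[0] > 1 else 0.0
    near_const = keep & (sd < SD_MIN)
    for n in names[near_const]:
        removed.append((str(n), "near-constant"))
    keep &= ~near_const

    surviving = [i for i in range(len(names)) if keep[i]]
    if surviving:
        order = sorted(surviving, key=lambda i: names[i])
        sub = X[:, order]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        kept_sorted: list[int] = []
        for j in range(len(order)):
            if any(abs(corr[j, i]) > CORR_MAX for i in kept_sorted):
                removed.append((str(names[order[j]]), "correlated"))
                keep[order[j]] = False
            else:
                kept_sorted.append(j)

    if not keep.any():
        raise DescriptorError("pruning removed every descriptor")
    idx = np.where(keep)[0]
    pruned = DescriptorMatrix(
        compound_ids=list(m.compound_ids),
        descriptor_names=[m.descriptor_names[i] for i in idx],
        values=X[:, idx],
        backend=m.backend,
    )
    return pruned, removed


def normalize(m: DescriptorMatrix, stats: Optional[pd.DataFrame] = None) -> DescriptorMatrix:
    """Z-score each column; fit stats here, or apply training-set stats.

    In apply mode the provided (mean, sd) are used verbatim so that
    validation/external sets are expressed on the training scale.
    """
    if stats is None:
        mean = m.values.mean(axis=0)
        sd = m.values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [m.descriptor_names[i] for i in np.where(sd == 0)[0]]
            raise DescriptorError(f"zero-variance descriptors in fit mode (prune first): {zero}")
        stats = pd.DataFrame({"mean": mean, "sd": sd}, index=m.descriptor_names)
    else:
        missing = [n for n in m.descriptor_names if n not in stats.index]
        if missing:
            raise DescriptorError(f"normalization stats missing for: {missing[:5]}")
        stats = stats.loc[m.descriptor_names]
    z = (m.values - stats["mean"].to_numpy()) / stats["sd"].to_numpy()
    return DescriptorMatrix(
        compound_ids=list(m.compound_ids),
        descriptor_names=list(m.descriptor_names),
        values=z,
        norm_stats=stats,
        backend=m.backend,
    )
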