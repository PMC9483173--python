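"""Leverage-based applicability domain with the h > 3p/n rule.

The leverage of a query row x against the training descriptor matrix X is
h = x' (X'X)^-1 x, the diagonal entry of the hat (projection) matrix a row
would have.  Compounds with h above 3p/n (p descriptors, n training
compounds) sit outside the chemical space spanned by the training set and
their predictions are flagged as unreliable.  The boundary itself (h equal
to the threshold) counts as in-domain.

The Gram inverse falls back to the Moore-Penrose pseudoinverse when X'X is
singular, which happens whenever descriptors surviving the 0.95 correlation
filter remain collinear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ADModel:
    gram_inverse: np.ndarray
    p: int
    n: int

    @property
    def threshold(self) -> float:
        return 3.0 * self.p / self.n

    def __post_init__(self) -> None:
        self.gram_inverse = np.asarray(self.gram_inverse, dtype=float)
        if self.gram_inverse.shape != (self.p, self.p):
            raise ValueError("gram_inverse must be p x p")
        if not np.allclose(self.gram_inverse, self.gram_inverse.T, atol=1e-10):
            raise ValueError("gram_inverse must be symmetric")


def fit_ad(X_train: np.ndarray) -> ADModel:
    """Fit the applicability domain on the (normalized, selected) training matrix.

    SMOTE rows must be excluded by the caller: the domain describes real
    chemical space, not interpolated points.
    """
    X = np.asarray(X_train, dtype=float)
    n, p = X.shape
    if n <= p:
        logger.warning("n=%d <= p=%d: X'X is singular, using pseudoinverse", n, p)
    gram = X.T @ X
    inv = np.linalg.pinv(gram, hermitian=True)
    inv = (inv + inv.T) / 2.0  # enforce exact symmetry
    return ADModel(gram_inverse=inv, p=p, n=n)


def leverage(ad: ADModel, x: np.ndarray) -> float:
    """h = x' (X'X)^-1 x for a single descriptor row."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != ad.p:
        raise ValueError(f"expected {ad.p} descriptors, got {x.shape[0]}")
    return float(x @ ad.gram_inverse @ x)


def leverages(ad: ADModel, X: np.ndarray) -> np.ndarray:
    """Vectorized leverage for a matrix of rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ad.p:
        raise ValueError(f"expected {ad.p} descriptors, got {X.shape[1]}")
    return np.einsum("ij,jk,ik->i", X, ad.gram_inverse, X)


def in_domain(ad: ADModel, x: np.ndarray) -> bool:
    """True iff leverage(x) <= 3p/n (boundary inclusive)."""
    return leverage(ad, x) <= ad.threshold


def in_domain_mask(ad: ADModel, X: np.ndarray) -> np.ndarray:
    return leverages(ad, X) <= ad.threshold
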