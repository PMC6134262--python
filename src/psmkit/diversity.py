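"""Presence/absence binarization, phytochemical richness, and dissimilarities.

Two dissimilarity measures drive the multivariate analyses:

* **Canberra** on raw intensities — for each sample pair, the mean of
  ``|x_i - y_i| / (x_i + y_i)`` over features where ``x_i + y_i > 0``
  (double zeros carry no information about a pair and are excluded; the
  normalization by the count of informative features bounds the distance in
  [0, 1]).  This is the convention of the vegan/R ecology stack.  The raw
  unnormalized sum is available via ``normalize=False`` for cross-checks.
* **Jaccard** on presence/absence — ``1 - |A ∩ B| / |A ∪ B|`` over the
  presence sets of two samples, quantifying phytochemical turnover.

Phytochemical richness is the per-sample count of present features.
Presence means intensity strictly above a threshold (default 0: any
positive intensity counts, appropriate for background-subtracted tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .feature_io import FeatureTable, ValidationError

METRICS = ("canberra", "jaccard", "euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among samples."""

    sample_ids: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if self.d.size and self.d.min() < -1e-12:
            raise ValidationError("distance matrix has negative entries")
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)

    @staticmethod
    def from_frame(df: pd.DataFrame, metric: str = "euclidean") -> "DistanceMatrix":
        return DistanceMatrix(sample_ids=[str(i) for i in df.index], d=df.to_numpy(float), metric=metric)


def binarize(table: FeatureTable, threshold: float = 0.0) -> np.ndarray:
    """Presence/absence matrix: 1 iff intensity strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (table.intensities > threshold).astype(np.int8)


def richness(table: FeatureTable, threshold: float = 0.0) -> pd.Series:
    """Per-sample phytochemical richness: number of present features."""
    counts = binarize(table, threshold).sum(axis=1)
    return pd.Series(counts, index=table.sample_ids, name="richness")


def canberra_matrix(table: FeatureTable, normalize: bool = True) -> DistanceMatrix:
    """Pairwise Canberra dissimilarities on raw intensities.

    ``d(x, y) = (1/NZ) * sum |x_i - y_i| / (x_i + y_i)`` over the NZ
    features with ``x_i + y_i > 0``.  A pair of all-zero samples has no
    informative feature; its distance is defined as 0 with a warning.
    With ``normalize=False`` the raw sum is returned instead of the mean.
    """
    X = table.intensities
    if X.size and X.min() < 0:
        raise ValidationError("Canberra requires nonnegative intensities")
    n = X.shape[0]
    D = np.zeros((n, n))
    warned = False
    for i in range(n):
        xi = X[i]
        # vectorized over all j > i
        s = xi[None, :] + X[i + 1:, :]
        a = np.abs(xi[None, :] - X[i + 1:, :])
        nz = s > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(nz, a / np.where(nz, s, 1.0), 0.0)
        nz_counts = nz.sum(axis=1)
        sums = ratio.sum(axis=1)
        if normalize:
            empty = nz_counts == 0
            if empty.any() and not warned:
                warnings.warn("sample pair with no nonzero features; distance set to 0")
                warned = True
            vals = np.where(nz_counts > 0, sums / np.maximum(nz_counts, 1), 0.0)
        else:
            vals = sums
        D[i, i + 1:] = vals
        D[i + 1:, i] = vals
    return DistanceMatrix(sample_ids=table.sample_ids, d=D, metric="canberra")


def jaccard_matrix(binary: np.ndarray, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarities on a presence/absence matrix.

    ``d(A, B) = 1 - |A ∩ B| / |A ∪ B|``; a pair of all-absent samples is
    assigned distance 0 with a warning.
    """
    B = np.asarray(binary)
    if B.size and not np.isin(B, (0, 1)).all():
        raise ValidationError("jaccard_matrix requires a 0/1 matrix; use binarize() first")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(B.shape[0])]
    Bb = B.astype(bool)
    empty = ~Bb.any(axis=1)
    if empty.sum() >= 2:
        warnings.warn("pair(s) of all-absent samples; Jaccard distance set to 0")
    # scipy's boolean 'jaccard' implements exactly 1 - |A∩B|/|A∪B| (0/0 -> 0)
    D = squareform(pdist(Bb, metric="jaccard"))
    return DistanceMatrix(sample_ids=list(sample_ids), d=D, metric="jaccard")


def euclidean_matrix(X: np.ndarray, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Plain Euclidean distances (used for oracles and diagnostics)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(sample_ids=list(sample_ids), d=D, metric="euclidean")
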