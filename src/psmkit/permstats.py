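"""Distance-based permutation tests honouring a blocked design.

Implements the machinery behind distance-matrix group comparisons:

* :func:`permanova` — permutational MANOVA.  The total sum of squares of a
  distance matrix is partitioned into between- and within-group components
  and summarized by a pseudo-F; significance comes from permuting group
  labels, optionally restricted to shuffle only within strata (experimental
  blocks or sites) so the test respects the blocked sampling design.
* :func:`permdisp` — homogeneity of multivariate dispersion: distances to
  group centers in principal-coordinate space (negative eigenvalue axes
  handled with the imaginary-part correction), tested with a permutation
  F-test.
* :func:`meandist` — mean within- and between-group dissimilarities, the
  centroid-separation diagnostic that distinguishes location from
  dispersion effects.

A significant pseudo-F can reflect centroid differences, dispersion
differences, or both; the latter two functions are the diagnostics that
disentangle them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .diversity import DistanceMatrix
from .feature_io import ValidationError

#: largest number of distinct within-strata label arrangements that the
#: exact-enumeration mode will enumerate
EXACT_ENUMERATION_CAP = 500_000


@dataclass
class PermanovaResult:
    F: float
    r2: float
    p: float
    n_perm: int
    df_between: int
    df_within: int
    observed_ge_count: int
    method: str  # "exact" or "monte-carlo"
    degenerate: bool = False  # SS_W == 0

    def summary(self) -> str:
        return (f"perMANOVA: F={self.F:.4g} r2={self.r2:.4g} p={self.p:.4g} "
                f"({self.method}, {self.n_perm} permutations)")


@dataclass
class DispersionResult:
    F: float
    p: float
    distances_to_center: np.ndarray
    group_centers: dict
    center_type: str
    n_perm: int
    groups: np.ndarray


@dataclass
class MeanDissimilarity:
    groups: list
    m: np.ndarray                       # g x g; diagonal = within, off = between
    singleton: np.ndarray               # diagonal undefined for singleton groups
    centroid_separation: np.ndarray     # g x g bool: between > both withins


# ---------------------------------------------------------------------------
# perMANOVA
# ---------------------------------------------------------------------------

def _ss_parts(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances.

    SS_T = (1/N) sum_{i<j} d_ij^2 ; SS_W = sum_g (1/n_g) sum_{i<j in g} d_ij^2.
    """
    n = D2.shape[0]
    ss_t = D2.sum() / (2.0 * n)
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_w += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_t, ss_w


def _pseudo_f(ss_t: float, ss_w: float, n: int, a: int) -> float:
    ss_a = ss_t - ss_w
    if ss_w <= 0:
        return math.inf
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def _within_strata_arrangements(codes: np.ndarray, strata_codes: np.ndarray):
    """Yield all distinct label arrangements obtained by permuting labels
    within each stratum (exact-enumeration mode)."""
    from sympy.utilities.iterables import multiset_permutations

    strata_ids = np.unique(strata_codes)
    per_stratum = []
    for s in strata_ids:
        idx = np.flatnonzero(strata_codes == s)
        per_stratum.append((idx, [np.array(p) for p in multiset_permutations(codes[idx].tolist())]))
    total = 1
    for _, perms in per_stratum:
        total *= len(perms)
    if total > EXACT_ENUMERATION_CAP:
        raise ValidationError(
            f"exact enumeration would require {total} arrangements (cap {EXACT_ENUMERATION_CAP})")
    for combo in itertools.product(*(perms for _, perms in per_stratum)):
        arr = np.empty_like(codes)
        for (idx, _), part in zip(per_stratum, combo):
            arr[idx] = part
        yield arr


def _permute_within_strata(rng: np.random.Generator, codes: np.ndarray,
                           strata_codes: np.ndarray, n_perm: int,
                           check: bool = False) -> np.ndarray:
    """(n_perm, n) array of label permutations restricted to strata."""
    out = np.tile(codes, (n_perm, 1))
    for s in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == s)
        out[:, idx] = rng.permuted(out[:, idx], axis=1)
    if check:
        for s in np.unique(strata_codes):
            idx = np.flatnonzero(strata_codes == s)
            ref = np.sort(codes[idx])
            assert (np.sort(out[:, idx], axis=1) == ref).all(), \
                "permutation altered a stratum's label multiset"
    return out


def permanova(
    D: DistanceMatrix,
    groups,
    strata=None,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "auto",
    check_strata: bool = False,
) -> PermanovaResult:
    """Permutational MANOVA of a distance matrix against group labels.

    Parameters
    ----------
    groups : per-sample labels defining the tested partition (the composite
        condition factor).
    strata : optional per-sample block/site labels; permutations shuffle
        labels only within each stratum.
    method : "exact" enumerates every distinct within-strata arrangement
        (p = count{F_perm >= F_obs} / n_arrangements, observed arrangement
        included); "monte-carlo" samples ``n_perm`` arrangements and applies
        the +1/+1 convention p = (count + 1)/(n_perm + 1); "auto" selects
        exact for n <= 9 samples.
    check_strata : assert on every permutation draw that each stratum's
        label multiset is preserved (debug aid).
    """
    labels = np.asarray(groups)
    n = D.n
    if labels.shape[0] != n:
        raise ValidationError("groups length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("permanova needs at least 2 groups")
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape[0] != n:
            raise ValidationError("strata length does not match distance matrix")
        _, strata_codes = np.unique(strata, return_inverse=True)
    else:
        strata_codes = np.zeros(n, dtype=int)

    D2 = D.d ** 2
    ss_t, ss_w = _ss_parts(D2, codes, a)
    degenerate = ss_w <= 1e-300 or not ss_t > 0
    f_obs = _pseudo_f(ss_t, ss_w, n, a)
    r2 = 0.0 if ss_t <= 0 else (ss_t - ss_w) / ss_t

    if method == "auto":
        method = "exact" if n <= 9 else "monte-carlo"

    if method == "exact":
        count = 0
        total = 0
        for arr in _within_strata_arrangements(codes, strata_codes):
            ss_t_p, ss_w_p = _ss_parts(D2, arr, a)
            f_perm = _pseudo_f(ss_t_p, ss_w_p, n, a)
            total += 1
            if f_perm >= f_obs - 1e-12 or (math.isinf(f_obs) and math.isinf(f_perm)):
                count += 1
        p = count / total
        n_used = total
        obs_ge = count
    elif method == "monte-carlo":
        rng = np.random.default_rng(seed)
        perms = _permute_within_strata(rng, codes, strata_codes, n_perm, check=check_strata)
        count = 0
        for arr in perms:
            f_perm = _pseudo_f(*_ss_parts(D2, arr, a), n, a)
            if f_perm >= f_obs - 1e-12 or (math.isinf(f_obs) and math.isinf(f_perm)):
                count += 1
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
        obs_ge = count
    else:
        raise ValueError(f"unknown method {method!r}")

    return PermanovaResult(
        F=f_obs, r2=float(r2), p=float(p), n_perm=n_used,
        df_between=a - 1, df_within=n - a,
        observed_ge_count=obs_ge, method=method, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _pcoa_axes(D: DistanceMatrix, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes of D, split by eigenvalue sign.

    Returns ``(real_axes, imag_axes)``: coordinates on positive-eigenvalue
    axes and on negative-eigenvalue axes (scaled by sqrt(|lambda|)).  A
    non-Euclidean dissimilarity (e.g. Canberra, Jaccard) generally has both.
    """
    n = D.n
    A = -0.5 * D.d ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    scale = max(abs(evals).max(), 1.0)
    pos = evals > tol * scale
    neg = evals < -tol * scale
    if not pos.any():
        raise ValidationError("degenerate geometry: no positive eigenvalues in PCoA")
    real_axes = evecs[:, pos] * np.sqrt(evals[pos])
    imag_axes = evecs[:, neg] * np.sqrt(-evals[neg]) if neg.any() else np.zeros((n, 0))
    return real_axes, imag_axes


def _spatial_median(X: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld algorithm for the geometric median of rows of X."""
    if X.shape[0] == 0 or X.shape[1] == 0:
        return np.zeros(X.shape[1])
    c = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - c, axis=1)
        if (d < 1e-12).any():
            # median coincides with a data point; nudge via standard rule
            mask = d >= 1e-12
            if not mask.any():
                return c
            w = 1.0 / d[mask]
            c_new = (X[mask] * w[:, None]).sum(axis=0) / w.sum()
        else:
            w = 1.0 / d
            c_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(c_new - c) < tol * (1 + np.linalg.norm(c)):
            return c_new
        c = c_new
    return c


def _anova_f(z: np.ndarray, codes: np.ndarray, a: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(a):
        zg = z[codes == g]
        ss_b += len(zg) * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
    # variation at rounding level (e.g. exactly equal dispersions recovered
    # through an eigendecomposition) counts as zero
    eps = 1e-20 * max((z ** 2).sum(), 1e-300)
    if ss_b + ss_w <= eps:
        return 0.0
    if ss_w <= eps:
        return math.inf
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def permdisp(
    D: DistanceMatrix,
    groups,
    center_type: str = "spatial_median",
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Test homogeneity of multivariate dispersion among groups.

    Samples are embedded by principal coordinates (keeping negative-
    eigenvalue axes); each sample's distance to its group center is
    ``z = sqrt(max(0, d_real^2 - d_imag^2))`` where the two parts are
    Euclidean distances along positive- and negative-eigenvalue axes.  The
    group centers are spatial medians (default) or centroids, computed
    separately in the real and imaginary subspaces.  A one-way ANOVA F on z
    is assessed by permuting group labels of z.
    """
    labels = np.asarray(groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("permdisp needs at least 2 groups")
    for g, lab in enumerate(uniq):
        if (codes == g).sum() < 2:
            raise ValidationError(f"group {lab!r} has fewer than 2 samples")
    if center_type not in ("spatial_median", "centroid"):
        raise ValueError("center_type must be 'spatial_median' or 'centroid'")

    real_axes, imag_axes = _pcoa_axes(D)
    z = np.empty(D.n)
    centers = {}
    for g, lab in enumerate(uniq):
        idx = np.flatnonzero(codes == g)
        if center_type == "centroid":
            c_r = real_axes[idx].mean(axis=0)
            c_i = imag_axes[idx].mean(axis=0) if imag_axes.shape[1] else np.zeros(0)
        else:
            c_r = _spatial_median(real_axes[idx])
            c_i = _spatial_median(imag_axes[idx]) if imag_axes.shape[1] else np.zeros(0)
        centers[str(lab)] = (c_r, c_i)
        d_real2 = ((real_axes[idx] - c_r) ** 2).sum(axis=1)
        d_imag2 = ((imag_axes[idx] - c_i) ** 2).sum(axis=1) if imag_axes.shape[1] else 0.0
        z[idx] = np.sqrt(np.maximum(0.0, d_real2 - d_imag2))

    f_obs = _anova_f(z, codes, a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm = _anova_f(z, rng.permutation(codes), a)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)

    return DispersionResult(
        F=float(f_obs), p=float(p), distances_to_center=z,
        group_centers=centers, center_type=center_type, n_perm=n_perm,
        groups=labels,
    )


# ---------------------------------------------------------------------------
# mean dissimilarity decomposition
# ---------------------------------------------------------------------------

def meandist(D: DistanceMatrix, groups) -> MeanDissimilarity:
    """Mean within-group (diagonal) and between-group (off-diagonal)
    dissimilarities, plus a centroid-separation flag per group pair
    (between-mean exceeding both within-means indicates location effects)."""
    labels = np.asarray(groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    m = np.full((g, g), np.nan)
    singleton = np.zeros(g, dtype=bool)
    for i in range(g):
        idx_i = np.flatnonzero(codes == i)
        if len(idx_i) < 2:
            singleton[i] = True
        else:
            sub = D.d[np.ix_(idx_i, idx_i)]
            m[i, i] = sub[np.triu_indices(len(idx_i), 1)].mean()
        for j in range(i + 1, g):
            idx_j = np.flatnonzero(codes == j)
            m[i, j] = m[j, i] = D.d[np.ix_(idx_i, idx_j)].mean()
    sep = np.zeros((g, g), dtype=bool)
    for i in range(g):
        for j in range(i + 1, g):
            if not (singleton[i] or singleton[j]):
                sep[i, j] = sep[j, i] = m[i, j] > m[i, i] and m[i, j] > m[j, j]
    return MeanDissimilarity(groups=[str(u) for u in uniq], m=m,
                             singleton=singleton, centroid_separation=sep)
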