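"""Non-metric multidimensional scaling and standard-error group ellipses.

NMDS seeks a k-dimensional configuration whose inter-point distances
reproduce the *rank order* of an input dissimilarity matrix.  Badness of
fit is Kruskal's stress-1,

    stress = sqrt( sum (d_hat - d)^2 / sum d^2 ),

where ``d`` are configuration distances and ``d_hat`` their isotonic
(monotone non-decreasing) regression on the rank order of the input
dissimilarities (primary, "untied" treatment of ties).  Optimization
alternates isotonic regression with a Guttman-transform majorization step;
multiple restarts (one principal-coordinate start plus random starts) guard
against local minima and the lowest-stress solution is returned, centered
and rotated to its principal axes.

Group uncertainty on the ordination plane is summarized by standard-error
ellipses: ``(x - c)^T (Cov/n_g)^{-1} (x - c) <= chi2_k(level)`` with ``c``
the group mean score and ``Cov`` the group score covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .diversity import DistanceMatrix
from .feature_io import ValidationError


@dataclass
class NMDSResult:
    scores: np.ndarray          # n x k, centered, principal-axis rotated
    stress: float               # Kruskal stress-1 of the best restart
    converged: bool
    n_restarts: int
    best_restart: int
    seed: int | None
    sample_ids: list[str]
    stress_history: list[np.ndarray] = field(default_factory=list)  # per restart


@dataclass
class EllipseParams:
    group: str
    center: np.ndarray
    covariance: np.ndarray      # standard-error covariance Cov/n_g
    radius_scale: float         # sqrt(chi2_k quantile at `level`)
    level: float
    n: int
    degenerate: bool = False    # singular covariance: major axis only

    @property
    def area(self) -> float:
        det = np.linalg.det(self.covariance)
        return float(np.pi * self.radius_scale ** 2 * np.sqrt(max(det, 0.0)))


def _isotonic_fit(d_config: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone fit of configuration distances in dissimilarity order."""
    fitted_sorted = isotonic_regression(d_config[order], increasing=True).x
    out = np.empty_like(d_config)
    out[order] = fitted_sorted
    return out


def _stress1(d_config: np.ndarray, d_hat: np.ndarray) -> float:
    denom = (d_config ** 2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((d_hat - d_config) ** 2).sum() / denom))


def _guttman_update(X: np.ndarray, d_config: np.ndarray, d_hat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_config > 0, d_hat / d_config, 0.0)
    B = -squareform(ratio)
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def _pcoa_start(D: DistanceMatrix, k: int, rng: np.random.Generator) -> np.ndarray:
    n = D.n
    A = -0.5 * D.d ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = (J @ A @ J + (J @ A @ J).T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    idx = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[idx], 0.0, None)
    X = evecs[:, idx] * np.sqrt(lam)
    weak = lam <= 1e-12 * max(abs(evals).max(), 1.0)
    if weak.any():  # pad degenerate axes with small noise
        X[:, weak] = rng.normal(scale=1e-4 * (1 + X.std()), size=(n, weak.sum()))
    return X


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> NMDSResult:
    """Minimize Kruskal stress-1 of a k-dimensional configuration of D.

    Restart 0 starts from classical principal coordinates; the remaining
    ``n_restarts - 1`` use random Gaussian configurations.  The best
    (lowest final stress) restart is returned; ``converged`` reports
    whether its stress change fell below ``tol`` within ``max_iter``.
    """
    n = D.n
    if k >= n:
        raise ValidationError(f"k={k} must be < number of samples ({n})")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    diss = D.condensed()
    # primary treatment of ties: stable sort keeps tied dissimilarities in
    # input order and lets the isotonic fit choose freely within a tie block
    order = np.argsort(diss, kind="stable")

    best = None
    histories = []
    for r in range(n_restarts):
        if r == 0:
            X = _pcoa_start(D, k, rng)
        else:
            X = rng.normal(size=(n, k))
        hist = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            d_config = pdist(X)
            if d_config.max() <= 0:  # collapsed configuration; reseed
                X = rng.normal(size=(n, k))
                d_config = pdist(X)
            # the isotonic fit minimizes sum (d_hat - d)^2, so it is already
            # optimally scaled for stress-1 at the current configuration
            d_hat = _isotonic_fit(d_config, order)
            stress = _stress1(d_config, d_hat)
            hist.append(stress)
            if abs(prev - stress) < tol:
                converged = True
                break
            prev = stress
            X = _guttman_update(X, d_config, d_hat)
        histories.append(np.array(hist))
        final = hist[-1]
        if best is None or final < best[0] - 1e-15:
            best = (final, X.copy(), converged, r)

    stress, X, converged, r_best = best
    # center and rotate to principal axes; deterministic sign convention
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    # flip each axis so its largest-magnitude score is positive
    lead = X[np.abs(X).argmax(axis=0), np.arange(X.shape[1])]
    X = X * np.where(lead >= 0, 1.0, -1.0)
    return NMDSResult(
        scores=X, stress=float(stress), converged=converged,
        n_restarts=n_restarts, best_restart=r_best, seed=seed,
        sample_ids=list(D.sample_ids), stress_history=histories,
    )


def evaluate_stress(D: DistanceMatrix, scores: np.ndarray) -> float:
    """Stress-1 of an arbitrary configuration against D (for diagnostics
    and invariance checks)."""
    diss = D.condensed()
    order = np.argsort(diss, kind="stable")
    d_config = pdist(np.asarray(scores, float))
    d_hat = _isotonic_fit(d_config, order)
    return _stress1(d_config, d_hat)


def group_ellipses(res: NMDSResult, groups, level: float = 0.95) -> list[EllipseParams]:
    """Standard-error confidence ellipses of group mean scores.

    Groups with fewer than 3 samples are skipped with a warning.  A
    singular covariance yields a degenerate ellipse (flag set; the
    covariance still carries the major axis).
    """
    labels = np.asarray(groups)
    if labels.shape[0] != res.scores.shape[0]:
        raise ValidationError("groups length does not match scores")
    k = res.scores.shape[1]
    q = chi2.ppf(level, df=k)
    out = []
    for lab in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 3:
            warnings.warn(f"group {lab!r} has < 3 samples; ellipse skipped")
            continue
        pts = res.scores[idx]
        c = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        if pts.shape[0] == 1 or not np.all(np.isfinite(cov)):
            cov = np.zeros((k, k))
        se_cov = cov / len(idx)
        degenerate = np.linalg.matrix_rank(se_cov, tol=1e-12 * max(1.0, np.abs(se_cov).max())) < k
        if degenerate:
            warnings.warn(f"group {lab!r}: singular covariance; degenerate ellipse")
        out.append(EllipseParams(
            group=str(lab), center=c, covariance=se_cov,
            radius_scale=float(np.sqrt(q)), level=level, n=len(idx),
            degenerate=bool(degenerate),
        ))
    return out
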