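"""Fuzzy C-means clustering with Mahalanobis distance.

Cells are softly assigned to K clusters by minimising the fuzzy objective

    J_m = sum_i sum_j u_ij^m D(x_i, mu_j)^2,   sum_j u_ij = 1,

with the usual alternating updates: centers are u^m-weighted means and
memberships follow u_ij = 1 / sum_k (D_ij / D_ik)^(2/(m-1)).  The distance D
is either Euclidean or Mahalanobis; in Mahalanobis mode each cluster carries
its own covariance matrix, re-estimated every iteration from the current
memberships (u^m-weighted scatter) and regularised so it stays invertible
even for small or degenerate clusters — the failure mode that breaks
Mahalanobis-based merging in other gating tools when a population has fewer
cells than markers.

Centers are initialised by k-means++ seeding with an explicit RNG seed, so
fits are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .data_io import FlowSample

__all__ = [
    "ClusterModel",
    "mahalanobis",
    "regularize_covariance",
    "fcm_fit",
    "hard_assign",
]

_ZERO_DIST = 1e-12


@dataclass
class ClusterModel:
    """Fitted fuzzy C-means model.

    ``memberships`` rows sum to one; ``covariances`` are the regularised
    per-cluster covariance matrices used for the Mahalanobis distances
    (identity matrices in Euclidean mode).  ``objective_trace`` records the
    fuzzy objective J_m after each iteration.
    """

    centers: np.ndarray  # (K, M)
    memberships: np.ndarray  # (N, K)
    covariances: np.ndarray  # (K, M, M)
    fuzzifier: float
    distance_mode: str
    objective_trace: list[float]
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def mahalanobis(x: np.ndarray, mu: np.ndarray, S: np.ndarray) -> float:
    """Mahalanobis distance sqrt((x-mu) S^-1 (x-mu)^T).

    With S = I this is the Euclidean distance.  S must be symmetric; it is
    regularised if necessary to guarantee invertibility.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    d = x - mu
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(regularize_covariance(S, n_points=S.shape[0] + 1), d)
    return float(np.sqrt(max(d @ sol, 0.0)))


def regularize_covariance(S: np.ndarray, n_points: int) -> np.ndarray:
    """Make a covariance matrix safely invertible.

    Adds a ridge eps*I with eps = 1e-6 * trace(S)/M (eps = 1e-6 if the trace
    is zero).  When the effective number of points is at most the
    dimensionality the off-diagonal entries are unreliable, so only the
    diagonal is kept before adding the ridge.
    """
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    tr = float(np.trace(S))
    eps = 1e-6 * tr / m if tr > 0 else 1e-6
    if n_points <= m:
        return np.diag(np.diag(S)) + eps * np.eye(m)
    return S + eps * np.eye(m)


def _pairwise_mahalanobis(x: np.ndarray, centers: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(N, K) matrix of Mahalanobis distances via per-cluster Cholesky solves."""
    n, _ = x.shape
    k = centers.shape[0]
    d = np.empty((n, k), dtype=float)
    for j in range(k):
        L = np.linalg.cholesky(covs[j])
        y = np.linalg.solve(L, (x - centers[j]).T)  # (M, N)
        d[:, j] = np.sqrt(np.sum(y * y, axis=0))
    return d


def _memberships_from_distances(dist: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update, with the zero-distance convention:
    a cell coinciding with one or more centers splits its membership equally
    among those centers."""
    p = 2.0 / (m - 1.0)
    zero = dist < _ZERO_DIST
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = dist ** (-p)
        u = inv / inv.sum(axis=1, keepdims=True)
    rows = np.any(zero, axis=1)
    if np.any(rows):
        u[rows] = 0.0
        z = zero[rows]
        u[rows] = z / z.sum(axis=1, keepdims=True)
    return u


def _weighted_covariances(
    x: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float
) -> np.ndarray:
    n, dim = x.shape
    k = centers.shape[0]
    w = u**m
    covs = np.empty((k, dim, dim), dtype=float)
    for j in range(k):
        wj = w[:, j]
        tot = wj.sum()
        if tot <= 0:
            covs[j] = np.eye(dim)
            continue
        d = x - centers[j]
        S = (d * wj[:, None]).T @ d / tot
        # effective sample size of the weighted scatter
        n_eff = int(tot**2 / max((wj**2).sum(), 1e-300))
        covs[j] = regularize_covariance(S, n_points=max(n_eff, 1))
    return covs


def fcm_fit(
    sample: FlowSample,
    K: int,
    m: float = 2.0,
    distance_mode: str = "mahalanobis",
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> ClusterModel:
    """Fit fuzzy C-means with K clusters.

    Parameters
    ----------
    sample
        Cells to cluster.
    K
        Number of clusters; must satisfy 1 <= K <= N.
    m
        Fuzzifier (> 1); m = 2 is the conventional default.
    distance_mode
        ``"mahalanobis"`` (per-cluster covariances, re-estimated each
        iteration) or ``"euclidean"``.
    seed
        Seed for the k-means++ center initialisation.
    tol
        Convergence threshold on the max absolute membership change.
    max_iter
        Iteration cap.
    """
    if distance_mode not in ("mahalanobis", "euclidean"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = sample.values
    n, dim = x.shape
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")

    if K == 1:
        center = x.mean(axis=0, keepdims=True)
        u = np.ones((n, 1))
        cov = regularize_covariance(np.cov(x, rowvar=False, ddof=0).reshape(dim, dim), n)
        return ClusterModel(center, u, cov[None], m, distance_mode, [0.0], 0, True)

    centers, _ = kmeans_plusplus(x, n_clusters=K, random_state=seed)
    covs = np.broadcast_to(np.eye(dim), (K, dim, dim)).copy()
    dist = cdist(x, centers)
    u = _memberships_from_distances(dist, m)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = u**m
        denom = w.sum(axis=0)
        dead = denom <= 0
        centers = (w.T @ x) / np.where(dead, 1.0, denom)[:, None]
        if np.any(dead):
            centers[dead] = x[np.argmax(dist.min(axis=1))]  # reseed empty cluster
        if distance_mode == "mahalanobis":
            covs = _weighted_covariances(x, centers, u, m)
            dist = _pairwise_mahalanobis(x, centers, covs)
        else:
            dist = cdist(x, centers)
        u_new = _memberships_from_distances(dist, m)
        trace.append(float(np.sum(u_new**m * dist**2)))
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        if delta < tol:
            converged = True
            break
    if distance_mode == "euclidean":
        covs = np.broadcast_to(np.eye(dim), (K, dim, dim)).copy()
    return ClusterModel(centers, u, covs, m, distance_mode, trace, it, converged)


def hard_assign(model: ClusterModel) -> np.ndarray:
    """Crisp per-cell labels: argmax membership, ties to the lowest index."""
    return np.argmax(model.memberships, axis=1)
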