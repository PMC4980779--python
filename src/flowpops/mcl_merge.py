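"""Merge over-clustered centers into final populations with Markov clustering.

Mode counting deliberately over-estimates the number of populations (a
population spread across several eigenvectors is counted once per axis), so
the fuzzy C-means stage typically splits some populations into several
clusters.  This module builds a similarity graph over the K cluster centers,
runs Markov clustering (MCL) on it, and merges the centers that end up in the
same MCL segment into one final population.

MCL alternates *expansion* (matrix power of the column-stochastic transition
matrix, spreading flow) and *inflation* (element-wise power followed by
column renormalisation, sharpening flow) until the matrix stabilises into
isolated segments.  K is the number of centers — tens, not cells — so dense
matrix algebra is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .fuzzy_cluster import ClusterModel

__all__ = [
    "CenterGraph",
    "MCLResult",
    "PopulationAssignment",
    "build_center_graph",
    "mcl",
    "merge_populations",
]


@dataclass
class CenterGraph:
    """Symmetric non-negative similarity matrix over cluster centers,
    with unit self-loops."""

    adjacency: np.ndarray  # (K, K)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")
        if np.any(a < 0) or np.any(np.diag(a) <= 0):
            raise ValueError("adjacency entries must be >= 0 with positive diagonal")
        self.adjacency = a


@dataclass
class MCLResult:
    """Partition of center indices into MCL segments."""

    segments: list[set[int]]
    converged_matrix: np.ndarray
    iterations: int
    converged: bool


@dataclass
class PopulationAssignment:
    """Map from initial clusters to final merged populations."""

    merge_map: dict[int, int]
    final_labels: np.ndarray
    n_populations: int


def build_center_graph(
    centers: np.ndarray,
    sigma: float | str = "auto",
    scale: float | None = None,
) -> CenterGraph:
    """Gaussian similarity graph over cluster centers.

    A_ij = exp(-||mu_i - mu_j||^2 / (2 sigma^2)) off the diagonal, A_ii = 1.

    ``sigma`` sets the merging length-scale: centers much closer than sigma
    are near-fully connected (and will be merged by MCL), centers much
    farther apart are effectively disconnected.  With ``sigma="auto"`` the
    scale is taken from the clusters themselves: three times the typical
    within-cluster standard deviation ``scale`` when provided (redundant
    centers of one population sit within a few standard deviations of each
    other, distinct populations are much farther), otherwise a quarter of
    the median pairwise center distance.
    """
    centers = np.asarray(centers, dtype=float)
    k = centers.shape[0]
    if k == 1:
        return CenterGraph(np.ones((1, 1)))
    dist = squareform(pdist(centers))
    if sigma == "auto":
        if scale is not None and scale > 0:
            sigma_val = 3.0 * float(scale)
        else:
            med = float(np.median(dist[np.triu_indices(k, 1)]))
            sigma_val = med / 4.0 if med > 0 else 1.0
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")
    a = np.exp(-(dist**2) / (2.0 * sigma_val**2))
    np.fill_diagonal(a, 1.0)
    return CenterGraph(a)


def cluster_scale(model: ClusterModel) -> float:
    """Typical within-cluster standard deviation of a fitted model.

    Median over clusters of sqrt(trace(S_j) / M); used as the length-scale
    for the center similarity graph.
    """
    m = model.centers.shape[1]
    spreads = [np.sqrt(max(np.trace(S), 0.0) / m) for S in model.covariances]
    return float(np.median(spreads))


def _normalize_columns(s: np.ndarray) -> np.ndarray:
    cols = s.sum(axis=0)
    cols = np.where(cols > 0, cols, 1.0)
    return s / cols


def mcl(
    graph: CenterGraph,
    expansion: int = 2,
    inflation: float = 2.0,
    prune: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> MCLResult:
    """Run Markov clustering on a center graph.

    Iterates S <- normalize(power_elementwise(S^expansion, inflation)),
    zeroing entries below ``prune`` before renormalising, until the max-abs
    change drops below ``tol`` or ``max_iter`` is hit (the latter returns the
    current segmentation with ``converged=False``).
    """
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    s = _normalize_columns(graph.adjacency.astype(float))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = s
        s = np.linalg.matrix_power(s, expansion)
        s = s**inflation
        s[s < prune] = 0.0
        s = _normalize_columns(s)
        if float(np.max(np.abs(s - prev))) < tol:
            converged = True
            break
    segments = _extract_segments(s)
    return MCLResult(segments, s, it, converged)


def _extract_segments(s: np.ndarray) -> list[set[int]]:
    """Segments from a converged MCL matrix.

    Attractors are rows with a positive diagonal entry; every node joins the
    attractor with the largest flow into it (ties to the lowest attractor
    index), and attractors that share support in any column are unioned.
    """
    k = s.shape[0]
    attractors = [i for i in range(k) if s[i, i] > 0]
    if not attractors:  # pathological; treat max-row node as attractor
        attractors = [int(np.argmax(s.sum(axis=1)))]
    parent = {a: a for a in attractors}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for j in range(k):
        support = [a for a in attractors if s[a, j] > 0]
        for a in support[1:]:
            union(support[0], a)

    assign: dict[int, int] = {}
    sub = s[attractors, :]  # flow from each column into each attractor row
    for j in range(k):
        best = int(np.argmax(sub[:, j]))  # argmax is first max -> lowest index
        assign[j] = find(attractors[best])
    roots = sorted(set(assign.values()))
    seg_of_root = {r: i for i, r in enumerate(roots)}
    segments: list[set[int]] = [set() for _ in roots]
    for j, r in assign.items():
        segments[seg_of_root[r]].add(j)
    return segments


def merge_populations(labels: np.ndarray, result: MCLResult) -> PopulationAssignment:
    """Relabel cells from initial clusters to merged populations.

    Each initial cluster maps to the index of its MCL segment; segments are
    numbered by their smallest member so the mapping is deterministic.
    """
    labels = np.asarray(labels, dtype=int)
    k = max(int(labels.max()) + 1, max((max(s) for s in result.segments), default=-1) + 1)
    covered = set().union(*result.segments) if result.segments else set()
    if covered != set(range(k)):
        raise ValueError("MCL segments do not partition the initial cluster indices")
    order = sorted(range(len(result.segments)), key=lambda i: min(result.segments[i]))
    merge_map: dict[int, int] = {}
    for new_idx, seg_idx in enumerate(order):
        for c in result.segments[seg_idx]:
            merge_map[c] = new_idx
    lut = np.array([merge_map[c] for c in range(k)], dtype=int)
    return PopulationAssignment(
        merge_map=merge_map,
        final_labels=lut[labels],
        n_populations=len(result.segments),
    )
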