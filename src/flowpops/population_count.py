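"""Estimate the initial number of clusters K by counting KDE modes.

The data are projected onto each eigenvector of the sample covariance matrix
(PCA axes).  For each 1-D projection a Gaussian kernel density estimate is
formed with a Scott-type bandwidth h = (7/2) sigma* N^(-1/3), and modes are
counted as the number of statistically significant +/- sign changes of the
density gradient along a regular grid.  Significance of the gradient at each
grid point uses a plug-in standard error with a two-sided Bonferroni
correction over the grid (a SiZer-style test).  K is the total mode count
over all eigen-projections, floored at 1.

The intent is an upper-ish bound on the number of populations: a cluster that
projects onto several eigenvectors is counted more than once, and the excess
is removed later by Markov-clustering merging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data_io import FlowSample

__all__ = [
    "ModeCountResult",
    "eigen_projections",
    "scott_bandwidth",
    "kde_and_gradient",
    "count_modes",
    "estimate_initial_k",
]

GRID_SIZE = 512  # grid points per projection; resolves modes separated by > h

_CHUNK = 65536  # cells per block in the KDE sweeps, keeps memory ~ G * chunk


@dataclass
class ModeCountResult:
    """Mode counts per eigen-projection and the resulting initial K."""

    per_eigenvector_modes: list[int]
    K: int
    bandwidths: list[float]


def eigen_projections(sample: FlowSample) -> list[np.ndarray]:
    """Project centered cells onto the covariance eigenvectors.

    Returns one length-N score vector per eigenvector, ordered by descending
    eigenvalue.  Eigenvector sign is arbitrary; mode counts are unaffected.
    """
    x = sample.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells to form a covariance matrix")
    xc = x - x.mean(axis=0)
    cov = np.cov(xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    scores = xc @ evecs[:, order]
    return [scores[:, j].copy() for j in range(scores.shape[1])]


def scott_bandwidth(e: np.ndarray) -> float:
    """Scott-type KDE bandwidth h = (7/2) * sigma* * N^(-1/3).

    ``sigma*`` is the sample standard deviation of the projection; a constant
    vector has no scale and raises.
    """
    e = np.asarray(e, dtype=float)
    n = e.size
    if n < 2:
        raise ValueError("need at least 2 points")
    sigma = float(np.std(e, ddof=1))
    if sigma <= 0:
        raise ValueError("constant vector: bandwidth undefined")
    return 3.5 * sigma * n ** (-1.0 / 3.0)


def kde_and_gradient(
    e: np.ndarray, grid: np.ndarray, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE and its analytic gradient on a grid.

    f(l)  = (1 / (N h))   sum_i K((l - e_i) / h)
    f'(l) = -(1 / (N h^3)) sum_i (l - e_i) K((l - e_i) / h)

    with K the standard normal density.
    """
    e = np.asarray(e, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    n = e.size
    dens = np.zeros_like(grid)
    grad = np.zeros_like(grid)
    for start in range(0, n, _CHUNK):
        block = e[start : start + _CHUNK]
        u = (grid[:, None] - block[None, :]) / h  # (G, chunk)
        k = np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)
        dens += k.sum(axis=1)
        grad += (u * k).sum(axis=1)
    dens /= n * h
    grad *= -1.0 / (n * h * h)
    return dens, grad


def _gradient_significance(
    e: np.ndarray, grid: np.ndarray, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and its pointwise plug-in standard error on the grid.

    The gradient is the mean over cells of g_i(l) = -(l - e_i) K((l-e_i)/h) / h^3;
    its standard error is std_i(g_i) / sqrt(N).
    """
    e = np.asarray(e, dtype=float)
    n = e.size
    s1 = np.zeros_like(grid)
    s2 = np.zeros_like(grid)
    for start in range(0, n, _CHUNK):
        block = e[start : start + _CHUNK]
        d = grid[:, None] - block[None, :]
        u = d / h
        g = -d * (np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)) / h**3
        s1 += g.sum(axis=1)
        s2 += (g * g).sum(axis=1)
    mean = s1 / n
    var = np.maximum(s2 / n - mean * mean, 0.0) * n / max(n - 1, 1)
    se = np.sqrt(var / n)
    return mean, se


def _make_grid(e: np.ndarray, h: float, size: int = GRID_SIZE) -> np.ndarray:
    return np.linspace(e.min() - 3 * h, e.max() + 3 * h, size)


def count_modes(e: np.ndarray, alpha: float = 0.05) -> int:
    """Count significant KDE modes of a 1-D projection.

    A mode is a transition of the density gradient from significantly positive
    to significantly negative along the grid; grid points are declared
    significant when |gradient| / SE exceeds the two-sided Bonferroni normal
    quantile z(1 - alpha / (2 G)).
    """
    e = np.asarray(e, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 points")
    h = scott_bandwidth(e)
    grid = _make_grid(e, h)
    grad, se = _gradient_significance(e, grid, h)
    z = norm.ppf(1.0 - alpha / (2.0 * grid.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, np.abs(grad) / np.where(se > 0, se, 1.0), np.inf)
    signif = stat > z
    signs = np.sign(grad[signif])
    modes = 0
    prev = 0.0
    for s in signs:
        if s < 0 and prev > 0:
            modes += 1
        if s != 0:
            prev = s
    return modes


def estimate_initial_k(sample: FlowSample, alpha: float = 0.05) -> ModeCountResult:
    """Estimate the initial cluster count K for a sample.

    K is the sum of significant mode counts over all eigen-projections,
    floored at 1 so that downstream clustering always has a target.
    """
    counts: list[int] = []
    bandwidths: list[float] = []
    for e in eigen_projections(sample):
        sigma = float(np.std(e, ddof=1))
        if sigma <= 0:
            # degenerate direction (zero variance): contributes no modes
            counts.append(0)
            bandwidths.append(0.0)
            continue
        counts.append(count_modes(e, alpha=alpha))
        bandwidths.append(scott_bandwidth(e))
    k = max(1, int(sum(counts)))
    return ModeCountResult(per_eigenvector_modes=counts, K=k, bandwidths=bandwidths)
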