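"""Cohort-level anomaly detection from multi-subject cytometry data.

All subjects' cells are pooled into one matrix and the two-stage clustering
pipeline is run once on the pool.  Each subject is then summarised by a
feature row (the "GDataset"): for every final population, the median
fluorescence intensity (MFI) of the subject's cells in that population, per
marker, followed by the percentage of the subject's cells falling in it.

On this P x L subject-feature table a modified density-peak statistic is
computed per subject:

* rho_i — local density, the reciprocal of the mean squared distance to the
  omega = round(r * P) nearest neighbours;
* delta_i — mean distance to the gamma nearest *higher-density* subjects
  (gamma = floor(P/100), floored at 1), with the global density maximum
  assigned its distance to the farthest subject.

Anomalous subjects are isolated (low rho) and far from denser regions (high
delta), so their delta/rho ratio is extreme; an iterative chi-square outlier
test on the ratio list flags them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2

from .data_io import FlowSample
from .mcl_merge import PopulationAssignment
from .pipeline import ClusterRun, RunConfig, identify_cell_types

__all__ = [
    "CohortFeatures",
    "DensityPeakResult",
    "AnomalyReport",
    "pool_and_cluster",
    "build_gdataset",
    "standardize",
    "local_density",
    "delta_distance",
    "detect_anomalies",
    "run_anomaly_pipeline",
]


@dataclass
class CohortFeatures:
    """Per-subject feature table (one row per subject).

    Column layout, per final population j: M MFI columns (one per marker)
    followed by one percentage column.  Before standardisation each subject's
    percentage columns sum to 100.
    """

    subject_ids: list[str]
    features: np.ndarray  # (P, L)
    marker_names: list[str]
    n_populations: int
    standardized: bool = False

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    def column_names(self) -> list[str]:
        names = []
        for j in range(self.n_populations):
            names += [f"pop{j}_mfi_{m}" for m in self.marker_names]
            names.append(f"pop{j}_pct")
        return names

    def percentage_columns(self) -> np.ndarray:
        m = len(self.marker_names)
        return np.arange(self.n_populations) * (m + 1) + m


@dataclass
class DensityPeakResult:
    """Per-subject density-peak quantities and the flagged outliers."""

    rho: np.ndarray
    delta: np.ndarray
    ratios: np.ndarray  # delta / rho
    psi_sets: list[list[int]]
    omega: int
    gamma: int
    flagged: set[int]


@dataclass
class AnomalyReport:
    """Everything the cohort pipeline produces, JSON-serialisable via to_dict."""

    subject_ids: list[str]
    rho: np.ndarray
    delta: np.ndarray
    ratios: np.ndarray
    flagged: set[int]
    n_populations: int
    omega: int
    gamma: int
    cluster_run: ClusterRun | None = None
    features: CohortFeatures | None = None

    def flagged_ids(self) -> list[str]:
        return sorted(self.subject_ids[i] for i in self.flagged)

    def to_dict(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "rho": self.rho.tolist(),
            "delta": self.delta.tolist(),
            "ratio": self.ratios.tolist(),
            "flagged_indices": sorted(int(i) for i in self.flagged),
            "flagged_subjects": self.flagged_ids(),
            "n_populations": self.n_populations,
            "omega": self.omega,
            "gamma": self.gamma,
        }


def pool_and_cluster(
    samples: list[FlowSample],
    per_subject_cap: int | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[FlowSample, np.ndarray, ClusterRun]:
    """Pool subjects into one matrix and run the clustering pipeline on it.

    Returns the pooled sample, a per-cell subject index (provenance), and the
    full :class:`ClusterRun`.  ``per_subject_cap`` subsamples each subject's
    cells without replacement, reproducibly from ``seed``.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 subjects to pool")
    panel = samples[0].marker_names
    for s in samples:
        if s.marker_names != panel:
            raise ValueError(
                f"marker panel mismatch for subject {s.subject_id or s.sample_id!r}: "
                f"{s.marker_names} != {panel}"
            )
    rng = np.random.default_rng(seed)
    blocks, provenance = [], []
    for idx, s in enumerate(samples):
        vals = s.values
        if per_subject_cap is not None and vals.shape[0] > per_subject_cap:
            keep = rng.choice(vals.shape[0], size=per_subject_cap, replace=False)
            vals = vals[np.sort(keep)]
        blocks.append(vals)
        provenance.append(np.full(vals.shape[0], idx))
    pooled = FlowSample(
        sample_id="pooled",
        marker_names=list(panel),
        values=np.vstack(blocks),
    )
    subject_index = np.concatenate(provenance)
    config = replace(config, seed=seed) if config else RunConfig(seed=seed)
    run = identify_cell_types(pooled, config)
    return pooled, subject_index, run


def build_gdataset(
    pooled: FlowSample,
    subject_index: np.ndarray,
    assignment: PopulationAssignment,
    subject_ids: list[str] | None = None,
) -> CohortFeatures:
    """Extract the per-subject MFI + percentage feature table.

    For a subject with no cells in some population the percentage is 0 and
    the MFI columns are imputed with that population's pooled (all-subject)
    MFI, so absence is carried solely by the percentage feature.
    """
    labels = assignment.final_labels
    subject_index = np.asarray(subject_index)
    n_pops = assignment.n_populations
    p = int(subject_index.max()) + 1
    m = pooled.n_markers
    if subject_ids is None:
        subject_ids = [f"subject{i}" for i in range(p)]
    pooled_mfi = np.empty((n_pops, m))
    for j in range(n_pops):
        cells = pooled.values[labels == j]
        pooled_mfi[j] = np.median(cells, axis=0) if cells.size else 0.0
    feats = np.empty((p, n_pops * (m + 1)))
    for i in range(p):
        mine = subject_index == i
        total = int(mine.sum())
        if total == 0:
            raise ValueError(f"subject {subject_ids[i]!r} has zero cells")
        for j in range(n_pops):
            sel = mine & (labels == j)
            count = int(sel.sum())
            col = j * (m + 1)
            if count:
                feats[i, col : col + m] = np.median(pooled.values[sel], axis=0)
            else:
                feats[i, col : col + m] = pooled_mfi[j]
            feats[i, col + m] = 100.0 * count / total
    return CohortFeatures(
        subject_ids=list(subject_ids),
        features=feats,
        marker_names=list(pooled.marker_names),
        n_populations=n_pops,
    )


def standardize(features: CohortFeatures) -> CohortFeatures:
    """Z-score each feature column (zero-variance columns become 0).

    MFI and percentage features live on different scales; the Euclidean
    distances behind rho and delta need commensurate columns.
    """
    x = features.features
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects to standardize")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return replace(features, features=z, standardized=True)


def _feature_matrix(features: CohortFeatures | np.ndarray) -> np.ndarray:
    if isinstance(features, CohortFeatures):
        return features.features
    return np.asarray(features, dtype=float)


def default_omega(r: float, p: int) -> int:
    """Neighbourhood size omega = round(r * P), kept within [1, P-1]."""
    return min(max(1, round(r * p)), p - 1)


def default_gamma(p: int) -> int:
    """Rarity threshold gamma = floor(P / 100), floored at 1."""
    return max(1, p // 100)


def local_density(
    features: CohortFeatures | np.ndarray,
    r: float = 0.15,
    omega: int | None = None,
) -> tuple[np.ndarray, int]:
    """Local density rho_i = omega / sum of squared distances to the omega
    nearest neighbours; returns (rho, omega).  ``omega`` overrides the
    default round(r * P) neighbourhood size."""
    x = _feature_matrix(features)
    p = x.shape[0]
    if p < 3:
        raise ValueError("need at least 3 subjects")
    if not 0 < r < 1:
        raise ValueError("density parameter r must be in (0, 1)")
    if omega is None:
        omega = default_omega(r, p)
    if not 1 <= omega <= p - 1:
        raise ValueError(f"omega must be in [1, {p - 1}]")
    d2 = squareform(pdist(x)) ** 2
    np.fill_diagonal(d2, np.inf)
    part = np.partition(d2, omega - 1, axis=1)[:, :omega]
    denom = part.sum(axis=1)
    rho = np.empty(p)
    pos = denom > 0
    rho[pos] = omega / denom[pos]
    if np.any(~pos):  # coincident subjects: sentinel = 10x the max finite density
        mx = rho[pos].max() if np.any(pos) else 1.0
        rho[~pos] = 10.0 * mx
    return rho, omega


def delta_distance(
    features: CohortFeatures | np.ndarray,
    rho: np.ndarray,
    gamma: int | None = None,
) -> tuple[np.ndarray, list[list[int]]]:
    """Mean distance delta_i to the gamma nearest subjects of higher density.

    psi_i is the set of (up to) gamma nearest neighbours of subject i among
    subjects with rho_j > rho_i; the global density maximum, which has no
    higher-density neighbour, takes delta = its distance to the farthest
    subject.
    """
    x = _feature_matrix(features)
    rho = np.asarray(rho, dtype=float)
    p = x.shape[0]
    if gamma is None:
        gamma = default_gamma(p)
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    dist = squareform(pdist(x))
    delta = np.empty(p)
    psi_sets: list[list[int]] = []
    for i in range(p):
        higher = np.flatnonzero(rho > rho[i])
        if higher.size == 0:
            delta[i] = dist[i].max()
            psi_sets.append([])
            continue
        order = higher[np.argsort(dist[i, higher], kind="stable")]
        psi = order[:gamma]
        delta[i] = float(dist[i, psi].mean())
        psi_sets.append(psi.tolist())
    return delta, psi_sets


def detect_anomalies(
    rho: np.ndarray, delta: np.ndarray, alpha: float = 0.05
) -> set[int]:
    """Chi-square outlier test on the delta/rho ratio list.

    A subject is flagged when its squared standardised ratio
    (x_i - mean)^2 / variance exceeds the chi-square(1) upper quantile at
    1 - alpha, with mean and (population) variance taken over the full ratio
    list and only the upper tail (x_i > mean) eligible — anomalies sit at
    extremely *high* delta/rho.  Keeping the reference moments fixed makes
    the test conservative on unremarkable cohorts: a lone extreme value
    inflates the variance and masks the merely-large ones, so flagging does
    not cascade down the sorted ratio list.
    """
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    ratios = delta / rho
    threshold = chi2.ppf(1.0 - alpha, df=1)
    var = ratios.var()
    if var <= 0:
        return set()
    stat = (ratios - ratios.mean()) ** 2 / var
    upper = ratios > ratios.mean()
    return set(np.flatnonzero((stat > threshold) & upper).tolist())


def run_anomaly_pipeline(
    samples: list[FlowSample],
    r: float = 0.15,
    alpha: float = 0.05,
    seed: int = 0,
    per_subject_cap: int | None = None,
    gamma: int | None = None,
    config: RunConfig | None = None,
) -> AnomalyReport:
    """Full cohort pipeline: pool, cluster, featurise, score, flag.

    Deterministic given ``seed``; ``r`` and ``alpha`` are the density and
    outlier-significance parameters.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 subjects for anomaly detection")
    pooled, subject_index, run = pool_and_cluster(
        samples, per_subject_cap=per_subject_cap, seed=seed, config=config
    )
    subject_ids = [
        s.subject_id or s.sample_id or f"subject{i}" for i, s in enumerate(samples)
    ]
    feats = build_gdataset(pooled, subject_index, run.assignment, subject_ids)
    z = standardize(feats)
    rho, omega = local_density(z, r=r)
    delta, psi = delta_distance(z, rho, gamma=gamma)
    flagged = detect_anomalies(rho, delta, alpha=alpha)
    return AnomalyReport(
        subject_ids=subject_ids,
        rho=rho,
        delta=delta,
        ratios=delta / rho,
        flagged=flagged,
        n_populations=run.n_populations,
        omega=omega,
        gamma=gamma if gamma is not None else default_gamma(len(samples)),
        cluster_run=run,
        features=z,
    )
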