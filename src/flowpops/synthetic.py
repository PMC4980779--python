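"""Seeded synthetic cytometry data: mixture samples and multi-subject cohorts.

Two generators stand in for public benchmark data:

* :func:`gen_mixture_sample` draws one subject's cells from a Gaussian
  mixture with known per-cell population labels — the classic
  "well-separated blobs" demonstration of automated gating.
* :func:`gen_cohort` draws a cohort of subjects from a shared mixture
  template with subject-level jitter of the population means; a chosen
  subset of subjects is made anomalous by shifting the means of selected
  markers in selected populations (in units of the pooled within-population
  standard deviation) and/or by changing population fractions, emulating
  diseased donors among healthy controls.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import FlowSample

__all__ = [
    "MixtureSpec",
    "CohortSpec",
    "gen_mixture_sample",
    "gen_cohort",
    "seven_population_spec",
    "cohort_template_spec",
    "default_cohort_spec",
]

# Seven well-separated 2-D populations on a 10-unit grid (pairwise center
# distance >= 10 with unit covariance), arranged so that the eigen-projection
# mode counts sum to the true population count.
_SEVEN_CENTERS = np.array(
    [[0, 10], [10, 0], [10, 10], [10, 20], [10, 30], [20, 0], [20, 20]],
    dtype=float,
)


@dataclass
class MixtureSpec:
    """Gaussian mixture description for one sample."""

    means: np.ndarray  # (n_populations, M)
    covariances: np.ndarray  # (n_populations, M, M)
    weights: np.ndarray  # (n_populations,)
    n_cells: int
    seed: int = 0
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        k, m = self.means.shape
        if self.covariances.shape != (k, m, m):
            raise ValueError("covariances must be (n_populations, M, M)")
        if self.weights.shape != (k,):
            raise ValueError("weights must have one entry per population")
        if np.any(self.weights <= 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        if not self.marker_names:
            self.marker_names = [f"M{i + 1}" for i in range(m)]

    @property
    def n_populations(self) -> int:
        return self.means.shape[0]

    @property
    def n_markers(self) -> int:
        return self.means.shape[1]


@dataclass
class CohortSpec:
    """Multi-subject cohort built from a shared mixture template.

    ``anomaly_shift`` is expressed in pooled within-population standard
    deviations and is applied to ``anomaly_markers`` of ``anomaly_population``
    for the anomalous subjects; ``anomaly_fraction_change`` is added to that
    population's weight (renormalised).  ``jitter_sd`` is the standard
    deviation of the per-subject, per-population mean perturbation shared by
    all subjects.
    """

    template: MixtureSpec
    n_subjects: int = 150
    cells_per_subject: int = 200
    jitter_sd: float = 0.3
    n_anomalous: int = 0
    anomaly_shift: float = 4.0
    anomaly_population: int = 0
    anomaly_markers: tuple[int, ...] = (2, 3)
    anomaly_fraction_change: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_anomalous >= self.n_subjects:
            raise ValueError("anomalous subject count must be < number of subjects")
        if self.anomaly_shift < 0:
            raise ValueError("anomaly shift must be >= 0")


def seven_population_spec(n_cells: int = 2100, seed: int = 0) -> MixtureSpec:
    """Default single-subject demonstration: seven unit-variance 2-D blobs,
    equal weights, 300 cells each."""
    k, m = _SEVEN_CENTERS.shape
    return MixtureSpec(
        means=_SEVEN_CENTERS,
        covariances=np.broadcast_to(np.eye(m), (k, m, m)).copy(),
        weights=np.full(k, 1.0 / k),
        n_cells=n_cells,
        seed=seed,
    )


def cohort_template_spec() -> MixtureSpec:
    """Default cohort template: three unit-variance populations in 5-D,
    pairwise means >= 10 apart, weights (0.5, 0.3, 0.2)."""
    means = np.zeros((3, 5))
    means[1, 0] = 10.0
    means[2, 1] = 10.0
    return MixtureSpec(
        means=means,
        covariances=np.broadcast_to(np.eye(5), (3, 5, 5)).copy(),
        weights=np.array([0.5, 0.3, 0.2]),
        n_cells=200,
    )


def default_cohort_spec(
    n_subjects: int = 150, n_anomalous: int = 2, seed: int = 0
) -> CohortSpec:
    """Default cohort: 150 subjects, 200 cells each, jitter sd 0.3, anomalous
    subjects shifted +4 pooled SD on markers 3-4 of population 1."""
    return CohortSpec(
        template=cohort_template_spec(),
        n_subjects=n_subjects,
        n_anomalous=n_anomalous,
        seed=seed,
    )


def gen_mixture_sample(
    spec: MixtureSpec, sample_id: str = "synthetic", subject_id: str | None = None
) -> tuple[FlowSample, np.ndarray]:
    """Draw one sample from a Gaussian mixture.

    Returns the sample and the per-cell generating-population labels.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.n_populations, size=spec.n_cells, p=spec.weights)
    values = np.empty((spec.n_cells, spec.n_markers))
    for j in range(spec.n_populations):
        idx = np.flatnonzero(labels == j)
        if idx.size:
            values[idx] = rng.multivariate_normal(
                spec.means[j], spec.covariances[j], size=idx.size
            )
    sample = FlowSample(
        sample_id=sample_id,
        subject_id=subject_id,
        marker_names=list(spec.marker_names),
        values=values,
    )
    return sample, labels


def pooled_within_sd(template: MixtureSpec) -> np.ndarray:
    """Per-marker pooled within-population standard deviation of a template
    (weight-averaged covariance diagonal)."""
    diag = np.array([np.diag(c) for c in template.covariances])
    return np.sqrt(np.sum(template.weights[:, None] * diag, axis=0))


def gen_cohort(spec: CohortSpec) -> tuple[list[FlowSample], set[int]]:
    """Generate a cohort of subjects plus the anomaly ground truth.

    Returns one :class:`FlowSample` per subject (``subject_id`` = ``S000``,
    ``S001``, ...) and the set of anomalous subject indices.
    """
    master = np.random.default_rng(spec.seed)
    anomalous = set(
        master.choice(spec.n_subjects, size=spec.n_anomalous, replace=False).tolist()
    )
    sd = pooled_within_sd(spec.template)
    samples: list[FlowSample] = []
    for p in range(spec.n_subjects):
        means = spec.template.means + master.normal(
            0.0, spec.jitter_sd, size=spec.template.means.shape
        )
        weights = spec.template.weights.copy()
        if p in anomalous:
            for mk in spec.anomaly_markers:
                means[spec.anomaly_population, mk] += spec.anomaly_shift * sd[mk]
            if spec.anomaly_fraction_change != 0.0:
                weights[spec.anomaly_population] = max(
                    weights[spec.anomaly_population] + spec.anomaly_fraction_change,
                    1e-3,
                )
                weights = weights / weights.sum()
        sub_spec = replace(
            spec.template,
            means=means,
            weights=weights,
            n_cells=spec.cells_per_subject,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        sample, _ = gen_mixture_sample(
            sub_spec, sample_id=f"S{p:03d}", subject_id=f"S{p:03d}"
        )
        samples.append(sample)
    return samples, anomalous
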