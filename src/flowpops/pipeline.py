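"""End-to-end single-sample cell-type identification.

Chains the three stages: KDE mode counting for the initial cluster count K,
Mahalanobis fuzzy C-means for the K initial clusters, and Markov clustering
of the cluster centers to merge redundant clusters into final populations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .data_io import FlowSample
from .fuzzy_cluster import ClusterModel, fcm_fit, hard_assign
from .mcl_merge import (
    MCLResult,
    PopulationAssignment,
    build_center_graph,
    cluster_scale,
    mcl,
    merge_populations,
)
from .population_count import ModeCountResult, estimate_initial_k

__all__ = ["RunConfig", "ClusterRun", "identify_cell_types"]


@dataclass
class RunConfig:
    """Tunable parameters of the full pipeline.

    Defaults: fuzzifier m = 2, mode-count significance 0.05, MCL expansion
    and inflation 2, density parameter r = 0.15 and outlier significance
    0.05 for the cohort stage.
    """

    m: float = 2.0
    alpha_modes: float = 0.05
    distance_mode: str = "mahalanobis"
    expansion: int = 2
    inflation: float = 2.0
    mcl_sigma: float | str = "auto"
    r: float = 0.15
    alpha_outlier: float = 0.05
    seed: int = 0
    markers: list[str] | None = None
    per_subject_cap: int | None = None
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 100

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a config from a JSON key-value file; keyword overrides win."""
        import json
        from pathlib import Path

        data = json.loads(Path(path).read_text())
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ClusterRun:
    """All artifacts of one cell-type identification run."""

    sample: FlowSample
    mode_result: ModeCountResult
    model: ClusterModel
    initial_labels: np.ndarray
    mcl_result: MCLResult
    assignment: PopulationAssignment

    @property
    def n_populations(self) -> int:
        return self.assignment.n_populations

    @property
    def final_labels(self) -> np.ndarray:
        return self.assignment.final_labels

    def population_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.final_labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def report(self) -> dict:
        """JSON-serialisable run summary."""
        return {
            "sample_id": self.sample.sample_id,
            "n_cells": self.sample.n_cells,
            "markers": self.sample.marker_names,
            "per_eigenvector_modes": self.mode_result.per_eigenvector_modes,
            "initial_k": self.mode_result.K,
            "bandwidths": self.mode_result.bandwidths,
            "fcm_iterations": self.model.n_iter,
            "fcm_converged": self.model.converged,
            "mcl_iterations": self.mcl_result.iterations,
            "mcl_converged": self.mcl_result.converged,
            "merge_map": {str(k): v for k, v in self.assignment.merge_map.items()},
            "n_populations": self.n_populations,
            "population_sizes": self.population_sizes(),
        }


def identify_cell_types(sample: FlowSample, config: RunConfig | None = None) -> ClusterRun:
    """Run the full two-stage pipeline on one sample."""
    config = config or RunConfig()
    if config.markers:
        sample = sample.select_markers(config.markers)
    mode_result = estimate_initial_k(sample, alpha=config.alpha_modes)
    model = fcm_fit(
        sample,
        K=mode_result.K,
        m=config.m,
        distance_mode=config.distance_mode,
        seed=config.seed,
        tol=config.fcm_tol,
        max_iter=config.fcm_max_iter,
    )
    initial_labels = hard_assign(model)
    graph = build_center_graph(
        model.centers, sigma=config.mcl_sigma, scale=cluster_scale(model)
    )
    mcl_result = mcl(graph, expansion=config.expansion, inflation=config.inflation)
    assignment = merge_populations(initial_labels, mcl_result)
    return ClusterRun(sample, mode_result, model, initial_labels, mcl_result, assignment)
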