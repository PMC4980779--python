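"""Headless plotting: biaxial population scatters and density-peak maps."""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .anomaly import AnomalyReport
from .data_io import FlowSample

__all__ = ["plot_biaxial", "plot_all_biaxial", "plot_decision_graph", "plot_sorted_ratios"]


def plot_biaxial(
    sample: FlowSample,
    labels: np.ndarray,
    marker_x: str,
    marker_y: str,
    out_path: str | Path,
    max_points: int = 20000,
    seed: int = 0,
) -> Path:
    """Scatter two markers coloured by population label (a synthetic 'gate').

    Down-samples to ``max_points`` cells for rendering speed; raises on an
    unknown marker or identical axes.
    """
    if marker_x == marker_y:
        raise ValueError("marker_x and marker_y must differ")
    for m in (marker_x, marker_y):
        if m not in sample.marker_names:
            raise KeyError(f"unknown marker {m!r}; sample has {sample.marker_names}")
    labels = np.asarray(labels)
    ix = sample.marker_names.index(marker_x)
    iy = sample.marker_names.index(marker_y)
    n = sample.n_cells
    keep = np.arange(n)
    if n > max_points:
        keep = np.sort(np.random.default_rng(seed).choice(n, max_points, replace=False))
    fig, ax = plt.subplots(figsize=(5, 5))
    for pop in np.unique(labels[keep]):
        sel = keep[labels[keep] == pop]
        ax.scatter(
            sample.values[sel, ix],
            sample.values[sel, iy],
            s=2,
            alpha=0.5,
            label=f"pop {pop}",
        )
    ax.set_xlabel(marker_x)
    ax.set_ylabel(marker_y)
    ax.legend(markerscale=4, fontsize=8)
    ax.set_title(sample.sample_id)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_all_biaxial(
    sample: FlowSample, labels: np.ndarray, out_dir: str | Path, **kwargs
) -> list[Path]:
    """One biaxial plot per unordered marker pair (M·(M−1)/2 files)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for mx, my in combinations(sample.marker_names, 2):
        fname = out_dir / f"biaxial_{mx}_vs_{my}.png"
        paths.append(plot_biaxial(sample, labels, mx, my, fname, **kwargs))
    return paths


def plot_decision_graph(report: AnomalyReport, out_path: str | Path) -> Path:
    """Delta-versus-rho scatter with flagged subjects highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    flagged = sorted(report.flagged)
    normal = [i for i in range(len(report.subject_ids)) if i not in report.flagged]
    ax.scatter(report.rho[normal], report.delta[normal], s=14, label="normal")
    if flagged:
        ax.scatter(
            report.rho[flagged], report.delta[flagged], s=30, c="red", label="flagged"
        )
    ax.set_xlabel(r"$\rho$ (local density)")
    ax.set_ylabel(r"$\delta$ (distance to denser subjects)")
    ax.legend(fontsize=8)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_sorted_ratios(report: AnomalyReport, out_path: str | Path) -> Path:
    """Subjects sorted by delta/rho; anomalies stand out at the high end."""
    order = np.argsort(report.ratios)
    colors = ["red" if i in report.flagged else "C0" for i in order]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(order)), report.ratios[order], color=colors, width=1.0)
    ax.set_xlabel("subjects (sorted)")
    ax.set_ylabel(r"$\delta/\rho$")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
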