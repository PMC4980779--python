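"""External evaluation of a clustering against reference labels.

The score is the class-size-weighted F-measure commonly used for cytometry
gating benchmarks: for every reference class, take the best F1 over predicted
clusters (precision = n_ij / |cluster j|, recall = n_ij / |class i|), then
average weighted by class size:

    F(L, L') = (1/N) * sum_i |l_i| * max_j F1(l_i, l'_j)

It is 1 for any bijective relabeling of the reference and decreases both when
classes are split across clusters (recall loss) and when clusters mix classes
(precision loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcl_merge import PopulationAssignment

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "pairwise_f",
    "f_measure",
    "count_populations",
]


@dataclass
class ContingencyTable:
    """Reference-class x predicted-cluster co-occurrence counts."""

    counts: np.ndarray  # (R, C) ints
    reference_sizes: np.ndarray  # (R,)
    predicted_sizes: np.ndarray  # (C,)
    reference_ids: np.ndarray
    predicted_ids: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def contingency_table(reference: np.ndarray, predicted: np.ndarray) -> ContingencyTable:
    """Build the contingency table of two label vectors of equal length."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape or reference.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length, got {reference.shape} vs {predicted.shape}"
        )
    ref_ids, ref_inv = np.unique(reference, return_inverse=True)
    pred_ids, pred_inv = np.unique(predicted, return_inverse=True)
    counts = np.zeros((ref_ids.size, pred_ids.size), dtype=np.int64)
    np.add.at(counts, (ref_inv, pred_inv), 1)
    return ContingencyTable(
        counts=counts,
        reference_sizes=counts.sum(axis=1),
        predicted_sizes=counts.sum(axis=0),
        reference_ids=ref_ids,
        predicted_ids=pred_ids,
    )


def pairwise_f(table: ContingencyTable, i: int, j: int) -> tuple[float, float, float]:
    """Precision, recall and F1 of reference class i vs predicted cluster j."""
    size_ref = int(table.reference_sizes[i])
    size_pred = int(table.predicted_sizes[j])
    if size_ref == 0 or size_pred == 0:
        raise ValueError("empty reference class or predicted cluster")
    nij = int(table.counts[i, j])
    precision = nij / size_pred
    recall = nij / size_ref
    f = 0.0 if nij == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def f_measure(
    reference: np.ndarray,
    predicted: np.ndarray,
    unassigned_label=None,
) -> float:
    """Class-size-weighted best-match F-measure in (0, 1].

    ``unassigned_label``, if given, marks reference cells without a manual
    gate; those cells are dropped before scoring.
    """
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    if unassigned_label is not None:
        keep = reference != unassigned_label
        reference, predicted = reference[keep], predicted[keep]
    if reference.size == 0:
        raise ValueError("no labelled cells to score")
    table = contingency_table(reference, predicted)
    counts = table.counts.astype(float)
    prec = counts / table.predicted_sizes[None, :]
    rec = counts / table.reference_sizes[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(counts > 0, 2 * prec * rec / (prec + rec), 0.0)
    best = f.max(axis=1)
    n = table.n
    return float(np.sum(table.reference_sizes * best) / n)


def count_populations(assignment: PopulationAssignment) -> int:
    """Number of final populations that received at least one cell."""
    return int(np.unique(assignment.final_labels).size)
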