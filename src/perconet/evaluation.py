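"""Comparison of retrieved vs planted partitions.

NMI is computed from the contingency (overlap) table of the two partitions,

    NMI(A,B) = -2 sum_ij N_ij ln(N_ij N / (N_i. N_.j))
               / [ sum_i N_i. ln(N_i./N) + sum_j N_.j ln(N_.j/N) ]

which is 0 when the retrieved structure carries no information about the
planted one and 1 for identical partitions (up to relabeling). Sensitivity
and specificity are computed per planted community after matching each
planted community to the retrieved community of largest overlap
(many-to-one, ties to the smaller retrieved label), then averaged
unweighted over planted communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MembershipError
from .network import Partition


@dataclass(frozen=True)
class ConfusionTable:
    """Overlap counts N_ij between partition A's and B's communities."""

    counts: np.ndarray  # C_A x C_B
    row_sums: np.ndarray
    col_sums: np.ndarray
    total: int


@dataclass(frozen=True)
class CommunityMatch:
    planted_label: int
    matched_label: int
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[CommunityMatch, ...]


@dataclass(frozen=True)
class EvalMetrics:
    nmi: float
    sensitivity: float
    specificity: float


def _check_nodes(a: Partition, b: Partition) -> None:
    if a.n_nodes != b.n_nodes:
        raise MembershipError(
            f"partitions cover different node sets ({a.n_nodes} vs {b.n_nodes})"
        )


def confusion_table(a: Partition, b: Partition) -> ConfusionTable:
    _check_nodes(a, b)
    counts = np.zeros((a.n_communities, b.n_communities), dtype=np.int64)
    np.add.at(counts, (a.labels, b.labels), 1)
    return ConfusionTable(
        counts, counts.sum(axis=1), counts.sum(axis=0), int(a.n_nodes)
    )


def nmi(a: Partition, b: Partition) -> float:
    """Normalized mutual information between two partitions, in [0, 1]."""
    table = confusion_table(a, b)
    ca, cb = table.counts.shape
    if ca == 1 and cb == 1:
        return 1.0  # both trivial: identical single-community partitions
    n = table.total
    nij = table.counts.astype(float)
    ni = table.row_sums.astype(float)
    nj = table.col_sums.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = nij * np.log(nij * n / np.outer(ni, nj))
    num = -2.0 * np.nansum(np.where(nij > 0, terms, 0.0))
    den = float(np.sum(ni * np.log(ni / n)) + np.sum(nj * np.log(nj / n)))
    if den == 0.0:
        return 1.0
    return float(min(1.0, max(0.0, num / den)))


def match_communities(planted: Partition, retrieved: Partition) -> MatchResult:
    """Match each planted community to the retrieved community of largest
    overlap (many-to-one; ties broken toward the smaller retrieved label)
    and tabulate TP/FP/TN/FN node counts against that match."""
    table = confusion_table(planted, retrieved)
    n = table.total
    matches = []
    for i in range(table.counts.shape[0]):
        j = int(np.argmax(table.counts[i]))  # argmax takes the first maximum
        tp = int(table.counts[i, j])
        fn = int(table.row_sums[i]) - tp
        fp = int(table.col_sums[j]) - tp
        tn = n - tp - fp - fn
        matches.append(CommunityMatch(i, j, tp, fp, tn, fn))
    return MatchResult(tuple(matches))


def sensitivity_specificity(
    planted: Partition, retrieved: Partition
) -> tuple[float, float]:
    """Partition-averaged Sensitivity = TP/(TP+FN) and
    Specificity = TN/(TN+FP). TN+FP = 0 (planted community covering every
    node) yields specificity 0 for that community."""
    result = match_communities(planted, retrieved)
    sens, spec = [], []
    for m in result.matches:
        sens.append(m.tp / (m.tp + m.fn))
        spec.append(m.tn / (m.tn + m.fp) if (m.tn + m.fp) > 0 else 0.0)
    return float(np.mean(sens)), float(np.mean(spec))


def evaluate(planted: Partition, retrieved: Partition) -> EvalMetrics:
    """Bundle NMI, sensitivity and specificity for one comparison."""
    se, sp = sensitivity_specificity(planted, retrieved)
    return EvalMetrics(nmi(planted, retrieved), se, sp)
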