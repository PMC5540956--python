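"""Subject-level Pearson connectivity and Fisher-averaged group matrices.

Subject matrices are pairwise Pearson correlations between node time
series. The group matrix averages subjects in Fisher z-space
(z = atanh(r), averaged, back-transformed with tanh), the
variance-stabilizing way to average correlation coefficients. For
downstream graph analysis the group matrix is converted to a weighted
network by dropping the diagonal and discarding negative edges (percolation
and the community-detection methods operate on non-negative weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError, ShapeError
from .network import WeightedNetwork
from .simulate import TimeSeriesPanel

_CLIP = 1.0 - 1e-7  # keep atanh finite for numerically perfect correlations


@dataclass(frozen=True)
class SubjectMatrix:
    """Pearson correlation matrix of one subject's node time series."""

    matrix: np.ndarray


@dataclass(frozen=True)
class GroupMatrix:
    """Fisher-averaged group correlation matrix."""

    matrix: np.ndarray
    n_subjects_in: int


def pearson_matrix(series: np.ndarray) -> SubjectMatrix:
    """Pairwise Pearson correlations of a node x time array."""
    y = np.asarray(series, dtype=np.float64)
    if y.ndim != 2:
        raise ShapeError("series must be a 2-d node x time array")
    if y.shape[1] < 3:
        raise ParameterError("need at least 3 timepoints")
    var = y.var(axis=1)
    dead = np.nonzero(var == 0)[0]
    if dead.size:
        raise DegenerateInputError(
            f"zero-variance time series at node(s) {dead.tolist()}"
        )
    m = np.corrcoef(y)
    m = np.clip(0.5 * (m + m.T), -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return SubjectMatrix(m)


def fisher_group_average(matrices: list[SubjectMatrix]) -> GroupMatrix:
    """Average subject matrices in Fisher z-space and back-transform."""
    if not matrices:
        raise ParameterError("need at least one subject matrix")
    shape = matrices[0].matrix.shape
    for sm in matrices:
        if sm.matrix.shape != shape:
            raise ShapeError("subject matrices must share the same dimension")
    z = np.mean(
        [np.arctanh(np.clip(sm.matrix, -_CLIP, _CLIP)) for sm in matrices], axis=0
    )
    r = np.tanh(z)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return GroupMatrix(r, len(matrices))


def panel_to_group(panel: TimeSeriesPanel) -> GroupMatrix:
    """Per-subject Pearson matrices followed by Fisher group averaging."""
    return fisher_group_average(
        [pearson_matrix(panel.data[k]) for k in range(panel.n_subjects)]
    )


def group_to_network(group: GroupMatrix) -> WeightedNetwork:
    """Weighted network from a group matrix: diagonal dropped, negative
    correlations discarded."""
    a = group.matrix.copy()
    np.fill_diagonal(a, 0.0)
    a[a < 0] = 0.0
    return WeightedNetwork.from_adjacency(a)
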