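"""Nodal participation and integration/segregation measures.

Participation coefficient (PC) variants
---------------------------------------

For node i with strength k_i and within-community strengths k_is over the
communities s of a partition,

    P_i = 1 - sum_s (k_is / k_i)^2 .

P_i is 0 when all of i's strength lies in one community and approaches 1 as
strength spreads evenly over many communities.  "Degree" is weighted strength
throughout.  Applied through time, the choice of reference partition matters:

``pc_s``
    One static partition applied at every slice.  Values are directly
    comparable across time because the community context never changes.

``pc_t``
    Each slice scored against its own temporal partition.  Each value is
    correct in isolation, but values at different times are relative to
    different community contexts, so contrasting them conflates a node's own
    edge changes with changes in the surrounding community structure — e.g.
    a community splitting through *weakened* edges raises pc_t, which reads
    as increased integration.

``tpc`` (temporal participation coefficient)
    Every slice is scored against the partition of *every* time point and
    the scores averaged:

        P_it = 1 - (1/T) sum_u sum_{s in partition u} (k_its(u) / k_it)^2 .

    All time points share the same (composite) community context, restoring
    comparability across time while retaining the temporal community
    information.  Duplicate partitions count with their multiplicity, so
    recurrent community configurations weigh in proportion to their
    prevalence.  The measure presumes community configurations can recur.

Conventions: a node with zero strength at a slice gets PC 0 at that slice
(no participation); z-scores use the population standard deviation, with
singleton or zero-variance communities scored 0.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    NodalMeasureSeries,
    PartitionSequence,
    StaticPartition,
    TemporalNetwork,
    ValidationError,
)

__all__ = [
    "static_pc",
    "pc_s",
    "pc_t",
    "tpc",
    "flexibility",
    "module_degree_zscore",
]

logger = logging.getLogger(__name__)


def _check_slice(net_slice: np.ndarray) -> np.ndarray:
    sl = np.asarray(net_slice, dtype=float)
    if sl.ndim != 2 or sl.shape[0] != sl.shape[1]:
        raise ValidationError("network slice must be square")
    if np.any(sl < 0):
        raise ValidationError("PC requires nonnegative weights (threshold first)")
    return sl


def _pc_from_strengths(within: np.ndarray, total: np.ndarray) -> np.ndarray:
    """P_i = 1 - sum_s (k_is/k_i)^2, with k_i = 0 mapped to P_i = 0."""
    out = np.zeros(total.shape)
    nz = total > 0
    if np.any(~nz):
        logger.debug("%d zero-strength node(s); PC set to 0", int((~nz).sum()))
    frac = within[nz] / total[nz, None]
    out[nz] = 1.0 - np.sum(frac**2, axis=1)
    return np.clip(out, 0.0, None)


def _membership(part: StaticPartition) -> np.ndarray:
    communities = np.unique(part.labels)
    return (part.labels[:, None] == communities[None, :]).astype(float)


def static_pc(net_slice: np.ndarray, part: StaticPartition) -> np.ndarray:
    """Participation coefficient of every node for one slice and one partition."""
    sl = _check_slice(net_slice)
    if part.n_nodes != sl.shape[0]:
        raise ValidationError(
            f"partition has {part.n_nodes} nodes, network has {sl.shape[0]}"
        )
    membership = _membership(part)
    within = sl @ membership
    total = sl.sum(axis=1)
    return _pc_from_strengths(within, total)


def _require_thresholded(net: TemporalNetwork) -> None:
    if not net.thresholded:
        raise ValidationError("PC requires a thresholded (nonnegative) network")


def pc_s(net: TemporalNetwork, part: StaticPartition) -> NodalMeasureSeries:
    """PC per time point with one static community partition."""
    _require_thresholded(net)
    values = np.column_stack(
        [static_pc(net.slice(t), part) for t in range(net.n_times)]
    )
    return NodalMeasureSeries(values, "PC_S", {"partition": "static"})


def _check_aligned(net: TemporalNetwork, parts: PartitionSequence) -> None:
    if parts.n_nodes != net.n_nodes or parts.n_times != net.n_times:
        raise ValidationError(
            f"partition sequence shape {parts.labels.shape} does not match "
            f"network (N={net.n_nodes}, T={net.n_times})"
        )


def pc_t(net: TemporalNetwork, parts: PartitionSequence) -> NodalMeasureSeries:
    """PC per time point, each slice scored against its own temporal partition."""
    _require_thresholded(net)
    _check_aligned(net, parts)
    values = np.column_stack(
        [static_pc(net.slice(t), parts.at(t)) for t in range(net.n_times)]
    )
    return NodalMeasureSeries(values, "PC_T", {"partition": "temporal"})


def tpc(net: TemporalNetwork, parts: PartitionSequence) -> NodalMeasureSeries:
    """Temporal participation coefficient.

    Each slice t is scored against the partition of every time point u and
    the T scores averaged, so every value shares the same composite
    community context.  Equals ``pc_s`` and ``pc_t`` exactly when the
    partition sequence is constant in time.
    """
    _require_thresholded(net)
    _check_aligned(net, parts)
    n, _, t_len = net.weights.shape
    total = net.weights.sum(axis=1)  # (N, T) strengths k_it
    nz = total > 0
    sum_sq = np.zeros((n, t_len))  # accumulates sum_u sum_s (k_its(u))^2
    for u in range(t_len):
        membership = _membership(parts.at(u))  # (N, K_u)
        # within[i, s, t] = k_its under partition u
        within = np.tensordot(net.weights, membership, axes=([1], [0]))
        within = np.swapaxes(within, 1, 2)  # (N, K_u, T)
        sum_sq += np.sum(within**2, axis=1)
    values = np.zeros((n, t_len))
    values[nz] = 1.0 - sum_sq[nz] / (t_len * total[nz] ** 2)
    values = np.clip(values, 0.0, None)
    return NodalMeasureSeries(values, "TPC", {"partition": "temporal, all u"})


def flexibility(parts: PartitionSequence) -> np.ndarray:
    """Fraction of consecutive time steps at which a node changes community.

    Requires consensus-relabeled input (labels comparable across slices).
    """
    if parts.n_times < 2:
        raise ValidationError("flexibility needs T >= 2")
    changes = parts.labels[:, 1:] != parts.labels[:, :-1]
    return changes.sum(axis=1) / (parts.n_times - 1)


def _zscore_slice(net_slice: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Within-module degree z-score for one slice under one labeling."""
    n = net_slice.shape[0]
    z = np.zeros(n)
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size < 2:
            continue  # singleton community: z = 0 by convention
        within = net_slice[np.ix_(members, members)].sum(axis=1)
        sd = within.std()  # population std
        if sd == 0:
            continue
        z[members] = (within - within.mean()) / sd
    return z


def module_degree_zscore(
    net: TemporalNetwork, part: StaticPartition | PartitionSequence
) -> NodalMeasureSeries:
    """Within-module degree z-score through time.

    With a static partition the same labeling scores every slice (z_S, the
    companion of pc_s); with a partition sequence each slice is scored under
    its own labeling (z_T, the companion of pc_t).
    """
    _require_thresholded(net)
    if isinstance(part, PartitionSequence):
        _check_aligned(net, part)
        name = "z_T"
        labels_at = lambda t: part.labels[:, t]  # noqa: E731
    else:
        if part.n_nodes != net.n_nodes:
            raise ValidationError("partition length must equal N")
        name = "z_S"
        labels_at = lambda t: part.labels  # noqa: E731
    values = np.column_stack(
        [_zscore_slice(net.slice(t), labels_at(t)) for t in range(net.n_times)]
    )
    return NodalMeasureSeries(values, name, {"partition": name})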