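"""Community detection and temporal consensus relabeling.

Static and per-slice community structure is found by modularity maximization
(Louvain, via networkx) on nonnegative weighted graphs.  Slice-wise
partitions carry arbitrary label alphabets; :func:`temporal_consensus`
relabels them so that a community keeps the same integer label for as long
as it persists, matching communities in consecutive slices by smallest
Jaccard distance between their node sets.  Consensus changes labels only —
never which nodes are grouped together.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .core import (
    PartitionSequence,
    StaticPartition,
    TemporalNetwork,
    ValidationError,
    densify_labels,
)

__all__ = [
    "detect_static_communities",
    "detect_slice_communities",
    "temporal_consensus",
    "jaccard_distance",
]

logger = logging.getLogger(__name__)


def _louvain_labels(adj: np.ndarray, resolution: float, seed: int) -> np.ndarray:
    """Louvain partition of a nonnegative symmetric matrix as dense labels.

    Zero-weight edges are dropped; isolated nodes become singletons.  Label
    order follows each community's smallest member node id, so the output is
    independent of the order networkx returns communities in.
    """
    n = adj.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(adj, 1))
    g.add_weighted_edges_from(
        (int(a), int(b), float(adj[a, b])) for a, b in zip(ii, jj)
    )
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(n, dtype=np.int64)
    for k, members in enumerate(comms):
        labels[members] = k
    return labels


def detect_static_communities(
    mean_net: np.ndarray, resolution: float = 1.0, seed: int = 0
) -> StaticPartition:
    """Modularity partition of a time-averaged (static) connectivity matrix."""
    adj = np.asarray(mean_net, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValidationError("static network must be square")
    if not np.allclose(adj, adj.T, rtol=0.0, atol=1e-12):
        raise ValidationError("static network must be symmetric")
    if np.any(adj < 0):
        raise ValidationError("static network must be nonnegative (threshold first)")
    if np.any(np.diagonal(adj) != 0):
        raise ValidationError("static network must have a zero diagonal")
    if not np.any(adj):
        raise ValidationError("static network has no edges")
    return StaticPartition(_louvain_labels(adj, resolution, seed))


def detect_slice_communities(
    net: TemporalNetwork, resolution: float = 1.0, seed: int = 0
) -> PartitionSequence:
    """Independent modularity partition of every temporal slice.

    Labels are arbitrary per slice (run :func:`temporal_consensus` to make
    them comparable across time).  Per-slice seeds are spawned
    deterministically from ``seed``.  An all-zero slice yields one singleton
    community per node, with a logged warning.
    """
    if not net.thresholded:
        raise ValidationError("slice community detection requires a thresholded network")
    n, _, t = net.weights.shape
    slice_seeds = np.random.SeedSequence(seed).generate_state(t) % (2**31)
    labels = np.empty((n, t), dtype=np.int64)
    for k in range(t):
        sl = net.weights[:, :, k]
        if not np.any(sl):
            logger.warning("slice %d has no edges; assigning singleton communities", k)
            labels[:, k] = np.arange(n)
        else:
            labels[:, k] = _louvain_labels(sl, resolution, int(slice_seeds[k]))
    return PartitionSequence(labels)


def jaccard_distance(a: frozenset, b: frozenset) -> float:
    """1 - |A intersect B| / |A union B| for two node sets."""
    inter = len(a & b)
    if inter == 0:
        return 1.0
    return 1.0 - inter / len(a | b)


def _slice_communities(labels: np.ndarray) -> dict:
    """Map label -> frozenset of member node indices for one slice."""
    out: dict = {}
    for node, lab in enumerate(labels):
        out.setdefault(int(lab), set()).add(node)
    return {lab: frozenset(m) for lab, m in out.items()}


def temporal_consensus(parts: PartitionSequence) -> PartitionSequence:
    """Relabel slice-wise partitions so communities keep their label over time.

    Sweeping forward from the second slice, each community is matched
    one-to-one to the community of the (already relabeled) previous slice
    with the smallest Jaccard distance between their node sets, in ascending
    distance order; ties break by the smallest member node id of the current
    community, then of the candidate previous community.  A match requires
    at least one shared node (distance < 1); a community that matches
    nothing gets a fresh label never used before.  Node memberships are
    never altered, so the partition structure at every slice is preserved
    exactly, and the sweep is idempotent.
    """
    labels = parts.labels
    n, t = labels.shape
    out = np.empty_like(labels)
    out[:, 0] = densify_labels(labels[:, 0].tolist())
    next_fresh = int(out[:, 0].max()) + 1
    prev = _slice_communities(out[:, 0])
    for k in range(1, t):
        cur = _slice_communities(labels[:, k])
        candidates = []
        for cur_lab, cur_members in cur.items():
            for prev_lab, prev_members in prev.items():
                d = jaccard_distance(cur_members, prev_members)
                if d < 1.0:
                    candidates.append(
                        (d, min(cur_members), min(prev_members), cur_lab, prev_lab)
                    )
        candidates.sort()
        mapping: dict = {}
        used_prev: set = set()
        for d, _, _, cur_lab, prev_lab in candidates:
            if cur_lab in mapping or prev_lab in used_prev:
                continue
            mapping[cur_lab] = prev_lab
            used_prev.add(prev_lab)
        # Fresh labels for unmatched communities, in smallest-member order.
        unmatched = sorted(
            (lab for lab in cur if lab not in mapping),
            key=lambda lab: min(cur[lab]),
        )
        for lab in unmatched:
            mapping[lab] = next_fresh
            next_fresh += 1
        out[:, k] = [mapping[int(lab)] for lab in labels[:, k]]
        prev = {mapping[lab]: members for lab, members in cur.items()}
    return PartitionSequence(out)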