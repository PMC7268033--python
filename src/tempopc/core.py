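"""Domain types and file formats for temporal-network participation analysis.

The central objects are a node-by-time signal matrix (:class:`NodeTimeSeries`),
a stack of weighted undirected connectivity snapshots
(:class:`TemporalNetwork`), and community partitions, either a single static
labeling (:class:`StaticPartition`) or one labeling per snapshot
(:class:`PartitionSequence`).

All node and time indices are 0-based, in memory and on disk.  Networks are
undirected and weighted with a zero diagonal; each time slice must be
symmetric.  File formats are plain text: CSV/TSV node-by-time matrices for
signals, measures and partitions, and a 4-column TSV edge list
``(i, j, t, weight)`` for temporal networks.  Writers prepend a ``#`` header
comment carrying the format version.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

FORMAT_VERSION = "tempopc-format-v1"

__all__ = [
    "NodeTimeSeries",
    "TemporalNetwork",
    "StaticPartition",
    "PartitionSequence",
    "CommunityStrengthProfile",
    "NodalMeasureSeries",
    "ValidationError",
    "ParseError",
    "threshold_negative_edges",
    "community_strengths",
    "read_timeseries",
    "write_timeseries",
    "read_temporal_edgelist",
    "write_temporal_edgelist",
    "read_partition",
    "write_partition",
    "densify_labels",
]


class ValidationError(ValueError):
    """An object violates a domain-type invariant."""


class ParseError(ValueError):
    """An on-disk file violates its format contract."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeTimeSeries:
    """N-node by T-timepoint signal matrix (e.g. parcellated BOLD signals).

    Parameters
    ----------
    values
        Real matrix of shape (N, T), all finite, N >= 2 and T >= 2.
    node_ids
        Unique, ordered node identifiers; defaults to ``0..N-1`` as strings.
    """

    values: np.ndarray
    node_ids: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        values = _as_float_array(self.values, "time series")
        if values.ndim != 2:
            raise ValidationError("time series must be a 2-D node x time matrix")
        n, t = values.shape
        if n < 2 or t < 2:
            raise ValidationError(f"need N >= 2 and T >= 2, got N={n}, T={t}")
        ids = self.node_ids
        if ids is None:
            ids = tuple(str(i) for i in range(n))
        else:
            ids = tuple(str(i) for i in ids)
        if len(ids) != n:
            raise ValidationError(f"{len(ids)} node ids for {n} nodes")
        if len(set(ids)) != n:
            raise ValidationError("node ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TemporalNetwork:
    """Weighted undirected connectivity snapshots: an N x N x T weight stack.

    Every time slice is symmetric with a zero diagonal.  ``thresholded``
    records that negative edges have been removed (a prerequisite for
    modularity community detection and the participation coefficient).
    """

    weights: np.ndarray
    node_ids: tuple = None  # type: ignore[assignment]
    thresholded: bool = False

    def __post_init__(self):
        w = _as_float_array(self.weights, "network weights")
        if w.ndim != 3 or w.shape[0] != w.shape[1]:
            raise ValidationError("weights must have shape (N, N, T)")
        n = w.shape[0]
        if n < 2:
            raise ValidationError("need at least 2 nodes")
        for t in range(w.shape[2]):
            sl = w[:, :, t]
            if not np.allclose(sl, sl.T, rtol=0.0, atol=1e-12):
                raise ValidationError(f"slice {t} is not symmetric")
            if np.any(np.diagonal(sl) != 0):
                raise ValidationError(f"slice {t} has a nonzero diagonal")
        if self.thresholded and np.any(w < 0):
            raise ValidationError("thresholded network has negative weights")
        ids = self.node_ids
        if ids is None:
            ids = tuple(str(i) for i in range(n))
        else:
            ids = tuple(str(i) for i in ids)
        if len(ids) != n or len(set(ids)) != n:
            raise ValidationError("node ids must be unique and match N")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_times(self) -> int:
        return self.weights.shape[2]

    def slice(self, t: int) -> np.ndarray:
        return self.weights[:, :, t]


def _validate_labels(labels: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if not np.issubdtype(arr.dtype, np.integer):
        flo = np.asarray(labels, dtype=float)
        if np.any(~np.isfinite(flo)) or np.any(flo != np.round(flo)):
            raise ValidationError(f"{name} labels must be integers")
        arr = flo.astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValidationError(f"{name} labels must be nonnegative")
    return arr


@dataclass(frozen=True)
class StaticPartition:
    """One community label per node, from time-averaged connectivity."""

    labels: np.ndarray

    def __post_init__(self):
        arr = _validate_labels(self.labels, "static partition")
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("static partition must be a nonempty 1-D vector")
        object.__setattr__(self, "labels", arr)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_communities(self) -> int:
        return np.unique(self.labels).size


@dataclass(frozen=True)
class PartitionSequence:
    """Community label of every node at every time point (N x T).

    Labels are only comparable across time after temporal consensus
    relabeling (see :func:`tempopc.communities.temporal_consensus`), which
    makes a given integer denote the "same" community at different slices.
    """

    labels: np.ndarray

    def __post_init__(self):
        arr = _validate_labels(self.labels, "partition sequence")
        if arr.ndim != 2:
            raise ValidationError("partition sequence must be a 2-D node x time matrix")
        object.__setattr__(self, "labels", arr)

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_times(self) -> int:
        return self.labels.shape[1]

    def at(self, t: int) -> StaticPartition:
        return StaticPartition(self.labels[:, t])

    def n_communities_at(self, t: int) -> int:
        return np.unique(self.labels[:, t]).size


@dataclass(frozen=True)
class CommunityStrengthProfile:
    """Within-community strengths of every node at one slice.

    ``within`` has shape (N, K): entry (i, s) is node i's summed edge weight
    to members of community s.  ``total`` is node strength k_it; for any full
    partition the rows of ``within`` sum exactly to ``total``.
    """

    within: np.ndarray
    total: np.ndarray
    community_labels: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.within.sum(axis=1), self.total, rtol=0.0, atol=1e-9):
            raise ValidationError("within-community strengths do not sum to total strength")


@dataclass(frozen=True)
class NodalMeasureSeries:
    """Node-by-time values of one nodal measure with its provenance."""

    values: np.ndarray
    measure_name: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        values = _as_float_array(self.values, f"{self.measure_name} values")
        if values.ndim != 2:
            raise ValidationError("measure values must be node x time")
        object.__setattr__(self, "values", values)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def threshold_negative_edges(net: TemporalNetwork) -> TemporalNetwork:
    """Set strictly negative edge weights to zero.

    Standard preprocessing before modularity community detection and the
    participation coefficient, which are defined on nonnegative weights.
    Idempotent; the input network is not modified.
    """
    w = np.where(net.weights < 0, 0.0, net.weights)
    return TemporalNetwork(w, node_ids=net.node_ids, thresholded=True)


def community_strengths(
    net_slice: np.ndarray, partition: StaticPartition
) -> CommunityStrengthProfile:
    """Per-community strength profile of one network slice under a partition."""
    net_slice = np.asarray(net_slice, dtype=float)
    n = net_slice.shape[0]
    if partition.n_nodes != n:
        raise ValidationError(
            f"partition has {partition.n_nodes} nodes, slice has {n}"
        )
    communities = np.unique(partition.labels)
    membership = (partition.labels[:, None] == communities[None, :]).astype(float)
    within = net_slice @ membership  # (N, K)
    total = net_slice.sum(axis=1)
    return CommunityStrengthProfile(within=within, total=total, community_labels=communities)


def densify_labels(raw: Sequence) -> np.ndarray:
    """Re-encode arbitrary labels to dense 0-based ints, by first appearance."""
    seen: dict = {}
    out = np.empty(len(raw), dtype=np.int64)
    for i, lab in enumerate(raw):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_file(path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, comment="#", header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ParseError(f"{path}: ragged or missing cells at row {row}")
    return df


def _strip_header_row(df: pd.DataFrame) -> pd.DataFrame:
    # Optional header row: first cell empty or literally "node", remaining
    # cells the consecutive time indices 0..T-1.
    first_cell = str(df.iloc[0, 0]).strip().lower()
    if first_cell not in ("node", "node_id", "id"):
        return df
    try:
        idx = [int(v) for v in df.iloc[0, 1:]]
    except ValueError as exc:
        raise ParseError(f"header row is not numeric time indices: {exc}") from exc
    if idx != list(range(len(idx))):
        raise ParseError("header time indices must be 0..T-1")
    return df.iloc[1:].reset_index(drop=True)


def read_timeseries(path, format: str = "csv") -> NodeTimeSeries:
    """Read a node-by-time signal matrix from CSV or TSV.

    First column holds node ids; an optional header row carries 0-based time
    indices.  Lines starting with ``#`` are comments.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ParseError(f"unknown time-series format {format!r}")
    df = _strip_header_row(_read_matrix_file(path, sep))
    ids = [str(v) for v in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ParseError(f"{path}: duplicate node id {dup!r}")
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    return NodeTimeSeries(values, node_ids=ids)


def write_timeseries(ts: NodeTimeSeries, path, format: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[format]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} timeseries\n")
        for i, nid in enumerate(ts.node_ids):
            row = sep.join(repr(float(v)) for v in ts.values[i])
            fh.write(f"{nid}{sep}{row}\n")


def read_temporal_edgelist(path) -> TemporalNetwork:
    """Read a temporal network from a 4-column TSV edge list (i, j, t, weight).

    Indices are 0-based; edges are undirected and may be stored in either
    orientation (or both, if the weights agree).  Absent triples are weight 0.
    """
    df = _read_matrix_file(path, "\t")
    if df.shape[1] != 4:
        raise ParseError(f"{path}: expected 4 columns (i, j, t, weight), got {df.shape[1]}")
    try:
        i = df.iloc[:, 0].astype(int).to_numpy()
        j = df.iloc[:, 1].astype(int).to_numpy()
        t = df.iloc[:, 2].astype(int).to_numpy()
        w = df.iloc[:, 3].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    if np.any(i < 0) or np.any(j < 0) or np.any(t < 0):
        raise ParseError(f"{path}: negative index")
    if np.any(i == j):
        row = int(np.argmax(i == j))
        raise ParseError(f"{path}: self-loop at row {row}")
    n = int(max(i.max(), j.max())) + 1
    nt = int(t.max()) + 1
    weights = np.zeros((n, n, nt))
    seen: dict = {}
    for row, (a, b, tt, ww) in enumerate(zip(i, j, t, w)):
        key = (min(a, b), max(a, b), tt)
        if key in seen:
            if seen[key] != ww:
                raise ParseError(
                    f"{path}: conflicting weights for edge {key} at row {row}"
                )
            continue
        seen[key] = ww
        weights[a, b, tt] = ww
        weights[b, a, tt] = ww
    return TemporalNetwork(weights, thresholded=bool(np.all(weights >= 0)))


def write_temporal_edgelist(net: TemporalNetwork, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} temporal-edgelist\ti\tj\tt\tweight\n")
        n, _, nt = net.weights.shape
        for t in range(nt):
            sl = net.weights[:, :, t]
            ii, jj = np.nonzero(np.triu(sl, 1))
            for a, b in zip(ii, jj):
                fh.write(f"{a}\t{b}\t{t}\t{float(sl[a, b])!r}\n")


Partition = Union[StaticPartition, PartitionSequence]


def read_partition(path) -> Partition:
    """Read community labels from CSV: rows are nodes, columns are time points.

    A single column yields a :class:`StaticPartition`.  Labels are re-encoded
    to dense nonnegative integers in order of first appearance (row-major),
    so the label alphabet of the source file does not matter.
    """
    df = _read_matrix_file(path, ",")
    raw = df.to_numpy()
    flat = densify_labels([v for row in raw for v in row])
    labels = flat.reshape(raw.shape)
    if labels.shape[1] == 1:
        return StaticPartition(labels[:, 0])
    return PartitionSequence(labels)


def write_partition(part: Partition, path) -> None:
    path = Path(path)
    labels = part.labels if isinstance(part, PartitionSequence) else part.labels[:, None]
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} partition\n")
        for row in labels:
            fh.write(",".join(str(int(v)) for v in row) + "\n")
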