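"""Synthetic data: toy two-snapshot scenarios and recurring-state time series.

The toy scenarios are small hand-built temporal networks (two snapshots
each) in which a community merges, splits, extends, or absorbs a focal node
between the snapshots.  Each scenario plants its per-slice community
partitions and a static partition, and declares the expected *direction* of
change of each participation measure for the focal node — the directions,
not the magnitudes, are the scenario's contract, since they follow from the
topology change alone.  Two edge-weight levels (strong 1.0, weak 0.5 or
0.1-0.25) are used throughout.

The recurring-state generator emulates parcellated resting-state-like
signals: piecewise-stationary epochs, each drawn from a multivariate normal
whose correlation matrix has the block structure of one of K community
"states", with states recurring cyclically.  Recurrence is the regime the
temporal participation coefficient presumes, so this generator is the
package's stand-in for empirical multi-run recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    NodeTimeSeries,
    PartitionSequence,
    StaticPartition,
    TemporalNetwork,
    ValidationError,
)

__all__ = [
    "ToyScenario",
    "RecurringStateSpec",
    "make_toy",
    "TOY_NAMES",
    "generate_recurring_timeseries",
    "generate_random_temporal_network",
    "generate_random_partition_sequence",
]


@dataclass(frozen=True)
class ToyScenario:
    """A two-snapshot toy network with planted partitions and expected signs.

    ``expected_signs`` maps measure name ('pc_s', 'pc_t', 'tpc') to the
    expected direction ('+', '-', '0') of the focal node's change from the
    first to the second snapshot.
    """

    name: str
    network: TemporalNetwork
    planted_partitions: PartitionSequence
    static_partition: StaticPartition
    focal_node: int
    expected_signs: dict = field(default_factory=dict)
    description: str = ""


def _stack(n: int, edges_t1: dict, edges_t2: dict) -> TemporalNetwork:
    w = np.zeros((n, n, 2))
    for t, edges in enumerate((edges_t1, edges_t2)):
        for (i, j), weight in edges.items():
            w[i, j, t] = w[j, i, t] = weight
    return TemporalNetwork(w, thresholded=True)


def _clique(nodes, weight=1.0) -> dict:
    return {
        (a, b): weight for idx, a in enumerate(nodes) for b in nodes[idx + 1 :]
    }


def _make_fig1b() -> ToyScenario:
    # Static community template; the focal node's edges spread evenly over
    # all three communities at the second snapshot -> participation rises.
    base = {}
    for comm in ([0, 1, 2], [3, 4, 5], [6, 7, 8]):
        base.update(_clique(comm))
    t1 = dict(base)
    t1.update({(0, 3): 0.5, (0, 6): 0.5})
    t2 = dict(base)
    del t2[(0, 2)]
    t2.update({(0, 3): 1.0, (0, 6): 1.0})
    labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
    return ToyScenario(
        name="fig1b",
        network=_stack(9, t1, t2),
        planted_partitions=PartitionSequence(np.column_stack([labels, labels])),
        static_partition=StaticPartition(labels),
        focal_node=0,
        expected_signs={"pc_s": "+", "pc_t": "+", "tpc": "+"},
        description="even spread of the focal node's edges under a fixed partition",
    )


def _make_fig1c() -> ToyScenario:
    # The focal node strengthens its edge toward the blue community and is
    # absorbed into it -- per-slice PC with temporal communities *drops*
    # even though the edge it grew points across the original boundary.
    t1 = {(0, 1): 1.0, (2, 3): 1.0, (0, 2): 0.8}
    t2 = {(0, 1): 1.0, (2, 3): 1.0, (0, 2): 2.0}
    p1 = np.array([0, 0, 1, 1])
    p2 = np.array([1, 0, 1, 1])  # focal node absorbed into the blue community
    return ToyScenario(
        name="fig1c",
        network=_stack(4, t1, t2),
        planted_partitions=PartitionSequence(np.column_stack([p1, p2])),
        static_partition=StaticPartition(p1),
        focal_node=0,
        expected_signs={"pc_t": "-"},
        description="absorption into the community the node strengthened toward",
    )


def _make_fig1d() -> ToyScenario:
    # The focal node's own edges are identical in both snapshots; the blue
    # community splits through changes among *other* nodes, which still
    # moves the focal node's per-slice temporal-community PC.
    focal = {(0, 1): 1.0, (0, 2): 0.5, (0, 3): 0.5}
    t1 = dict(focal)
    t1.update(_clique([2, 3, 4, 5]))
    t2 = dict(focal)
    t2.update({(2, 4): 1.0, (3, 5): 1.0,
               (2, 3): 0.1, (2, 5): 0.1, (3, 4): 0.1, (4, 5): 0.1})
    p1 = np.array([0, 0, 1, 1, 1, 1])
    p2 = np.array([0, 0, 1, 2, 1, 2])
    return ToyScenario(
        name="fig1d",
        network=_stack(6, t1, t2),
        planted_partitions=PartitionSequence(np.column_stack([p1, p2])),
        static_partition=StaticPartition(p1),
        focal_node=0,
        expected_signs={"pc_t": "+", "pc_s": "0"},
        description="partition change driven entirely by edges not touching the focal node",
    )


def _split_family(extend: bool) -> ToyScenario:
    # Blue community {0,1,2,3} with halves {0,1} and {2,3}; cross-half edges
    # weaken (split) or strengthen (extend) between the snapshots.  The
    # static partition resolves the halves; the temporal partition merges
    # them whenever the cross-half edges are strong.
    cross_strong, cross_weak = 0.5, 0.1
    w1, w2 = (cross_strong, cross_weak) if not extend else (cross_weak, cross_strong)
    base = {(0, 1): 1.0, (2, 3): 1.0, (4, 5): 1.0, (3, 4): 0.2}
    t1 = dict(base)
    t1.update({(a, b): w1 for a in (0, 1) for b in (2, 3)})
    t2 = dict(base)
    t2.update({(a, b): w2 for a in (0, 1) for b in (2, 3)})
    merged = np.array([0, 0, 0, 0, 1, 1])
    split = np.array([0, 0, 1, 1, 2, 2])
    p1, p2 = (merged, split) if not extend else (split, merged)
    if extend:
        signs = {"pc_t": "-", "pc_s": "+", "tpc": "+"}
    else:
        signs = {"pc_t": "+", "pc_s": "-", "tpc": "-"}
    return ToyScenario(
        name="fig2_extend" if extend else "fig2_split",
        network=_stack(6, t1, t2),
        planted_partitions=PartitionSequence(np.column_stack([p1, p2])),
        static_partition=StaticPartition(split),
        focal_node=0,
        expected_signs=signs,
        description=(
            "community extension through strengthened edges"
            if extend
            else "community split through weakened edges"
        ),
    )


def _make_fig3() -> ToyScenario:
    # The averaged-context fix: the focal node spreads its strength evenly
    # across the boundary at the second snapshot and is absorbed; scored
    # against *both* community contexts and averaged, its participation
    # rises -- the same community contexts back every estimate.
    t1 = {(0, 1): 1.0, (2, 3): 1.0, (0, 2): 0.25}
    t2 = {(0, 1): 1.0, (2, 3): 1.0, (0, 2): 1.0}
    p1 = np.array([0, 0, 1, 1])
    p2 = np.array([1, 0, 1, 1])
    return ToyScenario(
        name="fig3",
        network=_stack(4, t1, t2),
        planted_partitions=PartitionSequence(np.column_stack([p1, p2])),
        static_partition=StaticPartition(p1),
        focal_node=0,
        expected_signs={"tpc": "+", "pc_s": "+"},
        description="averaging over all community contexts restores comparability",
    )


_TOY_BUILDERS = {
    "fig1b": _make_fig1b,
    "fig1c": _make_fig1c,
    "fig1d": _make_fig1d,
    "fig2_split": lambda: _split_family(extend=False),
    "fig2_extend": lambda: _split_family(extend=True),
    "fig3": _make_fig3,
}

TOY_NAMES = tuple(sorted(_TOY_BUILDERS))


def make_toy(name: str) -> ToyScenario:
    """Build one of the named two-snapshot toy scenarios."""
    try:
        return _TOY_BUILDERS[name]()
    except KeyError:
        raise ValidationError(
            f"unknown toy scenario {name!r}; choose from {TOY_NAMES}"
        ) from None


# ---------------------------------------------------------------------------
# Recurring-state time-series generator
# ---------------------------------------------------------------------------


def _default_states(n_nodes: int, k_states: int) -> tuple:
    """K phase-shifted balanced bipartitions of the node set.

    State s labels node i by whether ``(i + s * N/(2K)) mod N`` falls in the
    first half, so consecutive states regroup a fraction of the nodes while
    every state stays a 50/50 split.
    """
    half = n_nodes // 2
    idx = np.arange(n_nodes)
    return tuple(
        (((idx + s * half // k_states) % n_nodes) < half).astype(np.int64)
        for s in range(k_states)
    )


@dataclass(frozen=True)
class RecurringStateSpec:
    """Parameters of the piecewise-stationary recurring-state generator.

    Defaults describe a parcellated resting-state-like recording at desk
    scale: 40 nodes, 200 time points, two community states alternating in
    epochs of 50 time points (so each state occurs twice — the recurrence
    the temporal participation coefficient presumes), within-block
    correlation 0.6 against between-block 0.05, temporal autocorrelation
    0.8 (hemodynamic-like signals are smooth in time, which is what lets
    distance-based estimation weights find supporting time points), and
    additive sensor noise with standard deviation 0.1.
    """

    n_nodes: int = 40
    n_times: int = 200
    epoch_length: int = 50
    states: tuple = None  # type: ignore[assignment]
    within_corr: float = 0.6
    between_corr: float = 0.05
    ar_coeff: float = 0.8
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_times % self.epoch_length != 0:
            raise ValidationError("epoch_length must tile n_times")
        states = self.states
        if states is None:
            states = _default_states(self.n_nodes, 2)
        states = tuple(np.asarray(s, dtype=np.int64) for s in states)
        for s in states:
            if s.shape != (self.n_nodes,):
                raise ValidationError("each state must label every node")
        n_epochs = self.n_times // self.epoch_length
        if n_epochs < 2 * len(states):
            raise ValidationError(
                f"{n_epochs} epochs cannot let {len(states)} states recur twice each"
            )
        if not (-1 < self.between_corr < self.within_corr < 1):
            raise ValidationError("need -1 < between_corr < within_corr < 1")
        if not 0 <= self.ar_coeff < 1:
            raise ValidationError("ar_coeff must be in [0, 1)")
        object.__setattr__(self, "states", states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def epoch_state(self, epoch: int) -> int:
        return epoch % self.n_states

    def planted_partition_sequence(self) -> PartitionSequence:
        """The block labels each time point was generated under (N x T)."""
        labels = np.empty((self.n_nodes, self.n_times), dtype=np.int64)
        for e in range(self.n_times // self.epoch_length):
            sl = slice(e * self.epoch_length, (e + 1) * self.epoch_length)
            labels[:, sl] = self.states[self.epoch_state(e)][:, None]
        return PartitionSequence(labels)


def _state_correlation(spec: RecurringStateSpec, state: np.ndarray) -> np.ndarray:
    same = state[:, None] == state[None, :]
    corr = np.where(same, spec.within_corr, spec.between_corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_recurring_timeseries(spec: RecurringStateSpec) -> NodeTimeSeries:
    """Sample a node-by-time signal matrix with recurring block correlation.

    Within each epoch, latent samples are drawn from a zero-mean
    multivariate normal whose correlation matrix carries the epoch state's
    block structure, with stationary AR(1) temporal smoothing of coefficient
    ``spec.ar_coeff`` (smoothing acts on the latent innovations, so the
    cross-node correlation structure is preserved exactly); independent
    Gaussian noise of sd ``spec.noise_sd`` is added on top.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    chols = []
    for state in spec.states:
        corr = _state_correlation(spec, state)
        try:
            chols.append(np.linalg.cholesky(corr))
        except np.linalg.LinAlgError:
            raise ValidationError(
                "state correlation matrix is not positive definite; "
                "reduce the within/between contrast"
            ) from None
    values = np.empty((spec.n_nodes, spec.n_times))
    phi = spec.ar_coeff
    innov_scale = np.sqrt(1.0 - phi**2)
    for e in range(spec.n_times // spec.epoch_length):
        z = rng.standard_normal((spec.n_nodes, spec.epoch_length))
        if phi > 0:
            for t in range(1, spec.epoch_length):
                z[:, t] = phi * z[:, t - 1] + innov_scale * z[:, t]
        values[:, e * spec.epoch_length : (e + 1) * spec.epoch_length] = (
            chols[spec.epoch_state(e)] @ z
        )
    if spec.noise_sd > 0:
        values += spec.noise_sd * rng.standard_normal(values.shape)
    return NodeTimeSeries(values)


def generate_random_temporal_network(
    n_nodes: int, n_times: int, density: float, seed: int = 0
) -> TemporalNetwork:
    """Random nonnegative symmetric snapshots for property-based tests."""
    if not 0 < density <= 1:
        raise ValidationError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    w = np.zeros((n_nodes, n_nodes, n_times))
    iu = np.triu_indices(n_nodes, 1)
    for t in range(n_times):
        present = rng.random(iu[0].size) < density
        weights = rng.uniform(0.05, 1.0, size=iu[0].size) * present
        sl = np.zeros((n_nodes, n_nodes))
        sl[iu] = weights
        w[:, :, t] = sl + sl.T
    return TemporalNetwork(w, thresholded=True)


def generate_random_partition_sequence(
    n_nodes: int, n_times: int, max_communities: int = 4, seed: int = 0
) -> PartitionSequence:
    """Random label matrix with 1..max_communities communities per slice."""
    rng = np.random.default_rng(seed)
    labels = np.empty((n_nodes, n_times), dtype=np.int64)
    for t in range(n_times):
        k = int(rng.integers(1, max_communities + 1))
        labels[:, t] = rng.integers(0, k, size=n_nodes)
    return PartitionSequence(labels)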