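"""Divergence diagnostics between participation-coefficient methods.

Given aligned node-by-time series of PC_S, PC_T and TPC (plus the companion
within-module z-scores), these diagnostics quantify how much the methods
disagree: per-node rank correlations of the time series, overlap of
top-percentile "temporal hub" selections, a sign-quadrant analysis of
(PC_T - PC_S) against (z_T - z_S), heteroscedasticity of one method against
another, and the correlation of time-averaged PC across nodes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import NodalMeasureSeries, ValidationError

__all__ = [
    "OverlapReport",
    "QuadrantReport",
    "nodewise_correlation",
    "hub_overlap",
    "quadrant_analysis",
    "heteroscedasticity_test",
    "mean_over_time_correlation",
]


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, NodalMeasureSeries) else np.asarray(series, dtype=float)


def _check_same_shape(arrays) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValidationError(f"series shapes differ: {sorted(shapes)}")


@dataclass(frozen=True)
class OverlapReport:
    """Intersection fractions of top-percentile selections between methods.

    ``fractions`` maps a sorted tuple of method names (pairs and the full
    set) to the fraction of selected (node, time) points shared by all
    methods in the subset.  The triple intersection can never exceed any
    pairwise one.
    """

    threshold_pct: float
    mode: str
    fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        for subset, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0 + 1e-12:
                raise ValidationError(f"overlap fraction for {subset} outside [0,1]")


@dataclass(frozen=True)
class QuadrantReport:
    """Sign-quadrant fractions of (PC_T - PC_S) versus (z_T - z_S).

    Keys of ``fractions`` are sign pairs like ``('+', '-')`` for
    (delta PC, delta z).  ``discordant`` sums the two opposite-sign quadrants
    in which the static and temporal pipelines give opposite
    integration/segregation readings of the same (node, time) point.
    Points falling exactly on an axis are excluded and reported in
    ``on_axis``.
    """

    fractions: dict
    discordant: float
    on_axis: float


def nodewise_correlation(
    a, b, method: str = "spearman"
) -> np.ndarray:
    """Per-node correlation of two measure time series.

    Returns an N-vector of correlations across time (Spearman rank by
    default, with average ranks for ties).  Nodes whose series is constant
    in either input have no defined correlation and are returned as NaN.
    """
    av, bv = _values(a), _values(b)
    _check_same_shape([av, bv])
    if av.shape[1] < 3:
        raise ValidationError("nodewise correlation needs T >= 3")
    func = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}.get(method)
    if func is None:
        raise ValidationError(f"unknown correlation method {method!r}")
    out = np.full(av.shape[0], np.nan)
    for i in range(av.shape[0]):
        if np.ptp(av[i]) == 0 or np.ptp(bv[i]) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[i] = func(av[i], bv[i]).statistic
    return out


def _top_indices(values: np.ndarray, m: int, order_keys) -> set:
    """Indices of the m largest values; cutoff ties broken by ``order_keys``."""
    order = np.lexsort(order_keys + (-values,))
    return set(order[:m].tolist())


def _selection_size(count: int, pct: float) -> int:
    """ceil(pct% of count), robust to binary-float edge cases like 20% of 240."""
    return max(1, math.ceil(pct * count / 100.0 - 1e-9))


def hub_overlap(series_by_method: dict, pct: float, mode: str = "per_node") -> OverlapReport:
    """Overlap of top-``pct``% "temporal hub" selections between methods.

    ``per_node`` selects, for each node separately, its top pct% of time
    points per method and averages the per-node intersection fractions;
    ``pooled`` selects the top pct% over all (node, time) points at once.
    The selection size is ceil(pct% of the candidate count); exact ties at
    the cutoff resolve to the earliest time, then the lowest node id.
    """
    if not 0 < pct < 100:
        raise ValidationError("pct must be in (0, 100)")
    if mode not in ("per_node", "pooled"):
        raise ValidationError(f"unknown mode {mode!r}")
    names = sorted(series_by_method)
    if len(names) < 2:
        raise ValidationError("need at least two methods")
    mats = {k: _values(v) for k, v in series_by_method.items()}
    _check_same_shape(list(mats.values()))
    n, t = mats[names[0]].shape

    subsets = [
        tuple(c)
        for r in range(2, len(names) + 1)
        for c in itertools.combinations(names, r)
    ]
    fractions = {}
    if mode == "pooled":
        m = _selection_size(n * t, pct)
        flat_node, flat_time = np.unravel_index(np.arange(n * t), (n, t))
        sel = {
            k: _top_indices(mats[k].ravel(), m, (flat_node, flat_time))
            for k in names
        }
        for subset in subsets:
            inter = set.intersection(*(sel[k] for k in subset))
            fractions[subset] = len(inter) / m
    else:
        m = _selection_size(t, pct)
        times = np.arange(t)
        per_node = {subset: [] for subset in subsets}
        for i in range(n):
            sel = {k: _top_indices(mats[k][i], m, (times,)) for k in names}
            for subset in subsets:
                inter = set.intersection(*(sel[k] for k in subset))
                per_node[subset].append(len(inter) / m)
        for subset in subsets:
            fractions[subset] = float(np.mean(per_node[subset]))
    return OverlapReport(threshold_pct=pct, mode=mode, fractions=fractions)


def quadrant_analysis(pc_s, pc_t, z_s, z_t) -> QuadrantReport:
    """Classify every (node, time) point by the signs of the method differences.

    delta PC = PC_T - PC_S and delta z = z_T - z_S.  The quadrants where the
    two deltas have opposite signs are the discordant ones: there the
    static-community pipeline reads the point as more integrated while the
    temporal-community pipeline reads it as more segregated, or vice versa.
    """
    arrays = [_values(x) for x in (pc_s, pc_t, z_s, z_t)]
    _check_same_shape(arrays)
    ps, pt, zs, zt = arrays
    dpc = pt - ps
    dz = zt - zs
    total = dpc.size
    on_axis = np.count_nonzero((dpc == 0) | (dz == 0))
    fractions = {}
    for sp, sz in itertools.product(("+", "-"), repeat=2):
        mask = (dpc > 0 if sp == "+" else dpc < 0) & (dz > 0 if sz == "+" else dz < 0)
        fractions[(sp, sz)] = np.count_nonzero(mask) / total
    discordant = fractions[("+", "-")] + fractions[("-", "+")]
    return QuadrantReport(
        fractions=fractions, discordant=discordant, on_axis=on_axis / total
    )


def heteroscedasticity_test(x, y, n_bins: int = 10):
    """Bartlett test for unequal variance of ``y`` across quantile bins of ``x``.

    ``y`` is grouped by x-quantile bins (deciles by default); Bartlett's
    statistic tests whether the y-variance is equal across bins, against a
    chi-square reference.  Bins with fewer than 2 points trigger a reduction
    of the bin count (with a warning); fewer than 2 usable bins is an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    while n_bins >= 2:
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        groups = [y[idx == b] for b in range(n_bins)]
        groups = [g for g in groups if g.size > 0]
        if all(g.size >= 2 for g in groups) and len(groups) >= 2:
            stat, p = stats.bartlett(*groups)
            return {"statistic": float(stat), "p": float(p), "n_bins": len(groups)}
        warnings.warn(
            f"bin with <2 points at n_bins={n_bins}; reducing", stacklevel=2
        )
        n_bins -= 1
    raise ValidationError("fewer than 2 usable bins")


def mean_over_time_correlation(series_by_method: dict) -> dict:
    """Pearson correlation across nodes of per-node time-averaged values."""
    names = sorted(series_by_method)
    mats = {k: _values(v) for k, v in series_by_method.items()}
    _check_same_shape(list(mats.values()))
    if mats[names[0]].shape[0] < 3:
        raise ValidationError("need N >= 3 nodes")
    means = {k: mats[k].mean(axis=1) for k in names}
    out = {}
    for a, b in itertools.combinations(names, 2):
        out[(a, b)] = float(stats.pearsonr(means[a], means[b]).statistic)
    return out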