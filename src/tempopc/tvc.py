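"""Time-varying connectivity estimation.

Two per-timepoint estimators of a :class:`~tempopc.core.TemporalNetwork` from
a node-by-time signal matrix:

``weighted Pearson``
    For each time point t, a Pearson correlation matrix computed with
    per-timepoint weights derived from the Euclidean distance between the
    multivariate signal at t and at every other time point.  Time points
    whose overall activity pattern resembles t's support the estimate at t
    — "spatially nearby" rather than temporally nearby time points, in
    contrast to a sliding window.

``MTD`` (multiplication of temporal derivatives)
    The product of the temporal derivatives of each pair of signals,
    normalized by the derivative standard deviations and smoothed with a
    moving average over +/- ``half_window`` time points.

Neither estimator thresholds negative edges; apply
:func:`tempopc.core.threshold_negative_edges` before community detection and
participation measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import NodeTimeSeries, TemporalNetwork, ValidationError

__all__ = [
    "TemporalWeightMatrix",
    "temporal_distance_weights",
    "weighted_pearson_slice",
    "estimate_tvc_weighted_pearson",
    "estimate_tvc_mtd",
]


@dataclass(frozen=True)
class TemporalWeightMatrix:
    """T x T matrix of per-timepoint estimation weights.

    Row t holds the weight of every time point in the connectivity estimate
    at t, scaled to [0, 1] within the row; the diagonal (a time point's own
    weight) is 1 because its self-distance is 0.
    """

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("temporal weights must be a square T x T matrix")
        if not np.all(np.isfinite(w)):
            raise ValidationError("temporal weights must be finite")
        if np.any(w < 0) or np.any(w > 1):
            raise ValidationError("temporal weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)


def temporal_distance_weights(ts: NodeTimeSeries) -> TemporalWeightMatrix:
    """Distance-derived estimation weights for the weighted-Pearson method.

    For each pair of time points the Euclidean distance between the two
    N-dimensional signal vectors is computed.  Each row of the distance
    matrix is min-max scaled to [0, 1] and converted to a similarity
    (1 - scaled distance), so the nearest time points carry the largest
    weight and a time point's own weight is 1.
    """
    if ts.n_times < 3:
        raise ValidationError("temporal weighting needs T >= 3")
    dist = squareform(pdist(ts.values.T, metric="euclidean"))
    if np.all(dist == 0):
        raise ValidationError(
            "all time points are identical; temporal weighting is undefined "
            "(use an unweighted Pearson correlation instead)"
        )
    weights = np.empty_like(dist)
    for t in range(dist.shape[0]):
        row = dist[t]
        lo, hi = row.min(), row.max()
        if hi == lo:
            # All other time points equidistant: uniform support.
            weights[t] = 1.0
        else:
            weights[t] = 1.0 - (row - lo) / (hi - lo)
    return TemporalWeightMatrix(weights)


def weighted_pearson_slice(ts: NodeTimeSeries, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of all node pairs.

    Uses frequency-style weights: weighted mean mu_i = sum_t w_t x_it / sum_t w_t
    and weighted (co)variance with denominator sum_t w_t.  The diagonal of the
    returned N x N matrix is set to 0 (self-correlation carries no edge).
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size != ts.n_times:
        raise ValidationError("weight vector length must equal T")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if np.count_nonzero(w) < 2:
        raise ValidationError("need at least two strictly positive weights")
    x = ts.values
    wsum = w.sum()
    mu = (x * w).sum(axis=1) / wsum
    xc = x - mu[:, None]
    cov = (xc * w) @ xc.T / wsum
    var = np.diagonal(cov)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValidationError(
            f"zero weighted variance for node {ts.node_ids[bad[0]]}"
        )
    denom = np.sqrt(np.outer(var, var))
    r = cov / denom
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return (r + r.T) / 2.0


def estimate_tvc_weighted_pearson(ts: NodeTimeSeries) -> TemporalNetwork:
    """Per-timepoint weighted-Pearson connectivity (T slices, unthresholded)."""
    wmat = temporal_distance_weights(ts).weights
    n, t = ts.n_nodes, ts.n_times
    out = np.empty((n, n, t))
    for k in range(t):
        out[:, :, k] = weighted_pearson_slice(ts, wmat[k])
    return TemporalNetwork(out, node_ids=ts.node_ids, thresholded=False)


def estimate_tvc_mtd(ts: NodeTimeSeries, half_window: int = 4) -> TemporalNetwork:
    """Multiplication-of-temporal-derivatives connectivity (T-1 slices).

    dx_it = x_it - x_i(t-1); the raw coupling is
    m_ijt = dx_it * dx_jt / (sigma_i * sigma_j) with sigma the population
    standard deviation of each derivative series, smoothed by a moving
    average over t +/- half_window with truncated windows at the boundaries.
    """
    if half_window < 0:
        raise ValidationError("half_window must be >= 0")
    if ts.n_times < 2 * half_window + 2:
        raise ValidationError(
            f"MTD needs T >= {2 * half_window + 2} for half_window={half_window}"
        )
    dx = np.diff(ts.values, axis=1)  # (N, T-1)
    sigma = dx.std(axis=1)  # population std
    bad = np.flatnonzero(sigma == 0)
    if bad.size:
        raise ValidationError(
            f"zero derivative variance for node {ts.node_ids[bad[0]]}"
        )
    z = dx / sigma[:, None]
    n, tm1 = z.shape
    raw = np.einsum("it,jt->ijt", z, z)  # m_ijt
    if half_window == 0:
        smooth = raw
    else:
        csum = np.concatenate(
            [np.zeros((n, n, 1)), np.cumsum(raw, axis=2)], axis=2
        )
        smooth = np.empty_like(raw)
        for t in range(tm1):
            lo = max(0, t - half_window)
            hi = min(tm1, t + half_window + 1)
            smooth[:, :, t] = (csum[:, :, hi] - csum[:, :, lo]) / (hi - lo)
    for t in range(tm1):
        np.fill_diagonal(smooth[:, :, t], 0.0)
    return TemporalNetwork(smooth, node_ids=ts.node_ids, thresholded=False)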