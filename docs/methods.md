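# Methods

## The problem

The participation coefficient (PC) of a node quantifies how evenly the
node's connection strength spreads over the communities of a network.  For
node *i* with strength *k_i* and within-community strengths *k_is* over the
communities *s* of a partition,

    P_i = 1 − Σ_s (k_is / k_i)²,

so P = 0 when all strength stays in one community and P → 1 − 1/M as
strength spreads evenly over M communities.  In temporal (multilayer)
network analyses — time-varying functional connectivity in particular — PC
is routinely computed per snapshot, and the resulting time series is read
as a node's "integration" profile.  The value of PC, however, is relative
to the community partition it is computed against.  When each snapshot is
scored against its own temporal partition (PC_T), consecutive values refer
to different community contexts and their differences conflate two things:
changes in the node's own edges and changes in the surrounding community
structure.  The canonical failure mode: a community splits because its
internal edges *weakened*; every member's PC_T jumps up, which reads as
increased integration while the opposite happened.

This package implements the per-snapshot measures and the correction: the
temporal participation coefficient (TPC), in which every snapshot *t* is
scored against the partition of *every* time point *u* and the T scores are
averaged,

    P_it = 1 − (1/T) Σ_u Σ_{s ∈ partition u} (k_its(u) / k_it)².

All time points then share one composite community context, restoring
comparability while retaining the temporal community information.  The sum
runs over all T partitions including repeats, so recurrent community
configurations weigh in proportion to their prevalence.  TPC presumes
*recurrence*: that community configurations can reappear at other times.
For systems with irreversible dynamics (e.g. contagion), scoring early
snapshots against late partitions is not meaningful and PC against a static
partition (PC_S) is the prudent choice.

## Pipeline

1. **Time-varying connectivity** (`tvc`).  The default estimator computes a
   weighted Pearson correlation per time point.  The weight of time point
   *u* in the estimate at *t* derives from the Euclidean distance between
   the N-dimensional signal vectors at *t* and *u*: each row of the T×T
   distance matrix is min–max scaled to [0, 1] and converted to a
   similarity, 1 − scaled distance.  "Spatially nearby" time points (similar
   multivariate configurations) thus support each estimate, in contrast to
   a sliding window's temporally nearby points.  The order of operations
   (scale first, then subtract from one) is a deliberate choice: subtracting
   raw, unbounded distances from one can go negative.  A time point's own
   weight is always 1.  Weighted moments use the frequency-weight
   convention (denominator Σw), so results are reproducible bit for bit.
   The alternative estimator is the multiplication of temporal derivatives
   (MTD): products of the per-step signal derivatives of each node pair,
   normalized by the population standard deviations of the derivative
   series and smoothed by a moving average over ±4 points (configurable),
   with truncated windows at the boundaries so the output always has T−1
   slices.
2. **Thresholding** (`core.threshold_negative_edges`).  Strictly negative
   edges are set to zero before community detection and PC — both are
   defined here on nonnegative weights.  Thresholding is explicit, never
   hidden inside an estimator.
3. **Communities** (`communities`).  Modularity maximization (Louvain,
   resolution 1 by default) on the time-averaged network gives the static
   partition; run independently per slice it gives the temporal partitions.
   Per-slice seeds are spawned deterministically from one seed.  An
   all-zero slice yields singleton communities with a logged warning.
4. **Temporal consensus** (`communities.temporal_consensus`).  Slice-wise
   Louvain labels are arbitrary; consensus relabels them so a persisting
   community keeps one label.  Sweeping forward, communities in consecutive
   slices are matched one-to-one in ascending Jaccard distance
   (1 − |A∩B|/|A∪B|) between their node sets; a match requires at least one
   shared node; unmatched communities get fresh, never-reused labels.
   Ties break by the smallest member node id of the current community, then
   of the candidate predecessor — both invariant to the incoming label
   alphabet, which makes the sweep deterministic and idempotent.  Consensus
   only renames: the per-slice partition structure is preserved exactly.
5. **Measures** (`measures`).  PC_S (static partition at every slice), PC_T
   (slice's own partition), TPC (all partitions, averaged), flexibility
   (fraction of consecutive steps at which a node's consensus label
   changes), and within-module degree z-scores z_S / z_T (z-score of
   within-community strength relative to the other members of the node's
   community, with the static or the slice partition respectively).
6. **Divergence diagnostics** (`compare`).  Per-node Spearman correlations
   between measure time series; top-percentile "temporal hub" overlap
   between methods (per node or pooled); the sign-quadrant analysis of
   (PC_T − PC_S) against (z_T − z_S), whose opposite-sign quadrants mark
   points the static and temporal pipelines interpret in contradictory
   ways; a Bartlett test of variance heterogeneity across quantile bins;
   and the cross-node correlation of time-averaged PC.

## Numerical conventions

- **Degree is weighted strength** throughout; the networks are weighted.
- **Zero strength**: a node with k_it = 0 gets PC = 0 at that slice ("no
  participation"); 0/0 is never formed.
- **z-scores** use the population (N-denominator) standard deviation;
  singleton and zero-variance communities give z = 0.
- **PC range**: all variants lie in [0, 1); uniform positive scaling of a
  node's edges at a slice leaves every variant unchanged (the measure
  depends only on strength ratios).
- **Degenerate weight rows**: if all pairwise time distances in a row are
  equal, the row falls back to uniform weights; an entirely constant signal
  matrix is rejected with a pointer to ordinary Pearson correlation.
- **Hub selection**: the top-pct% selection size is ceil(pct% · count),
  computed robustly against binary-float edge cases; exact value ties at
  the cutoff resolve to the earliest time, then the lowest node id, so
  selections are deterministic.
- **Quadrant analysis**: points exactly on an axis (zero difference) are
  excluded from quadrant fractions and reported separately.
- **Bartlett binning**: deciles of the x variable by default; bins with
  fewer than two points trigger a bin-count reduction with a warning.

## Synthetic data

Two generators stand in for empirical recordings; no neuroimaging data is
required or included.

**Toy scenarios** (`synthetic.make_toy`) are hand-built two-snapshot
networks with planted partitions: a focal node spreading its edges evenly
(fig1b); a node absorbed into the community it strengthened toward (fig1c);
a partition change driven entirely by edges not touching the focal node
(fig1d); a community splitting through weakened cross-half edges
(fig2_split) and extending through strengthened ones (fig2_extend); and the
averaged-context demonstration (fig3).  Edge weights use two levels (strong
1.0, weak 0.1–0.5); only the *signs* of the focal node's measure changes
are part of each scenario's contract, because those follow from the
topology change alone.  On fig2_split, PC_T rises while PC_S and TPC fall;
on fig2_extend the pattern mirrors — the central interpretation flip, with
TPC agreeing in sign with PC_S.

**Recurring-state series** (`synthetic.generate_recurring_timeseries`)
emulate parcellated resting-state-like signals: piecewise-stationary epochs
drawn from a zero-mean multivariate normal whose correlation matrix has the
block structure of one of K community states, the states recurring
cyclically so each occurs at least twice (TPC's recurrence regime).
Defaults: 40 nodes, 200 time points, epochs of 50, K = 2 phase-shifted
balanced bipartitions, within-block correlation 0.6 versus between-block
0.05, AR(1) temporal smoothing with coefficient 0.8 applied to the latent
innovations (hemodynamic-like signals are smooth in time; temporal
smoothness is also what gives the distance-based estimation weights any
purchase — with i.i.d. draws, same-state time points are no closer in
signal space than different-state ones), and additive sensor noise with
standard deviation 0.1.  Sampling is deterministic given the seed.

What the generator does *not* emulate: hemodynamic response functions,
scanner drift and motion artifacts, spatial autocorrelation between
parcels, and subject-level variability.  Passing tests on this generator
therefore demonstrate the measures' mathematical behavior under recurring
community structure, not empirical effect sizes.

A known property worth stating: through the full
signals → weighted-Pearson → Louvain pipeline, per-slice partitions recover
the planted blocks only partially (exact recovery in roughly half the
slices at the defaults).  The min–max distance-to-similarity transform
leaves every time point with substantial weight (distances in moderate
dimension concentrate mid-range), so each slice's estimate mixes the two
states and the slice partition resolves whichever state dominates that
slice's weight vector.  This is a property of the estimator, not a bug in
the generator; detection given clean block snapshots recovers the planted
partition essentially always, and the method-comparison results (the
package's point) are insensitive to it — the ordering "TPC tracks PC_S
more closely than PC_T does" holds across seeds in both median rank
correlation and hub overlap.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise every
code path with comfortably stable statistics: oracle equivalence on
hundreds of random instances up to 20 nodes × 10 slices; the
method-ordering experiment on 20 generator seeds at the default
40 × 200 configuration; the acceptance script's divergence report on 10
seeds derived from its `--seed` argument.

## Known limitations

- Louvain is delegated to networkx; partitions are deterministic given a
  seed but, like all modularity maximization, not globally optimal, and
  near-degenerate modularity landscapes (e.g. mixed-state estimates) can
  flip between similar partitions across seeds.
- The consensus matcher is greedy one-to-one; a globally optimal assignment
  (Hungarian) could differ on contrived many-way ties.
- Negative-edge information is discarded by thresholding; signed-network
  PC variants are out of scope.
- TPC costs O(T²·N·K) time; at hundreds of time points this is fast, but
  very long recordings may warrant deduplicating repeated partitions
  (intentionally not done here — repeats are meaningful weights).
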