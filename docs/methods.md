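# Methods

This note documents the models, parameter choices and numerical conventions
behind `modwalk`, and what its synthetic-data tests do and do not establish
about real data.

## EMG processing

Raw EMG (8 paretic-leg muscles, 2,000 Hz) is turned into a linear envelope
by: zero-lag high-pass at 40 Hz, demeaning, full-wave rectification, and
zero-lag low-pass at 4 Hz.  "Zero-lag fourth-order" is realized as
forward–backward passes of a second-order-sections Butterworth design, so the
*net* response is fourth order with zero phase — the usual reading in this
literature.  Filtering uses reflective padding of 3 × fs/f_c samples;
signals shorter than that raise rather than return ringing-dominated output.
Low-pass ringing can dip below zero; envelopes are clipped at 0 before
factorization, which requires nonnegativity.

Gait events come from per-belt vertical force: heel strike is an upward
crossing of a 20 N threshold and toe-off a downward crossing, each sustained
for at least 10 ms (debounce).  Both values are configurable; 20 N / 10 ms
are conventional for instrumented treadmills.  Event lists must interleave
(one toe-off between successive heel strikes of the same leg); violations
raise rather than silently reorder.

Each paretic heel-strike-to-heel-strike cycle is resampled to 101 points
(0–100%, linear interpolation) and cycles are averaged pointwise; fewer than
20 cycles triggers a warning, fewer than 2 heel strikes an error.  Six
gait-cycle bins — first double support, first/second half of single stance,
second double support, first/second half of swing — are bounded by the
*average* percent-of-cycle position of nonparetic toe-off, nonparetic heel
strike and paretic toe-off, with single stance and swing split at their
midpoints.  Binning after averaging (rather than per cycle) matches the fact
that the factorized matrix is itself the averaged cycle.  Bin means are exact
integrals of the piecewise-linear envelope over the (fractional) bin
interval, so closed-form oracles hold to machine precision.  Amplitude is
normalized per muscle by the mean of its highest bin; a muscle with no
positive bin mean raises by default (an option drops it with a warning),
because silent division by zero would corrupt the factorization input.

## Module extraction and the VAF rule

NNMF minimizes ‖X − WC‖²_F with multiplicative updates (epsilon-guarded),
run from `restarts` seeded random initializations (default 50) plus, within
a module-count sweep, one warm start: the previous k's solution padded with
a tiny random module.  Convergence is declared when the relative SSE change
over 10 iterations falls below 1e-6 (cap 10,000 iterations); the best-SSE
candidate wins, ties resolving to the earlier candidate, which makes fits
bit-reproducible given (X, k, seed, restarts).  Solutions are canonicalized
to unit-maximum weight columns with compensating activation scaling.

VAF is uncentered — 100·(1 − Σe²/Σx²) — computed overall, per muscle (row)
and per bin (the bin's column range pooled across muscles); the 90% / 5
percentage-point thresholds in the selection rule were calibrated to
uncentered VAF in the prior synergy literature.  The selection sweep stops at
the first k with min-VAF ≥ 90% over all 8 muscles and 6 bins; otherwise it
fits k+1 and stops at k if no individual muscle or bin gains more than 5
points (the lookahead fit is kept in the trail for inspection).  Warm starts
make overall VAF monotone in k, which the tests assert.  The two-vs-more
dichotomy places k = 1 with the two-module class (a "two or fewer"
reading; k = 1 occurs only for degenerate inputs).

Module recovery is scored by optimal one-to-one cosine matching of weight
columns (Hungarian assignment, identical to exhaustive permutation search at
these sizes).

## Gait metrics

The positive anterior impulse is the trapezoidal integral of
max(anterior force, 0) at the native sampling rate over the whole analyzed
trial; Pp is the paretic share of the two legs' impulses.  PSR is the ratio
of mean paretic step length to mean stride length.  Deviation from symmetry
is |value − 0.5| for both, so 0 is symmetric and 0.5 maximally asymmetric.

## Streamline asymmetry and harmonization

Asymmetry is the ratio of streamline weights: lesioned/non-lesioned for
stroke, right/left for controls; 1 means symmetric.  Scanner-batch effects
are removed by per-channel location–scale standardization: each batch is
z-scored and re-expressed on the pooled mean and standard deviation.  This
is a deliberate simplification of empirical-Bayes ComBat — it removes first-
and second-moment batch differences, preserves within-batch rank order, and
reproduces the important qualitative behavior that small weights can become
negative after harmonization (which is why the classification tree can carry
a negative CST cutoff).  Ratios are computed after harmonization, without
clamping; zero denominators raise and the record is excluded from
correlations with a warning.

## Cohort statistics

Spearman correlations use average ranks (tie-corrected) with p-values from
the t-approximation on n − 2 degrees of freedom, pairwise-complete per
variable pair; constant vectors raise.  Mann–Whitney U counts pairs with
ties as ½, exact p for small tie-free samples and the tie-corrected normal
approximation otherwise, two-sided.  One-way ANOVA post-hocs are pairwise t
tests with Bonferroni adjustment capped at 1.0.  No multiplicity adjustment
is applied across the correlation battery (the walking measures are
interrelated; the battery is exploratory).  These three statistics wrap
scipy.stats; independent brute-force implementations (Pearson-on-ranks,
exhaustive pair counting, mean-squares ratio) live in the test layer and the
acceptance experiments so the two routes stay distinct.

The "coarse" classification tree is CART with Gini impurity, candidate
thresholds at midpoints between sorted distinct feature values, best-first
growth, at most 4 internal splits, minimum leaf size 1.  Ties break toward
the lower feature index and lower threshold; leaf-label ties break
lexicographically.  These rules make training invariant to record order,
which is asserted on shuffled inputs.  Prediction descends with a strict
less-than on the left branch, matching how published cutoffs of this form
("< 0.27", "< −0.02") are stated.  Cross-validation uses seeded, stratified
five-fold splits with per-fold refits and a pooled out-of-fold confusion;
the resubstitution confusion of the full-data tree is reported alongside,
since published classification counts of this kind are typically
resubstitution-style and the two can differ substantially at n = 43.
Confusion percentages are exact functions of integer counts; displayed
percentages truncate toward zero (7/13 → 53%), the convention that matches
how such tables are printed.

The FMA-LE comparator predicts the two-module pattern when the 22-point
synergy subsection is strictly below 15 — the range where moving outside
flexor/extensor synergies is theoretically unavailable.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is evaluated.

**EMG.** Module activations (101-point templates) are tiled across cycles
whose durations carry lognormal multiplicative jitter (sd 3%, configurable)
around 1.2 s, mixed through nonnegative weights, and used to
amplitude-modulate a per-channel band-limited (20–450 Hz) Gaussian carrier.
The carrier is rescaled so that the rectified mean of its 40 Hz high-passed
version is 1, making the envelope chain approximately unit gain; envelope
noise is smooth (6 Hz low-passed) Gaussian noise scaled to `noise_sd` × the
per-muscle signal RMS, clipped at zero.  Default `noise_sd` is 0.05.
Recordings span `n_cycles` ≥ 20 cycles, the study's minimum.

**Module templates.**  The two-module pattern loads SO, MG, VM, LH, MH, GM
on a stance-spanning activation and TA, RF on a swing activation.  Four
modules follow the healthy convention — plantarflexors (late stance),
quadriceps + gluteus medius (early stance), hamstrings (terminal swing),
dorsiflexors + rectus femoris (swing) — as circular Gaussian bumps with
well-separated centers; three modules merge the temporally adjacent
hamstring and quadriceps groups.  Member weights are drawn in [0.8, 1.0],
non-member weights in [0, 0.05], seeded.

**GRF.**  Vertical force is a raised-sine bump spanning each stance phase
(events at 12% nonparetic toe-off, 50% nonparetic heel strike, 62% paretic
toe-off of the paretic cycle).  Propulsive lobes are *identical* half-sines
(duration 0.2 × cycle) ending at each toe-off, snapped to the sample grid,
so the paretic share of the positive anterior impulse equals `pp_true`
exactly by construction, independent of cycle jitter; braking lobes are
negative and kept clear of the propulsive lobes.  Step-length lists carry 3%
jitter but are rescaled so PSR equals `psr_true` exactly.

**Cohort.**  A reference stroke cohort splits 7:6:30 into severely impaired
two-module subjects (ipsilesional CST mean 0.5, ipsilesional CRP 3.3,
contralesional CRP 16.8 — strongly asymmetric), moderately impaired
two-module subjects (5.5 / 10.7 / 11.5 — near-symmetric, the subgroup a
streamline-based classifier misses), and more-than-two-module subjects
(4.1 / 8.6 / 13.2), with contralesional CST mean 8 throughout.  Counts are
Poisson around these means; ipsilesional CST counts of the non-severe groups
are gamma-Poisson overdispersed (shape 1.2), reflecting that severe CST
damage occurs among subjects who nonetheless keep more than two modules —
this is also why CRP, not CST, is the cleaner primary separator for the
tree, as in the study.  Healthy controls get large near-symmetric counts
(right/left ratios near 0.96 CST and 0.91 CRP).  A two-level scanner-batch
effect (scale 1.2, shift 1) is applied to raw counts and removed by
harmonization.  Clinical scores (FMA-LE, DGI, BBS, SMWT, speed) and the
propulsion-deviation target are linear in the subject's own batch-free
asymmetries plus Gaussian noise, with signs fixed to the observed
correlation directions; coupling strengths are set so the sign pattern is
recoverable with high probability at n = 43.  PSR is uncoupled (the study
found no PSR association).

## Problem sizes

The evaluation experiments use 100 subjects per true module count (300
total) for count recovery, 100 cohorts of 43 for sign recovery, 50 cohorts
for the tree-root analysis, 1,000 partitions for the VAF oracle and 200
sample sets for the statistics oracles; NNMF selection in the large
experiments uses 5 restarts per fit (the selection landscape at 8 × 101 is
benign; 50 restarts remains the single-fit default).

## Known limitations

- The generator produces idealized signals: no EMG artifacts or crosstalk,
  no ECG contamination, no missing clinical scores, no event-detection
  failures.  Passing recovery tests demonstrates the pipeline's correctness
  and its behavior under the configured noise, not robustness to real-world
  artifacts.
- Clinical couplings are linear with strong effect sizes, so the simulated
  Spearman correlations are larger in magnitude (≈ 0.6–0.85) than those a
  heterogeneous clinical cohort yields; only their *signs* are treated as
  recoverable targets.
- The location–scale harmonization ignores the shrinkage of empirical-Bayes
  ComBat; with few subjects per batch its variance estimates are noisier.
- Treadmill speed and cycle-duration statistics are conventional defaults,
  not estimated from data.
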