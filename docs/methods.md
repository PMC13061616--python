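# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Peri-event conventions

Time 0 is the event onset. Windows are half-open `[-pre, post)`: the sample
at t = 0 belongs to the post-window. Every "s.d." is the sample standard
deviation (n − 1 denominator). Peri-event z-scoring subtracts the pre-window
mean and divides by the pre-window s.d. per trial; a trial with zero
baseline s.d. carries no usable baseline and is excluded with a log message
rather than propagating infinities.

## Bootstrap significance bands

The band is a percentile bootstrap on the trial-mean trace: trials are
resampled with replacement (default 1,000 times), the mean trace is binned
(default 10 ms), and the per-bin CI is the (α/2, 1 − α/2) percentile
envelope. A bin is flagged significant only when its CI excludes the null
level, which defaults to 0 (the post-z-score baseline); a `null_level`
argument supports testing against any other reference. The percentile
bootstrap is an asymptotic method: at n = 3 trials its realised
false-positive rate is well above nominal, so the calibration suite
evaluates it at n = 100 trials per session, where the measured flagged-bin
rate on pure-noise sessions is ≈ 0.054 against a nominal 0.05 — inside the
binomial band for the simulation size used (50 sessions × 50 post-window
bins). Conclusions about few-trial real data should treat the band as
descriptive, not exact.

## Circular-rotation permutation test

A cell's CS-modulation statistic is the post-minus-pre mean-activity delta
(5 s + 5 s windows) averaged over CS trials. The null rotates the whole-
session trace by a random integer offset — preserving autocorrelation,
destroying event alignment — and recomputes the statistic; 500 rotations by
default. Implementation detail: rotations are evaluated through a doubled
cumulative sum (reading a rotated window is reading a shifted window of the
original trace), so the null costs O(n_rot · n_trials) per cell rather than
O(n_rot · n_samples).

Empirical p-values use the add-one correction (k + 1)/(n + 1), so p is
bounded below by 1/(n_rot + 1) and the test is valid at finite n_rot; the
raw proportion is available via `add_one=False`. Ties are counted as
at-least-as-extreme within 1e−12, which prevents the constant-trace
pathology (all null deltas equal to the observed delta would otherwise give
p = 0); constant traces are additionally short-circuited to `none`.
Modulation is assessed with two one-sided tests at α each (positive takes
precedence), matching the one-sided definition of the criterion;
the exact nominal false-call rate per tail at n_rot = 500, α = 0.05 is
25/501 ≈ 0.0499.

### Recovering a responder fraction

The raw positive-call rate overestimates the true responder fraction: with
reliable detection its expectation is f + (1 − f)·a where a is the nominal
false-call rate. `ModulationResult.recovered_fraction` therefore applies
the standard mixture correction (r − a)/(1 − a); the raw rate remains
available (`correct=False`). On sessions generated with f = 0.30 and a
clearly detectable effect the corrected estimator recovers the truth to
within ±0.05 across seeds, which is what the parameter-recovery suite
asserts.

## Decoders and their nulls

All decoders are logistic models with an L2 penalty at the conventional
default strength (C = 1); only the penalty form is prescribed by the
procedure being reproduced, so the strength is pinned and configurable. F1
is the binary score with the CS (or second-group) class positive.

* **CS from event activity.** Per trial the classifier sees a 5-s pre-CS
  sample and a pseudo 5-s post-CS sample assembled from 10 random
  non-contiguous 0.5-s intervals of the 30-s post window (disjointness is
  guaranteed by a combinatorial bijection, so construction never rejects).
  Cross-validation is trial-grouped 5-fold: both windows of a trial share a
  fold; fold assignment is round-robin after a seeded shuffle. The observed
  score averages F1 over constructions × folds.
* **Treatment group per animal.** One feature vector per mouse over the
  peri-CS window; category-mean features equate neuron counts by averaging
  100 draws of 5 neurons sampled with replacement. Folds are
  leave-one-mouse-out; a single-mouse fold scores F1 with `zero_division=1`
  so a correct all-negative prediction is not penalised. The null permutes
  group labels across mice.
* **CS versus ensemble size.** Neuron subsets sampled without replacement,
  50 per size, sizes 2..100 by default (truncated with a warning when fewer
  neurons exist).

Shuffle nulls for the time-series decoders circularly rotate the data by a
common random offset. The offset is required to exceed the full peri-event
span (pre + post window): smaller shifts leave a trial's response inside
its own 30-s post window, contaminating the null with self-realignments and
inflating its upper tail. (The modulation classifier keeps the narrower
exclusion zone of its 5-s windows, where contamination is negligible — its
null calibration is verified directly.) Null decoder scores are compared at
chance level computed, in the tests, by exact enumeration of coin-flip
predictions over the realised fold sizes — for tiny held-out folds the
expected F1 of an uninformed classifier is noticeably below 0.5 (≈ 0.43 for
six trials in five folds), and treating 0.5 as "chance" would be wrong.

Within a session the generator draws inter-CS intervals uniformly from
60–90 s. Besides mirroring the variable-ITI conditioning protocol, this is
statistically load-bearing: with strictly periodic trials a single rotation
by the trial period would re-align every trial at once and the rotation
null would have a heavy upper tail.

## Saturating fit of the size curve

`SaturatingModel` fits y = b·n/(a + n) (Michaelis–Menten form) by bounded
least squares (a ∈ (1e−6, 1e4], b ∈ (0, 1]), initialised at a₀ = median
size, b₀ = max observed score, with a geometric grid of restarts on
non-convergence. b is the asymptotic performance, a the size at half-
asymptote, and b/a the initial slope — reported as the information
contributed per neuron, together with a and b so alternative readings can
be derived. Uncertainty comes from refitting (default 1,000 times) after
resampling the 50 per-size replicate scores with replacement. On noiseless
curves the fit recovers (a, b) to ≤ 1e−4 and agrees with a brute-force grid
search; with σ = 0.02 replicate noise the bootstrap-median b/a stays within
a few percent of truth.

## PCA trajectories, clustering, correlation

Group trajectories come from PCA of trial-averaged, per-neuron
mean-normalised peri-CS activity (neurons × time); PC1's sign is oriented
to correlate positively with the mean population trace. The two-group
comparison permutes neuron group membership (mouse membership where
identities exist), recomputes |PC1_A(t) − PC1_B(t)| per bin (≥ 1,000
permutations, add-one p) and controls FDR across bins with
Benjamini–Hochberg at α = 0.05. k-means (k = 4, seeded, best of n_init
restarts) clusters −5..+30-s peri-CS response shapes. The decoder-
coefficient/freezing relation is a one-tailed Pearson correlation on
mouse-averaged coefficients.

## Single-unit statistics

Peri-pip spike counts use half-open 100-ms bins (a boundary spike belongs
to the later bin), averaged across all pips. Each of the five post-pip bins
is z-scored against the across-pip 500-ms baseline as
z = (bin value − baseline mean)/(s.d. of the baseline mean), where the
denominator is the null standard error of the bin-minus-baseline
difference: sd(per-pip baseline counts)/√n_pips · √(1 + 1/5). Under this
scaling z is asymptotically standard normal for a stationary unit, so the
false-positive rate of the "any of 5 bins > 2.58" criterion approaches the
union rate 1 − (1 − P(Z > 2.58))⁵ ≈ 0.0245 (verified both by a 400k-draw
normal-limit simulation and by Monte-Carlo on Poisson units); the
alternative of dividing by the s.d. of the five averaged baseline bin
values (`baseline_stat="per_bin_sd"`) has t-like tails and a several-fold
higher false-positive rate. The criterion is excitation-only by default,
exactly as defined; `two_sided=True` tests |z|. The Monte-Carlo
false-positive suite simulates 20-Hz units so the averaged bin counts are
in the normal regime the union formula presumes — at a few Hz, Poisson skew
alone inflates the rate. Silent or zero-spread units are flagged degenerate
and never responsive.

The freezing index (r_f − r_m)/(r_f + r_m) uses spikes-per-epoch-time
rates; it is antisymmetric under swapping the epoch labels, bounded in
[−1, 1], and reported as missing when both rates are zero. Proportion
comparisons are Pearson χ² (df = 1) without continuity correction.

## Synthetic data: what it does and does not show

The generator emulates the structure the statistics operate on — CS-locked
double-exponential transients (τ_rise/τ_decay defaults 0.5/2 s for neurons,
2/8 s for astrocytes, preserving the slower-astrocyte ordering),
exact-count responder subpopulations (so recovery error is classifier
error, not assignment noise), multiplicative group gains standing in for a
chemogenetic manipulation, variable 60–90-s ITIs, and piecewise-
homogeneous Poisson spiking with epoch-dependent rates and pip-locked
boosts in the first post-pip bin. Noise is iid Gaussian on ΔF/F by default;
an AR(1) option exists to stress the rotation null with autocorrelated
baselines.

No distributional description of the original recordings is available, so
these choices are stand-ins. Passing the recovery and calibration suites
shows the procedures are correct and calibrated under these conditions; it
does not certify behaviour under real-data pathologies (motion artefacts,
baseline drift, bursting units, non-stationary noise). Determinism is
end-to-end: one RNG stream per session keyed by the seed, per-cell/unit
sub-streams spawned deterministically, and every stochastic analysis takes
an explicit seed; identical (seed, config) reproduces outputs bit-for-bit.

## Problem sizes in the default suites

The test and acceptance runs use desk-scale sizes chosen to estimate each
quantity with adequate precision: 2,000 cells/units for calibration rates,
10 seeded sessions of 200 cells for fraction recovery, 100 window
constructions and 100 shuffles for the event-activity decoder, sizes
2..100 × 50 replicates for the saturating fit, and 50 sessions for the
bootstrap-band calibration.
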