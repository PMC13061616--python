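# fearcode

Statistical analysis of neural recordings from Pavlovian fear-conditioning
experiments: peri-event calcium-signal statistics, permutation-based
classification of stimulus-modulated cells, population decoding with
shuffle nulls, and single-unit spike statistics — plus a synthetic session
generator so that every procedure can be validated by parameter recovery.

## Who this is for

Systems-neuroscience labs analysing fibre photometry, one/two-photon Ca²⁺
imaging or extracellular unit recordings collected around conditioned-
stimulus (CS) presentations, freezing/movement epochs and auditory pips.
The package covers the statistics layer between upstream signal extraction
(ΔF/F traces, event rasters, sorted spikes) and figures: it does not do
image registration, source extraction or spike sorting.

## What it computes

**Photometry** (`fearcode.photometry`) — peri-event matrices with baseline
z-scoring z = (ΔF − mean(ΔF₍₋₅..₀₎))/s.d., percentile-bootstrap significance
bands on the trial-mean trace (1,000 resamples, 10-ms bins), trapezoidal
AUC, transient counting with a robust (median/MAD) threshold, and
movement-aligned averages normalised to the session mean.

**Imaging** (`fearcode.imaging`) — ΔF/F₀ with a session-median or 25-frame
moving-average F₀; exclusion of implausible events (peak ΔF/F₀ > 7 or
duration > 60 frames); CS-modulation calls from a circular-rotation
permutation null (post-minus-pre delta vs 500 rotations of the whole-session
trace, add-one p, two one-sided tests at α = 0.05) or from a paired t-test
on per-trial event activity; cross-stage responder categories (increasing /
decreasing / sustained / non-responsive); centroid-distance topography.

**Decoding** (`fearcode.decoding`) — three L2-logistic decoding analyses
scored by held-out F1 against circular-rotation or label-permutation nulls:

* CS decoding from event activity with pseudo post-CS windows built from
  10 non-contiguous 0.5-s intervals and trial-grouped 5-fold CV;
* treatment-group decoding per animal (5-neuron subsamples with replacement
  × 100, leave-one-mouse-out folds) from category means, population s.d. or
  principal components;
* CS decoding versus ensemble size (2..100 neurons, 50 subsets per size),
  summarised by the saturating fit **y = b·n/(a + n)** where *b* is the
  asymptotic performance, *a* the saturation rate, and **b/a** the initial
  slope — the information contributed per neuron — with a 1,000-fold
  bootstrap over per-size replicates.

Plus PCA population trajectories with a Benjamini–Hochberg-corrected
per-bin permutation test, k-means clustering of peri-CS response shapes,
and the one-tailed Pearson correlation between decoder coefficients and
freezing.

**Ephys** (`fearcode.ephys`) — pip-responsiveness (peri-pip spike counts in
100-ms bins z-scored to the 500-ms pre-pip baseline; responsive when any of
the 5 post-pip bins exceeds z = 2.58, the two-tailed P < 0.01 critical
value), the freezing-modulation index (r_freeze − r_move)/(r_freeze +
r_move), and Pearson χ² tests on responder proportions.

**Synthetic data** (`fearcode.synth`) — sessions with known ground truth:
CS-locked double-exponential transients on Gaussian (optionally AR(1))
baselines, configurable responder fractions and group gains, variable 60–90 s
inter-CS intervals, and piecewise-homogeneous Poisson spiking with
epoch-dependent rates and pip-locked boosts.

## Worked example

```python
import numpy as np
import fearcode as fc
from fearcode.decoding import SaturatingModel

cfg = fc.SynthConfig(seed=7, n_cells=120, n_trials=5,
                     fraction_positive=0.3, effect_size=3.0)
cells, schedule, truth = fc.generate_cell_session(cfg)

calls = fc.classify_modulation_circular(cells, n_rot=500, alpha=0.05, rng=0)
print(f"positive calls: {calls.fraction('positive'):.3f} "
      f"(true fraction {np.mean(truth.category == 'positive'):.3f})")
print(f"recovered fraction (bias-corrected): {calls.recovered_fraction():.3f}")

curve = fc.decode_cs_vs_popsize(cells, sizes=np.arange(2, 41, 2),
                                n_reps=10, n_shuffle_reps=10, seed=0)
fit = SaturatingModel.from_curve(curve).fit(n_boot=200, rng=0)
print(fit.summary())
```

prints

```
positive calls: 0.317 (true fraction 0.300)
recovered fraction (bias-corrected): 0.281
Saturating fit  y = b*n/(a+n)
  a (saturation rate, neurons): 0.5984
  b (asymptotic F1):            1
  b/a (info per neuron):        1.671
  info rate 95% CI:             [1.035, 3.643] (200 bootstrap refits)
```

The classifier calls 31.7% of cells positively CS-modulated; after
correcting for the test's nominal 5% false-call rate the recovered
responder fraction is 0.281, close to the generated truth of 0.30. The
size-decoding curve saturates very quickly here (a ≈ 0.6 neurons) because
this synthetic population is strongly and homogeneously informative, so
each neuron carries a lot of CS information (b/a ≈ 1.7 F1 per neuron);
weaker, sparser populations give larger a and smaller b/a.

A command-line pipeline mirrors the library (`fearcode all --seed 1
--outdir run/` runs generate → analyse → report with a JSON manifest; see
`fearcode --help`).

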