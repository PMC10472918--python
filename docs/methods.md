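# Methods

## The classification model

`spaten` detects a subject's sex (0 = female, 1 = male) from 4-second,
21-channel EEG segments with a deliberately minimal spatio-temporal CNN of two
trainable layers:

1. **Spatio-temporal cross-correlation.** Each of `n_kernels` kernels is a
   `channels x kernel_len` weight slab spanning *all* channels and sliding only
   along time. For the default spec (21 channels, 1000 samples, 16 kernels of
   19 samples = 76 ms) each kernel yields a 982-sample correlation curve. An
   unbiased ReLU zeroes negative correlations, so the sign of each kernel's
   dense-layer weight cleanly encodes which sex the kernel argues for.
2. **Temporal max pooling** over 75-sample windows with stride 25. The window
   count is `ceil(982 / 25) = 40`: windows are allowed to truncate at the
   sequence end. An unpadded pooling would produce 37 windows; the end-padded
   variant is adopted because it reproduces the printed output shape of the
   reference architecture.
3. **Global average** of the 40 window maxima per kernel, then a single
   sigmoid unit (logistic regression over the 16 averages).

The convolution carries no bias; only the sigmoid unit has one. The headline
parameter count therefore is weights only: `16*21*19 + 16 = 6400`
(`count_parameters` reports the bias-inclusive total separately).

Training minimizes the class-weighted binary cross-entropy with Adam
(defaults: learning rate 1e-3, batch 64). Class weights are inversely
proportional to class frequency. A 20% holdout is split off *by subject*
(stratified by sex) so no subject contributes segments to both folds; after
each epoch the segment-level balanced accuracy on the holdout is evaluated and
the best epoch's weights are returned. The forward and backward passes are
written directly in NumPy: with 6400 weights, explicit im2col matrix products
are faster to audit than a deep-learning framework and keep the attribution
module trivially consistent with the trained weights. Gradients were verified
against central finite differences in float64.

Subject-level predictions are majority votes over the thresholded (0.5)
per-segment outputs; even vote splits are resolved by the mean predicted
probability (>= 0.5 means male). Ensembles vote per model with the same
tie-break on the grand mean probability.

Two optimization caveats are documented rather than hidden:

* Adam's effective travel is roughly `learning_rate x steps`; very small
  datasets (tens of segments) need a larger learning rate (1e-2) or smaller
  batches than the defaults, which are tuned for thousands of segments.
* With very few kernels the ReLU can silence a kernel whose dense weight
  starts with the unhelpful sign; 8 or more kernels make this irrelevant.

## Relevance attribution

Because only the maximum of each pooling window reaches the output, the
contribution of the input to a prediction is closed-form. For window `i` and
kernel `k`, with `C_{i,k}` the rectified correlation curve restricted to the
window, the kernel-shaped submatrix of the segment at the argmax lag is
element-wise multiplied by the kernel, scaled by the window's maximum
correlation and by the dense weight `w_k`, and accumulated at its sample
positions:

    R'_{i,k} = X_[argmax C_{i,k}] (.) K_k * max C_{i,k}
    R_{i,k}  = R'_{i,k} * w_k

Overlapping windows add their contributions; windows whose rectified maximum
is zero contribute nothing; argmax ties resolve to the earliest lag. The total
relevance map is the sum over kernels; negative values pull toward female,
positive toward male. Summing a map over channels gives a relevance time
course; `|R|` time courses averaged in epochs around annotated R peaks give
the QRS-locked average used to quantify cardiac-artifact leakage (epochs that
cross a segment boundary are skipped and counted; epochs are averaged within
each subject before the grand mean, so subjects contribute equally). The
implementation is tested against an independent all-loops oracle at 1e-9.

## Preprocessing

The signal path mirrors standard clinical EEG hygiene: zero-phase order-4
Butterworth bandpass (broadband 1-40 Hz; delta 1-4, theta 4-8, alpha 8-14,
beta 14-30, gamma 30-40 Hz), bad-channel interpolation, ICA artifact
rejection, selection of 50 non-overlapping 4-s segments after skipping the
first 120 s, then per-segment normalization: common average reference,
per-channel de-meaning, and division by one *global* segment SD. The global
SD (rather than per-channel) preserves relative channel amplitudes, which
carry the topographic signal; for single-channel (ECG-only) segments the CAR
step is skipped because it would annihilate the data.

Segment quality is scored by a simple, deterministic rule: a channel is bad
within a window when its peak-to-peak amplitude exceeds 150 uV; windows are
ranked by bad-channel count, then total peak-to-peak amplitude, ties by start
sample. `select_segments` accepts a `quality_fn` hook so a cross-validated
algorithm can replace the scorer on real data. Bad channels for interpolation
are flat (< 0.1 uV p-p) or extreme (> 500 uV p-p) over the whole recording;
interpolation is the mean of the four nearest good neighbors on the schematic
layout.

ICA rejection is automated: a FastICA unmixing (scikit-learn, at most 20
components, fit on an evenly strided subsample of <= 30k time points, applied
to the full recording) is estimated on the EEG; any component whose time
course correlates with the ECG reference channel (or any user-supplied
reference, e.g. a blink template) at |r| > 0.3 is subtracted from the data.
Only the rejected component subspace is removed, so an input with nothing to
reject passes through unchanged. On the synthetic cardiac cohorts this rejects
one component (the scalp-projected QRS train) and reduces the maximum
EEG-to-ECG cross-correlation by well over half.

## The synthetic cohort generator

The generator is the ground truth against which every downstream stage is
tested. A recording is 21-channel EEG at 250 Hz plus one ECG reference
channel, 330 s by default (the minimum is 320 s: a 120 s lead-in plus 50
non-overlapping 4-s segments; the default leaves headroom for the edge
trimming of the channel-shift perturbation). Components:

* **Neural background:** 8 band-limited (2-30 Hz) unit-variance Gaussian
  sources mixed through random scalp patterns, scaled to 20 uV RMS per
  channel, plus 10 uV RMS 1/f noise (exponent 1) and 2 uV white sensor noise
  per channel.
* **Topographic effect:** males and females mix through different pattern
  matrices (`base` vs `base + effect_size * diff`). Both matrices are
  *column*-normalized, so the marginal variance of every channel is identical
  between the sexes and only the instantaneous cross-channel covariance — the
  topography — carries the label.
* **Spectral effect:** identical patterns, but males receive a gain of
  `1 + effect_size` in the alpha band of the mixed signal. Because all sources
  share one spectrum and one mixing matrix, the spatial correlation structure
  is preserved while per-channel spectral shape differs.
* **Cardiac effect:** a biphasic ~100 ms Q-R-S triangle with a T-wave bump is
  placed at heart rate 70 bpm with 5% RR jitter; the ECG channel carries it at
  300 uV peak. In cardiac mode the train leaks onto the scalp through a fixed
  random unit-norm projection at 15 uV (female) scaled by `1 + effect_size`
  for males. 15 uV was chosen as a realistic uncleaned-clinical-EEG artifact
  amplitude and is the smallest round value at which the shallow CNN reliably
  learns the leak against this background. R-peak sample indices are
  annotated exactly.
* Optional frontal blink bumps (off by default) provide an EOG-like reference
  for the ICA hook.

Determinism: cohort-level structure (patterns, leak projection, ages) derives
from the master seed; each subject's signals derive from
`(master seed, CRC32(subject_id))`, so any subject is reproducible in
isolation and disjoint cohorts are obtained by prefixing subject ids (the
evaluation cohort uses prefix `e`).

What the generator does *not* emulate: volume-conducted forward physics (no
head model), non-stationarity, state changes (eyes open/closed), medication
effects, realistic artifact families beyond ECG/blink, or any coupling
between age and the signal. Passing tests therefore demonstrate that the
pipeline recovers the mechanisms it is told to plant — not that real EEG
carries them at any particular strength. Real-data effect sizes are unknown
here, so only qualitative orderings (detectable vs chance) are meaningful;
the synthetic accuracies should not be compared numerically with accuracies
reported on clinical corpora.

## Perturbation experiments

* **Time-point shuffling** applies *one* random permutation of the sample
  columns jointly to all channels of a segment: waveforms, spectra and
  cross-temporal structure are destroyed, every instantaneous topography
  survives. Paired with 21x1 (single-sample) kernels this isolates purely
  topographic information. With a single global pooling window the model
  output is exactly permutation-invariant, which is tested.
* **Channel time-shifting** draws an independent uniform integer shift up to
  ±200 ms (±50 samples) per EEG channel and applies it to the *continuous*
  recording before segmentation, trimming both edges by the maximum shift so
  no padding enters segments. Per-channel waveforms and spectra are exactly
  preserved (each output channel is a slice of its input channel);
  cross-channel alignment is destroyed. The ECG row is not shifted and QRS
  annotations are re-indexed.
* **Channel restriction** projects datasets onto channel subsets (e.g. the
  single ECG reference with 1x19 kernels). In cardiac-mode cohorts the ECG
  channel itself carries no sex information (the effect lives in the scalp
  leak), so the ECG-only model stays at chance — mirroring the corresponding
  single-channel control.
* **Greedy channel selection** performs forward selection on accuracy with a
  caller-supplied train/evaluate function, averaging each candidate over
  `n_repeats` seeds (default 5); ties resolve to the alphabetically first
  label so duplicated (fully redundant) channels are never preferred.

The experiment suite (`evaluate.run_suite`) trains `n_repeats` independently
seeded networks per condition (band x perturbation x kernel shape), reports
mean ± SD of subject-level balanced and imbalanced accuracies, tests the
across-network majority-vote correct count with an exact one-sided binomial
test against the evaluation cohort's majority-class fraction, and applies
Bonferroni across conditions. A failing condition is recorded with its
diagnostic and does not abort the rest. The reference protocol raises the
kernel count to 512 for the channel-shift condition; the API supports any
kernel count, but the packaged experiment grids run that condition at 16
kernels — the chance-level outcome does not depend on capacity, and a
512-kernel training costs ~32x as much.

## Statistics

Balanced accuracy is `(TPR + TNR)/2` with male as the positive class (the
metric itself is invariant to that convention, which is why it is safe to fix
it). Binomial tests are exact tail sums (`scipy.stats.binomtest`), verified
against direct enumeration up to n = 500. Paired t-tests (scipy `ttest_rel`)
compare per-network accuracies paired by seed and raise a dedicated error on
zero difference variance; their type-I error is calibrated by simulation in
the tests. Bonferroni adjustment is `alpha / n_tests` (0.05 / 15 = 0.003 for
the reference grid).

## Problem sizes and the scaled-down protocol

The packaged experiments run on one CPU. Study conditions, chosen once:

| experiment            | cohort (train/eval) | segments | effect          | epochs |
|-----------------------|---------------------|----------|-----------------|--------|
| topographic recovery  | 60 / 30             | 50       | topographic 2.0 | 6      |
| time-shuffle control  | same cohort         | 50       | topographic 2.0 | 6      |
| channel-shift control | 60 / 30             | 50       | topographic 2.0 | 6      |
| spectral + shift      | 40 / 20             | 50       | spectral 2.0    | 6      |
| cardiac relevance     | 20 / 10 (+8 maps)   | 20       | cardiac 1.0     | 6      |

Under these strong, stationary effects the loss converges by epoch 2-3, so
the experiments run 6 epochs with best-holdout-epoch selection (the reference
protocol is 20 epochs with convergence around 5). Effect size 2.0 ("strong")
makes the qualitative orderings unambiguous at these cohort sizes;
`effect_mode="none"` cohorts verify the chance-level floor.

One statistical subtlety in the label-permuted control: an unconstrained
permutation of 60 subject labels retains a hypergeometric overlap with the
true labels (SD about 2 subjects), and a 50-segment majority vote amplifies
even that residual correlation into extreme accuracies when the planted
effect is strong. The control therefore permutes labels *balanced within each
true sex* (an exactly orthogonal assignment), which is the standard
restricted-permutation construction for this situation. Even then the
permutation null is wide: a model overfit to an arbitrary 30-vs-30 subject
split has a random but nonzero projection onto the planted sex axis, and
vote amplification turns that into subject-level accuracies with heavy
tails. The acceptance script therefore averages the control over three
permutations; a thorough permutation test would use hundreds, which is out
of its time budget. (The `effect_mode="none"` cohort provides the
complementary, well-behaved null: no sex axis exists for a model to align
with, and accuracies sit tightly at chance.) Per-subject pattern jitter
(`subject_variability`, default 0.3) keeps within-sex subjects heterogeneous,
which both is realistic and prevents the degenerate two-distribution cohort
in which every same-sex subject votes identically.

## Numerical choices

* Zero-phase (forward-backward) order-4 Butterworth filtering avoids latency
  distortion of topography timing; attenuation >= 20 dB one octave outside
  the passband is tested.
* Training runs in float32 (im2col matrix products); evaluation of spec
  contracts and all relevance computations run in float64.
* Argmax ties (pooling and attribution) resolve to the earliest lag;
  quality-score ties to the earlier window; vote ties to the mean
  probability — every tie-break is deterministic.
* EDF export quantizes to int16 over a symmetric per-file physical range;
  round-trip error is bounded by the quantization step (~0.01 uV at typical
  amplitudes) and is covered by a write-then-read test through the MNE EDF
  reader.
* Degenerate inputs raise typed errors: constant segments (zero SD), empty
  classes, zero-variance t-test differences, all-bad-channel interpolation.

## Known limitations

* The generator's linear instantaneous mixing cannot express effects that
  depend on propagation delays or nonlinearity; conclusions about such
  mechanisms are out of reach of this test bed.
* FastICA on ~5.5 min of 21-channel data separates a single strong artifact
  reliably but is not a substitute for curated artifact rejection on clinical
  recordings; the correlation threshold (|r| > 0.3) is a blunt criterion that
  can miss low-amplitude leakage.
* The simplified peak-to-peak quality scorer has no notion of channel-specific
  noise statistics; the `quality_fn` hook exists precisely so a stronger
  algorithm can be substituted for real data.
* Accuracies obtained on synthetic cohorts characterize the pipeline, not any
  population; they are expected to saturate near 1.0 at the planted effect
  sizes and say nothing about real-world detectability.
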