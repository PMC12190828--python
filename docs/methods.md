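# Methods

This note documents the models, parameter choices and numerical
conventions behind `bnnvision`, and what the synthetic test conditions
do and do not establish about real cultured networks.

## Feature extractor

The extractor is a six-layer stack: three convolution layers (12, 14, 8
filters, 5×5 kernels, stride 1, zero "same" padding, ReLU) each
followed by 2×2 max pooling with stride 2. The input resolution is
fixed at 40×40: three 2× poolings must reduce the side to the 5×5 map
geometry, which forces 40 → 20 → 10 → 5. Images of any size are
bilinearly resampled to 40×40 on load.

Training attaches a temporary head (flatten → 3-way softmax) and
minimizes cross-entropy with Adam (learning rate 5·10⁻⁴, batch 16, up
to 50 epochs, early stopping with patience 5 on validation loss and
best-weight restore). The head is discarded afterwards; only the
convolutional stack is used. The network is implemented directly in
NumPy (im2col convolutions; gradients verified against central finite
differences in the test suite), which keeps training deterministic
given the seed and fast enough (a few seconds for tens of images on one
CPU) that no deep-learning framework is needed.

"Normalized feature maps" is interpreted as per-map min–max scaling to
[0, 1]; a constant map scales to all zeros. This guarantees the latency
transform below receives arguments in its domain.

## Delayed-phase encoding

For pixel value *p* ∈ [0, 1] the latency is *t* = *t*max(1 −
arctan(δ·*p*)). With the default δ = tan(1) the transform spans exactly
[0, *t*max]; for user-supplied larger δ negative latencies are clamped
to 0. The position delay of pixel *i* (row-major within its 5×5 field)
is *i*/25 of a 1-s span; with *t*max = 1 s the raw times fill the
printed 2-s stimulation window. The subthreshold membrane oscillation
is a cosine with period *T* = 200 ms and zero initial phase: its peaks
define 10 slots in 2 s, and snapping raw times to the nearest peak
(ties to the earlier peak; times past the last peak at 1.8 s absorb
into it) simultaneously enforces the 200-ms minimum interval, the 5-Hz
per-channel rate ceiling, and the 8×10 binary matrix view. Coincident
pulses within a channel merge, which is the compression step. A
configurable significance floor (default *p* ≥ 0.05 emits a pulse)
reproduces the sparser programs of low-contrast receptive fields;
setting it to `None` makes every pixel emit.

## Culture simulator

The simulator is a phenomenological stand-in for a living network, not
a biophysical model. Its defaults:

| parameter | default | meaning |
|---|---|---|
| `spontaneous_rate` | 0.5 Hz/channel | Poisson background |
| `burst_rate_per_min` | 6 | network-wide synchronized bursts |
| `burst_participation` | 0.3 | fraction of channels joining a burst |
| `burst_boost_hz`, `burst_duration` | 25 Hz, 100 ms | burst intensity |
| `gain[e, c]` | — | expected extra spikes on channel c per pulse on electrode e |
| `decay_tau` | 50 ms | evoked kernel; exp(−0.2/τ) < 5 % forces recovery within 0.2 s |
| `latency` | 2 ms | conduction delay; no evoked spike precedes pulse + latency |
| `refractory` | 2 ms | greedy thinning of the spontaneous background |
| `plasticity_drift` | 1.0 (off) | per-stage multiplier on the evoked gain |

The refractory period is enforced on the spontaneous background only;
evoked-kernel spikes are superposed unthinned so that the expected
evoked count per pulse equals `gain[e, c]` exactly — thinning the
evoked transient would bias this mean by roughly τ-collision losses and
break the Poisson mean-recovery contract the tests check.
`make_gain` draws a structured gain matrix (each electrode strongly
drives a random ~10 % subset of channels with log-normal strengths over
a weak uniform base), so distinct pulse programs evoke separable
spatial patterns.

The staged session delivers each of 9 programs 50 times. Trials 1–15,
16–30 and 31–45 form the three training stages; the five trials
immediately following each stage (16–20, 31–35, 46–50) are that stage's
held-out test trials — the only reading under which 45 training + 3×5
test trials fit the 50 delivered repetitions. Fifty 2-s spontaneous
segments complete the ten firing patterns. With drift *d*, trials in
staged epoch *k* use gain multiplier *d*^(k−1).

The raw-voltage path renders spike tables as Gaussian noise plus a
stereotyped biphasic extracellular waveform; detection band-passes at
300–3000 Hz (zero-phase 4th-order Butterworth), estimates the noise SD
robustly as median(|x|)/0.6745, thresholds at 5.5 SD and keeps one
event per supra-threshold excursion with a 2-ms refractory period.

What the simulator does *not* reproduce: real cultures have
heavy-tailed rate distributions, distance-dependent correlations,
electrode drift, stimulation artifacts beyond a clean 10-ms window, and
plasticity far richer than a scalar gain multiplier. Passing tests
therefore validate the *analysis chain* (encoding geometry, estimator
correctness, protocol bookkeeping, statistical power under known
effects), not biological claims.

## Decoding

Artifact blanking removes spikes within 10 ms after *every* pulse in
the trial's program (the conservative reading of "after stimulation").
Counts in ten 200-ms windows per channel are concatenated
channel-major. PCA keeps the smallest component count reaching 95 %
variance (capped at n_samples − 1) unless a fixed count is given;
zero-variance data (the blank control) bypass PCA with an empty
embedding, making the decoder intercept-only. With balanced training
classes that decoder stays at its zero initialization, predicts the
lowest class index deterministically, and scores exactly 10 % on the
balanced 10-pattern test — the blank-control chance floor.

The classifier is the reference-class multinomial logit: P(y=j|x) ∝
exp(xᵀβⱼ) for j < k and the k-th (spontaneous) pattern as reference.
Fitting is full Newton/IRLS on the mean cross-entropy plus a ridge
penalty (10⁻⁶, intercepts unpenalized) that keeps separable data from
driving the MLE to infinity; step-halving guarantees a monotone loss
trace, and convergence is a loss change below 10⁻⁸. The tests verify
the fit against an independent BFGS minimization of the same objective
and against a numeric gradient at the optimum.

By default the protocol refits the decoder per stage (a pooled-training
flag exists): the per-stage reading matches the staged accuracies being
reported per training step.

## Connectivity

STTC uses tiles of half-width 10 ms, merged by interval union and
clipped at the recording edges. Degenerate cases: empty train → 0 with
a warning; denominators clamped away from 0 at 10⁻¹²; the result is
clipped to [−1, 1]. Representative channels are chosen by k-means
(k = 40, 10 restarts) on electrode *coordinates* — preserving spatial
coverage — taking the nearest channel to each centroid (duplicates fall
to the next nearest). Edge significance uses spike-time jitter
surrogates (±50 ms uniform, both trains, default 100 rounds, one-sided
α = 0.05 per pair). Modules come from consensus Louvain (repeated runs
→ co-assignment matrix → 0.5 threshold → recluster until stable, ≤ 10
rounds; negative edge weights are floored at 0 for modularity only).
Within-module degree z-scores use the population SD, with singleton or
zero-spread modules set to 0; the participation coefficient of an
isolated node is 0. Before/after comparisons are Welch t-tests per
metric with mean ± SD and quartile summaries. Note the node-strength
symbol and the module label are distinct concepts here even though some
texts reuse one symbol for both.

## Test and acceptance scales

All fixtures are generated programmatically. Desk-scale choices: the
fixture image set uses 12 images per class; sessions in the test suite
use 32–64 recording channels (the protocol, staging and estimators are
channel-count agnostic; 1024 remains the default for real-geometry
use); connectivity recordings are 120 s with 50 surrogate rounds. The
plasticity demonstration uses weak gains (drive 0.18 expected
spikes/pulse on 15 % of channels, 1.5 Hz background) with drift 1.6, a
regime where stage-1 accuracy starts mid-range and rises across stages;
the training-effect demonstration adds 45 shared-event pairs at 2 Hz
across 30 channels, a clearly supra-threshold coupling. The
acceptance script reports the blank-control stage-1 accuracy, which is
exact (10 %) by the constant-predictor argument above and independent
of these scales.

## Known limitations

- The extractor's training determinism holds within a fixed NumPy/BLAS
  build; across builds, floating-point summation order may differ.
- Louvain consensus on very sparse graphs can yield many singleton
  modules; metrics remain defined (z = 0, P = 0) but carry little
  information there.
- The simulator's evoked model is linear in pulses; saturation,
  adaptation and inhibition are out of scope.
- The jitter-surrogate null preserves rates but not burst structure;
  with strong bursting enabled, surrogate thresholds are conservative.
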