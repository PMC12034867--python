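# Methods

## Problem setting

Atherosclerotic renal artery stenosis (ARAS) alters the renal-artery
spectral Doppler waveform in two characteristic ways: a high-velocity jet at
the stenosis (peak systolic velocity, PSV, classically ≥ 180 cm/s) and a
delayed, blunted *tardus-parvus* upstroke downstream. The pipeline treats
ARAS detection as binary classification of a single beat's outer-envelope
velocity trace, sampled on a common time grid, with the stenotic kidney's
signal as the positive case and the contralateral kidney's signal from the
same patient as the site-matched control.

## Waveform model

One beat of length `heart_period` (s) is modeled piecewise:

- **Upstroke**, 0 ≤ t ≤ `accel_time`:
  `v(t) = edv + (psv − edv) · sin(π t / 2·accel_time)^peak_sharpness`.
  The curve rises monotonically from the end-diastolic velocity (EDV) to
  PSV, reaching the peak exactly at the acceleration time. The exponent
  `peak_sharpness ≥ 1` rounds (low values) or sharpens (high values) the
  peak; a low exponent with a long acceleration time yields the
  tardus-parvus morphology.
- **Decay**, t > `accel_time`:
  `v(t) = edv + (psv − edv) · exp(−(t − accel_time)/τ)` with
  `τ = (heart_period − accel_time)/4`, so the envelope has relaxed to
  within ~2% of EDV by the end of the cycle. The two pieces join
  continuously at the peak.

This is deliberately minimal: two shape parameters reproduce both stenosis
morphologies, and every parameter has a direct physiological reading.
Measurement noise is additive Gaussian on velocity (SD `noise_sd`,
default 2 cm/s), clipped at zero, applied when the analytic beat is rendered
into discrete samples at 2 ms resolution. Beat-to-beat variability,
respiratory modulation, and spectral-broadening artifacts are not modeled —
one beat per signal, matching a workflow in which a single representative
cycle is traced per image.

## Class regimes

Parameters are drawn per signal from truncated normal distributions. The
defaults (mean ± SD [bounds], velocities in cm/s, times in s):

| Parameter | normal | stenosis_jet | tardus_parvus |
| --- | --- | --- | --- |
| psv | 90 ± 15 [50, 160] | 220 ± 30 [150, 350] | 45 ± 10 [25, 90] |
| edv | 25 ± 5 [5, 45] | 60 ± 15 [20, 110] | 15 ± 4 [2, 24] |
| accel_time | 0.05 ± 0.01 [0.02, 0.09] | 0.05 ± 0.01 [0.02, 0.09] | 0.12 ± 0.02 [0.08, 0.25] |
| heart_period | 0.86 ± 0.08 [0.5, 1.4] | same | same |
| peak_sharpness | 2.0 ± 0.3 [1.2, 3.0] | 2.0 ± 0.3 [1.2, 3.0] | 1.3 ± 0.15 [1.0, 1.8] |

Anchors: the normal PSV sits well below and the stenosis-jet PSV well above
the 180 cm/s criterion (≥ 80% of jet draws exceed it); the jet's elevated
EDV reflects the raised diastolic flow through a tight stenosis; the
tardus-parvus regime pairs a blunted peak with a roughly doubled
acceleration time; heart period corresponds to ~70 bpm. Each regime's
bounds are arranged so that `psv > edv` and `accel_time < heart_period`
hold for every draw. The ARAS class defaults to `stenosis_jet` (tracing at
the stenosis site); `tardus_parvus` is available as an alternative regime
for downstream-site studies.

Cohorts are paired by design: each synthetic patient contributes one ARAS
and one normal signal at the same randomly chosen arterial site (origin /
proximal / middle / distal), so label balance is exactly 50/50 — mirroring
the case/contralateral-control study design, and deliberately unlike the
real-world prevalence of ARAS. Patient sex is assigned at the 101/198
female proportion of the reference cohort with a deterministic count.
Randomness flows from one cohort seed through a splittable seed sequence
(one child stream per patient), so per-patient draws are order-independent
and cohorts are bit-reproducible.

### What passing on synthetic data does and does not show

The default regimes are separable — a threshold on peak velocity alone
reaches AUC ≥ 0.9 — so near-perfect test metrics on synthetic cohorts
demonstrate that the pipeline's mechanics (digitization, grouping, training,
evaluation) are correct, not that the classifier would attain comparable
accuracy on clinical data, where class overlap, operator variability and
image-quality effects are all present.

## Digitization

- **Calibration**: two reference points per axis determine an affine
  pixel → physical map per axis; inverted image axes (pixel y grows
  downward) fall out as a negative slope. Coincident reference pixels are a
  degenerate-calibration error.
- **Duplicate timestamps** after mapping (manual traces double back by a
  pixel) are collapsed by averaging; decreasing timestamps are a data error
  naming the offending sample.
- **Beat isolation**: the systolic onset is the last local minimum before
  the first run of 3 strictly increasing samples whose total rise exceeds
  10% of the trace range (both thresholds configurable); the beat runs to
  the sample before the next onset past the peak. A flat trace — no
  detectable upstroke — raises a signal-quality error, the analogue of
  excluding images with inadequate signal extraction.
- **Grid**: 1000 timestamps from 0.1 to 2.5 s inclusive (step 2.4/999 s),
  fixed as a shared constant. Each beat is shifted so its first sample sits
  at 0.1 s and linearly interpolated. A single beat (~0.5–1.4 s) cannot
  fill the 2.4 s window; grid points beyond the last traced time hold the
  final traced velocity. Clamping neither invents data nor distorts beat
  morphology; time-stretching would confound the acceleration-time feature
  and zero-padding would create a spurious step edge.

## Splitting

The 80/20 train/test split and the 5-fold partition are grouped by patient:
both of a patient's signals stay on one side of every boundary. The two
signals share a session, operator and machine, so signal-level splitting
would leak paired information into the test set. A signal-level option
(`group_by_patient=False`) exists for replication studies. The test share
is the nearest-integer patient count (198 patients at 20% → 40 test
patients → 80 signals); fold sizes differ by at most one patient, with
remainders assigned to the lowest-indexed folds. Cross-validation runs on
the 80% training portion only; the held-out 20% is scored by the fold
models solely for the consistency audit and is consumed exactly once by the
final model. An SHA-256 checksum of the test rows taken before CV is
re-verified afterwards.

## Classifier

Three convolution blocks (32, 64, 128 channels; kernel 3, stride 1, same
padding; ReLU; max-pool 2) followed by a flatten, a 128-unit ReLU layer and
a 2-unit softmax head. For 1000-sample inputs the pooled lengths are
500/250/125 and the flattened vector has 16 000 entries. Training uses Adam
(lr 0.001, β₁ 0.9, β₂ 0.999), cross-entropy with mean reduction, batch
size 32 (final partial batch kept), default 500 epochs. No dropout, weight
decay, early stopping or LR schedule. Forward and backward passes are
written directly on NumPy arrays (convolution as one BLAS matmul over
sliding windows), which trains the study-sized problem in minutes on one
CPU core and makes every bit of the computation visible to the test suite.

Numerical and initialization choices:

- Hidden weights: He (fan-in-scaled normal), biases zero. The classifier
  head is initialized at zero, so an untrained network outputs uniform
  class probabilities — exactly uninformative. (A randomly initialized
  head on a zero-bias ReLU network is positively homogeneous in its input
  and therefore acts as an amplitude detector, which is a real, if
  surprising, source of spurious pre-training "skill" on amplitude-separated
  classes.) The head's gradient is nonzero at the first step, so training
  is unaffected.
- Input normalization: per-signal standardization (default), with
  `scale` (divide by 100 cm/s, preserving absolute velocity) and `none`
  (raw velocities) as options. Standardization removes the absolute PSV
  scale; the network still separates the default regimes through residual
  shape and relative-noise differences.
- Kernel size, padding, pooling window and initialization are package
  choices; only the channel progression, the dense sizes, the optimizer
  and its hyperparameters are fixed by the architecture definition.
- Determinism: initialization and the per-epoch shuffling schedule derive
  from the training seed; per-fold seeds derive from the master seed via a
  seeded integer draw (all below 2³¹). Reruns with the same seed are
  bit-identical on one worker.
- The epoch default is 500; the package's scaled-down profile for
  full-pipeline runs and the acceptance script uses 12 epochs at 198
  patients, which is past convergence on the default separable regimes.

## Evaluation

ARAS is the positive class throughout. Accuracy, precision, recall,
specificity and F1 come from exact confusion counts; ratios with zero
denominators are reported as undefined (`None`), never as 0. ROC curves
sweep grouped score thresholds with trapezoidal integration, so the AUC
equals the Mann–Whitney U statistic (half credit for ties) divided by
n₁·n₀. Fold statistics are aggregated as mean, sample SD (k−1), variance
= SD², and the normal-approximation 95% CI mean ± 1.96·SD/√k; with k = 5
folds this interval is approximate and is reported as the convention of the
aggregation table it mirrors, not as an exact small-sample interval.

The consistency audit asks whether the five fold models assign the same
class to the same signal. Each training signal is validated only once
across folds, so the only signal set scored by all five models is the
held-out test set; the audit therefore runs every fold model on the test
signals and reports the fraction with unanimous predictions (this scoring
is diagnostic only — it feeds nothing back into training).

## Problem sizes

The test suite exercises the full pipeline at 15–60 patients with 2–12
epochs, and the separable-cohort recovery check at the study size (198
patients, two signals each) with the 12-epoch profile over three seeds.
The acceptance script runs one full 198-patient analysis (5-fold CV plus
final evaluation) per invocation.

## Known limitations

- Single-beat signals only; no beat-to-beat or respiratory variability.
- The generator produces envelope traces, not spectrograms; image-domain
  effects (aliasing, spectral broadening, wall filter) are out of scope.
- Synthetic classes are parametrically clean; clinical overlap (moderate
  stenoses, poor insonation angles) is not emulated, so reported metrics
  are mechanics checks, not clinical performance estimates.
- The CI formula is a normal approximation over five folds.
- Fold-model agreement is measured on the test set; unanimity depends on
  training length and cohort size, and is expectedly low for undertrained
  smoke profiles.
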