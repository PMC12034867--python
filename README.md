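# renalflow

Detection of atherosclerotic renal artery stenosis (ARAS) from spectral
Doppler waveform envelopes with a 1-D convolutional neural network.

Renal duplex ultrasound is the first-line screen for ARAS, but reading the
spectral Doppler tracing — elevated peak systolic velocity (PSV ≥ 180 cm/s)
at the stenosis, or the delayed, blunted *tardus-parvus* upstroke downstream
of it — requires an experienced interpreter. `renalflow` implements a
complete, reproducible pipeline that classifies single-beat renal-artery
velocity envelopes as ARAS or normal:

1. **Digitization** (`renalflow.digitize`) — replicates a plot-digitizer
   workflow as plain math: two reference points per axis define an affine
   pixel → physical transform, the manually traced outer envelope becomes a
   (time s, velocity cm/s) trace, one cardiac cycle is isolated at the
   systolic upstroke, and the beat is linearly interpolated onto a fixed
   grid of 1000 timestamps spanning 0.1–2.5 s.
2. **Synthetic cohorts** (`renalflow.waveform_synth`) — a parametric
   single-beat waveform generator (raised-power sinusoidal upstroke to PSV
   over the acceleration time, exponential relaxation to EDV) emits
   patient-paired cohorts: each synthetic patient contributes one ARAS
   signal and one site-matched contralateral-normal control, so classes are
   balanced 50/50 by construction. Regimes: `normal` (PSV ≈ 90 cm/s),
   `stenosis_jet` (PSV ≈ 220 cm/s), `tardus_parvus` (PSV ≈ 45 cm/s,
   prolonged acceleration time).
3. **Dataset handling** (`renalflow.dataset`) — the datasheet format
   (`patient_id,label,site,t0001..t1000`), a patient-grouped 80/20
   train/test split, and 5-fold partitioning of the training patients.
4. **Classifier** (`renalflow.cnn`) — a 1-D CNN
   (conv 32 → pool → conv 64 → pool → conv 128 → pool → dense 128 →
   dense 2 → softmax) trained with Adam (lr 0.001, batch 32) on
   cross-entropy, implemented directly in NumPy with full seed determinism.
5. **Evaluation** (`renalflow.evaluate`) — confusion-matrix metrics
   (accuracy, precision, recall, specificity, F1), ROC/AUC, per-metric fold
   aggregation (mean, sample SD, variance, 95% CI = mean ± 1.96·SD/√k), a
   cross-fold prediction-consistency audit, and the final
   train-once/test-once evaluation.

## Worked example

```bash
renalflow run --seed 7 --out runs/demo --n-patients 60 --epochs 12
renalflow report --run-dir runs/demo
```

which prints (numbers produced by the run above):

```
## Test-set metrics

- accuracy: 1.0000
- precision: 1.0000
- recall: 1.0000
- specificity: 1.0000
- f1: 1.0000
- roc_auc: 1.0000

## Cross-validation summary

| Metric | Mean | SD | Variance | 95% CI |
| --- | --- | --- | --- | --- |
| accuracy | 0.8878 | 0.1139 | 0.0130 | 0.7880–0.9876 |
| precision | 0.8694 | 0.1545 | 0.0239 | 0.7340–1.0049 |
| recall | 0.9578 | 0.0579 | 0.0034 | 0.9070–1.0086 |
| specificity | 0.8178 | 0.2482 | 0.0616 | 0.6003–1.0353 |
| f1 | 0.9029 | 0.0859 | 0.0074 | 0.8276–0.9782 |
| roc_auc | 0.9855 | 0.0150 | 0.0002 | 0.9723–0.9987 |

Consistency: 83.3% of test signals received the same class from every fold model.
```

Reading this: the 12 test signals of the held-out 20% of patients were all
classified correctly by the final model (trained once on the other 80%),
while the five fold models — each trained on only ~38 patients — average
88.8% validation accuracy with visible fold-to-fold spread, and agree
unanimously on 83.3% of the test signals. Larger cohorts tighten both (see
below).

The same stages are available as library calls
(`generate_cohort`, `split_train_test`, `make_folds`, `fit`,
`run_cross_validation`, `final_evaluation`) and as individual subcommands
(`synth`, `digitize`, `split`, `crossval`, `evaluate`, `run`, `report`).

## Caveats

The package is developed and validated entirely on synthetic waveforms; the
generator's defaults produce cleanly separable classes, so the headline
numbers here characterize the pipeline's mechanics, not clinical
performance. See `docs/methods.md` for the waveform model, parameter
defaults, numerical choices, and known limitations.
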