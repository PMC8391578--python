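# eegcv

Epoch-based EEG classification for dementia cohorts (Alzheimer's disease,
frontotemporal dementia, healthy controls) with a side-by-side comparison
of the two cross-validation schemes used in this literature — and a
synthetic cohort generator that exposes why one of them lies.

## The problem

Clinical EEG studies routinely cut each recording into short overlapping
epochs, extract per-epoch features, pool all epochs into one table, and
score classifiers with k-fold cross-validation on that table. Because
every subject contributes dozens of epochs, random folds place epochs of
the *same* subject in both the training and the test set. Each person's
EEG carries a stable spectral fingerprint, so the classifier can score
highly by recognizing the subject rather than the disease; accuracies in
the high 90s evaporate when validation holds out whole patients.

This package implements the full pipeline and both validation schemes:

- **Conditioning** — artifact-interval excision, 500 → 250 Hz decimation
  (zero-phase anti-aliasing), 4th-order zero-phase Butterworth band-pass
  0.5–48 Hz.
- **Features** — 5 s epochs every 2.5 s; per channel the energies
  `E_b = Σ_n x_b[n]²` of the five rhythm bands (δ 0.5–4, θ 4–8, α 8–12,
  β 12–25, γ 25–48 Hz, each from a zero-phase Butterworth band filter)
  plus mean, population variance and interquartile range of the broadband
  signal: 8 features × 17 montaged channels + class label = 137 columns.
- **Classifiers** — decision tree (entropy splits with reduced-error-style
  pruning), random forest, MLP, linear SVM, Gaussian naive Bayes, 1-NN.
- **Validation** — pooled stratified 10-fold over epochs (leakage-prone by
  design) vs. leave-one-patient-out (LOPO): iteration *i* holds out all
  epochs of subject *i* of each class (round-robin reuse of the smaller
  class), so train and test subjects are always disjoint. Metrics from
  epoch-level confusion counts, patient class positive:
  accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP); dispersion σ = √(1/N Σᵢ(xᵢ−µ)²).
- **Synthetic cohorts** — per subject, each channel is a mixture of
  band-limited noises with class-level spectral profiles (EEG slowing for
  the patient groups) and subject-level fingerprints (per-band log-power
  offsets, per-channel gains). Class signal and fingerprint strength are
  independent dials, so leakage can be studied in isolation. Cohorts
  round-trip through EDF files.

## Worked example

```python
from eegcv import CohortSpec, ExperimentConfig, run_experiment

spec = CohortSpec(n_per_class={"AD": 2, "CN": 2}, duration_s=60.0, seed=3)
cfg = ExperimentConfig(cohort=spec, classifiers=("decision_tree", "naive_bayes", "knn"), seed=1)
report = run_experiment(cfg)
print(report.table[["problem", "classifier", "kfold_accuracy",
                    "lopo_accuracy", "kfold_minus_lopo"]].round(3).to_string(index=False))
```

prints

```
problem    classifier  kfold_accuracy  lopo_accuracy  kfold_minus_lopo
  AD/CN decision_tree           0.967          0.674             0.293
  AD/CN   naive_bayes           0.978          0.935             0.043
  AD/CN           knn           1.000          0.989             0.011
```

Even on this tiny cohort with a genuine class effect, pooled 10-fold
reads near-perfect for every learner, while LOPO — the estimate of how
the model would do on a *new* patient — is lower and spreads the learners
apart. The `kfold_minus_lopo` column is the leakage inflation.

The same pipeline is driven step by step by the numbered scripts under
`analysis/` (simulate → features → comparison → leakage-null → epoch
sweep; tables land in `results/`), and from the shell via the `eegcv`
CLI (`simulate`, `features`, `validate`, `compare`, `sweep`).

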