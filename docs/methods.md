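# Methods

## Signal model of the synthetic cohorts

Each subject's recording is a C-channel stationary Gaussian mixture of
band-limited noises. For channel c and rhythm band b,

    x_c(t) = g_c · Σ_b √(exp ℓ_b) · n_b(t) + σ_0 · w(t),

where n_b is white noise filtered to band b with the same zero-phase
4th-order Butterworth filter the feature extractor uses (then
variance-normalized), ℓ_b is the subject's log band power, g_c a positive
per-channel gain, and w broadband white noise with relative power
`noise_floor` (default 0.02) times the summed band power. Sharing the
band filters between generator and analyzer is deliberate: the
downstream features are exactly band energies plus moments, so the
generator's parameters are recoverable quantities, not decoration. The
model makes no claim to physiological realism — no 1/f continuum, no
transients, no inter-channel correlation, no artifacts — so passing
tests show that the *pipeline and validation logic* behave correctly,
not that any accuracy level transfers to clinical EEG.

Subject log band powers decompose as

    ℓ_b = m_b + s · (c_b − m_b) + ε_b,   ε_b ~ N(0, σ_subj²),

with c_b the class profile, m_b the grand mean over the cohort's class
profiles, s = `class_effect_scale`, and ε_b the subject fingerprint. The
scale multiplies only the *between-class* differences: at s = 0 every
class has the same expected spectrum (exchangeable labels) while
subjects still differ individually — the configuration that isolates
epoch leakage. The default class profiles encode EEG slowing
directionally (relative shares δ/θ/α/β/γ: CN .14/.12/.36/.28/.10,
AD .32/.26/.18/.14/.10, FTD intermediate); magnitudes are study
parameters, not clinical estimates. Per-channel gains are log-normal
(σ = 0.1), a second, purely spatial fingerprint component.

Cohort defaults mirror the emulated study design: 10 AD / 10 FTD / 8 CN
subjects, 500 Hz sampling, 17 montaged channels (the 16 double-banana
chains plus Fz–Cz; the list is opaque configuration since standard
variants have 16 or 18 derivations), 13 min patient and 21 min control
recordings. Subject fingerprint strength σ_subj defaults to 0.4 on log
band power — roughly ±50% power wobble per band, a visible but not
dominant individual signature. Each subject's sample stream is keyed by
(cohort seed, CRC32 of the subject id), so recordings are reproducible
individually and independent of generation order.

## Conditioning

Pipeline order: artifact-interval excision → decimation → band-pass.
Artifact intervals are inputs (the emulated device marks them; manual
inspection is not reproducible); epoch grids restart inside each clean
segment, so no epoch spans an excised span, and segments shorter than
one epoch are dropped. Decimation to 250 Hz uses an order-8 zero-phase
Butterworth anti-alias low-pass at 0.8× the new Nyquist — needed because
the subsequent 0.5–48 Hz band leaves little margin below 125 Hz. The
conditioning band-pass is a 4th-order Butterworth applied
forward-backward (zero-phase, effective order 8 in magnitude), standard
EEG practice that preserves epoch alignment. Note what a 48 Hz edge of
that order actually buys: |H(50 Hz)|² ≈ 0.39, i.e. mains interference is
suppressed, not annihilated — the tests assert the designed response, not
a folk figure.

## Features

Five-second epochs every 2.5 s (50% overlap; the "2.5 s interval" and
"2.5 s overlap" phrasings coincide at this setting). Per channel: five
band energies (time-domain sum of squares of the band-filtered signal —
absolute, not normalized, since nothing in the emulated protocol
normalizes them; an epoch-relative variant would be a one-line change)
and mean/population-variance/IQR of the 0.5–48 Hz signal. Population
variance (divisor N) matches the dispersion convention used for the CV
summaries. Column order is channel-major
(`<channel>_energy_delta … <channel>_iqr`), label last; subject ids are
carried out-of-band and are never predictors.

In the pipeline the band filters run over each clean segment once and
the band signals are windowed on the epoch grid. Filtering isolated 5 s
windows instead (the `band_energy` primitive, kept for single-epoch use
and oracle tests) inflates delta energy severely — the filter's impulse
response spans several delta cycles, and reflective padding of a short
window is a poor guess of the true continuation, which the segment
actually provides.

## Recovering band shares: the transfer-matrix estimator

Band-energy features are biased estimators of a subject's relative
band-power shares: the conditioning band-pass clips the outer edges of
delta and especially gamma (whose 25–48 Hz span abuts the 48 Hz edge),
and each analysis band filter multiplies the generator's identical
shaping. The bias is fully determined by the declared filter designs, so
`eegcv.recovery` integrates the squared-magnitude responses (|H|⁴ per
zero-phase pass) into a 5×5 band transfer matrix M — diagonal ≈ 0.89
except gamma ≈ 0.74 — and solves Mᵀp = e for the epoch-mean energies e.
Uncorrected shares are off by up to ~13% (gamma); de-biased estimates
land within a few percent of the specified shares.

## Validation schemes

Pooled k-fold: epochs shuffled with a fixed seed and split into k
class-stratified folds ignoring subject identity — deliberately
leakage-prone, as in the practice under study. LOPO: iteration i holds
out every epoch of subject i of each class; with unequal classes the
iteration count is the larger class size and the smaller class is reused
round-robin (i mod n), so each test set contains one subject per class
and every subject is tested at least once. (The emulated study describes
equal 9+9 training sets, which is arithmetically inconsistent with its
8-subject control group; round-robin pairing is this package's choice,
and an all-ordered-pairs scheme would be a straightforward alternative.)
Metrics come from epoch-level confusion counts with the patient class
positive; undefined ratios (empty denominator) are NaN, never silently
zero, and summary means skip NaN folds. Fold dispersion is the
population SD (divisor N).

Classifier configuration, where the emulated protocol is silent, follows
era-typical defaults: C4.5-style entropy tree with reduced-error-style
pruning (cost-complexity strength selected on a held-out third of the
training data, refit on all of it); random forest with 100 trees and
√p features per split; MLP with one hidden layer of
(n_features + n_classes)/2 units, ≤500 iterations, seeded; linear SVM
with C = 1; Gaussian naive Bayes; 1-NN. Features are standardized with
training-fold statistics only, and only for the scale-sensitive learners
(MLP, SVM, kNN) — fitting a scaler on pooled data would be a second
leakage channel. A "maxFolds = 8" forest setting reported for the
emulated study has no counterpart in standard random forests and is not
emulated.

## Study protocols and problem sizes

The canonical demonstrations (`eegcv.protocols`, also driven by the
`analysis/` scripts and `scripts/acceptance.py`) use desk-scale cohorts
chosen so each subject contributes ≈50–120 epochs, which is where the
leakage effect lives:

- **Leakage null** — 5+5 subjects (AD/CN), 300 s each,
  class_effect_scale = 0, σ_subj = 0.8 (strong fingerprints, the regime
  that makes the point sharply). Pooled 10-fold reaches ≥0.98 for trees,
  forests and 1-NN; LOPO hovers at chance. The chance band is
  0.5 ± 3·√(0.25/n_subjects): under the null each held-out subject is
  classified essentially en bloc, so the independent unit is the subject,
  not the epoch. Subject outcomes still share the cohort's fingerprint
  geometry, so the band is approximate — a single cohort draw can push
  one learner slightly outside it.
- **Scheme ordering** — 4+4 subjects, 150 s, class_effect_scale ∈
  {0, 0.5, 1}, all six classifiers: mean k-fold accuracy ≥ mean LOPO
  accuracy throughout. At strong effect scales both schemes approach
  ceiling and the gap collapses toward zero (occasionally an epsilon
  tie), which is itself informative: leakage inflation is largest
  exactly when the true class signal is weak — the regime where inflated
  claims are most misleading.
- **Parameter recovery** — one fingerprint-free subject per class, 60 s;
  transfer-matrix-corrected shares within ±10% of specification.
- **Filter selectivity** — unit tones at 2/6/10/18/35 Hz place ≥95% of
  summed band energy in δ/θ/α/β/γ respectively, cross-checked against
  FFT peak location and Parseval's identity.

## Numerical choices and degeneracies

Zero-phase filtering uses `sosfiltfilt` with its default reflective
padding. EDF export quantizes to 16 bits against a per-channel symmetric
physical range (error ≤ 1 digital step; features round-trip to ~10⁻³
relative), truncates to whole seconds, and stores subject/class in the
patient field; artifact intervals travel in a sidecar CSV, not EDF+
annotation streams. Ties in tree pruning prefer the stronger pruning. A
k-fold training split missing a class skips that fold with a warning;
LOPO requires ≥2 subjects per class and refuses otherwise. All
randomness flows from integer seeds through `numpy` `SeedSequence`;
protocol sub-seeds are derived with distinct salts.

## Known limitations

Synthetic recordings are stationary and channel-independent; leakage here
is spectral fingerprinting only, whereas clinical epoch leakage also
rides on artifacts, electrode placement and session effects — if
anything, real leakage is worse. Accuracy magnitudes on synthetic
cohorts are not comparable to clinical values; only the structural
contrast between validation schemes is the object of study. Three-way
classification, sub-band splits (α1/α2, β1–β3) and automatic artifact
detection are out of scope.
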