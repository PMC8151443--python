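# Methods

`sleepband` implements an automatic sleep-staging pipeline for two-channel
forehead ("headband") EEG: preprocessing, rule-based artifact cleaning,
overlapping-window training augmentation, a CNN+LSTM per-epoch classifier,
a hand-crafted-feature bagged-trees baseline, and leave-one-subject-out
(LOSO) evaluation. Because the clinical recordings this kind of pipeline is
built for are typically private, the package ships a seeded synthetic
cohort generator that reproduces the statistical features the pipeline
actually depends on; all shipped tests run against it.

## Preprocessing

Recordings (2 channels, µV, any rate ≥ 50 samples/s; the simulator uses
500 samples/s) are band-pass filtered to 0.5–12 Hz with a windowed-sinc
(Hamming) FIR, built as a cascade of a high-pass with 0.5 Hz transition
width and a low-pass with 2 Hz transition width, applied in a single
forward pass with group-delay compensation (linear phase, so compensation
is exact). The Hamming window gives ≈53 dB stopband attenuation and
passband ripple well inside ±5%. Filtering happens at the native rate, so
the 12 Hz cutoff doubles as the anti-alias filter; the signal is then
resampled to 25 Hz by a rational polyphase factor and cut into
nonoverlapping 30-s epochs of 750 samples aligned with the hypnogram
(epoch `i` ↔ `[30i, 30(i+1))` s, 0-based; trailing partial epochs are
discarded; epochs overlapping user-supplied exclusion intervals are
dropped together with their labels, and surviving epochs keep their
original temporal indices so later stages can detect the gaps).

## Artifact cleaning

Headband channels mirror each other when both electrodes make contact, so
a clean epoch shows high inter-channel Pearson correlation and
physiological amplitude. An epoch is flagged as corrupted iff its
correlation falls below `min_correlation` (default 0.9) **and** the mean
absolute amplitude of at least one channel exceeds `max_amplitude`
(default 40 µV). Design choices the rule's verbal description leaves open:
"mean amplitude" is the mean absolute value of the band-passed 25 Hz
epoch (closer to the "ordinary EEG stays below 100 µV" framing than RMS or
peak); correlation is signed Pearson; a zero-variance channel is assigned
correlation 0 rather than raising. Repair duplicates the lower-amplitude
(valid) channel over the corrupted one; if both channels exceed the
amplitude threshold there is nothing to copy and the epoch is dropped.
The rule applies to headband data only — PSG epochs are refused without an
explicit override. A grid search over correlation {0.6, 0.7, 0.8, 0.9} ×
amplitude {30, 40, 50, 60} µV (16 combinations) is provided with an
injected objective `eval_fn`, because the reference objective — mean LOSO
accuracy of the deep model per combination — is far outside interactive
budgets; tests exercise the grid with a cheap ground-truth-based score.

## Overlapping-window augmentation

Contiguous same-stage 30-s epochs are concatenated and re-sliced into
30-s windows whose starts are multiples of `30·(1−overlap)` s, aligned to
the block start (at 25 Hz the 75%-overlap step of 7.5 s is 187.5 samples;
starts are rounded to the nearest sample). Only fully contained windows
are kept, so a run of `L` epochs yields `floor((30L−30)/step)+1` windows
(`4L−3` at 75%). Runs break at stage changes, subject changes and index
gaps left by exclusions or dropped epochs, so no window ever spans a
transition or discontinuity. Augmentation refuses arrays marked as
validation folds: windows overlapping 75% with their neighbours would
otherwise leak information across the fold boundary.

## CNN+LSTM classifier

The network maps one 750×2 epoch to a 5-class softmax over
(W, N1, N2, N3, REM): three convolution blocks (8/16/32 filters doubling
layer-to-layer, kernel 7, stride 1, ReLU, non-overlapping max-pool 4)
produce an 11-step × 32-feature sequence that is passed — never
flattened — to two 64-unit LSTM layers (first returns sequences, second
its final state) and a dense softmax head. Dropout 0.2 is applied to both
LSTM outputs during training; every weight matrix carries an L2 penalty
of 0.001. Exact convolution hyperparameters (kernel 7, pool 4) are this
package's choice; any setting that keeps ≥2 time steps entering the
recurrent stack preserves the architecture's intent.

The network is implemented directly in NumPy — im2col convolutions,
unrolled LSTM, analytically derived backward passes (verified against
finite differences in the test suite) and an Adam optimizer. At this size
(~90k parameters) CPU training runs at ~30 ms per 64-sample batch, which
keeps full LOSO experiments on the synthetic cohort in the minutes range.

Training minimizes class-weighted categorical cross-entropy
`L = −w_c·log p_c`. Two weighting modes exist because the natural-language
definition of the weight ("the relative frequency of the label") would
*amplify* majority-class bias rather than correct it, contradicting the
weighting's stated purpose: `relative_frequency` implements that literal
definition (`w_c = n_c/N`), and `inverse_frequency` — the default —
implements the correction the weighting is for (`w_c ∝ N/n_c`, normalized
to mean 1). Reference optimizer settings are Adam with learning rate
5·10⁻⁵, β₁ = 0.99 (as specified, although 0.9 is conventional),
β₂ = 0.999, batch 64, 200 passes, no early stopping. Desk-scale runs
(`DESK_SCALE_TRAIN`) use 30 passes at learning rate 10⁻³, an appropriate
rate for the shortened schedule. Inputs are divided by a fixed 20 µV scale
rather than per-epoch standardized, so between-stage amplitude differences
(N3's high-amplitude slow waves) remain visible to the network. All
randomness (initialization, shuffling, dropout) derives from the training
seed; runs are bit-reproducible.

## Baseline feature bank

62 features per channel in 8 groups. The group names and cardinalities are
fixed (11 + 15 + 3 + 3 + 1 + 1 + 20 + 8); the formulas are this package's
documented, test-pinned definitions:

* **RSP (11)** — relative spectral power in 11 equal-width bands spanning
  0.5–12 Hz (Welch, 4-s Hamming windows, 50% overlap); sums to 1.
* **HP (15)** — per sub-band (0.5–4, 4–6, 6–8, 8–10, 10–12 Hz): spectral
  center frequency, bandwidth (power-weighted standard deviation around
  the center) and the PSD value at the center frequency.
* **SWI (3)** — slow-wave power ratios δ/θ, δ/α, δ/(θ+α) with δ = 0.5–4,
  θ = 4–8, α = 8–12 Hz.
* **Hjorth (3)** — activity (variance), mobility, complexity, with
  derivatives as first differences scaled by the sample rate.
* **Skewness, Kurtosis (1+1)** — standardized 3rd/4th central moments
  (kurtosis non-excess).
* **Bi-Spectrum (20)** — direct bispectrum estimate (4-s Hamming
  segments, 50% overlap) on the principal domain below 12 Hz: mean
  magnitude, normalized bispectral entropy, squared entropy,
  log-magnitude sums over the domain and its diagonal, first and second
  spectral moments of the diagonal (7), plus mean magnitude over a
  13-strip partition of the domain by first frequency (13).
* **Wavelet (8)** — relative energies of D1–D7 and A7 from a 7-level
  Daubechies-4 DWT (level 7 exceeds the advisory maximum for 750 samples;
  the boundary-affected deep levels are part of the pinned definition).

Epochs are demeaned before extraction, making every feature exactly
invariant to DC offsets. Degenerate inputs (zero variance) produce finite
features (ratios and entropies fall back to 0). Features are min–max
scaled to [0, 1] with ranges fitted on the training fold only; constant
features map to 0 and out-of-range validation values are clipped. The
classifier is a 100-tree bootstrap-aggregated decision-tree ensemble
(scikit-learn's `BaggingClassifier`; prediction ties resolve by class
order, scikit-learn's convention).

## Evaluation protocol

LOSO cross-validation: each subject in turn is held out; the remaining
subjects are cleaned (headband data only), pooled, augmented, and train a
fresh classifier; the held-out subject is cleaned with the same thresholds
— corruption is a property of the recording, not of the fold — but never
augmented. Fold aggregation reports the unweighted mean ± population
standard deviation across folds. Per-stage recall is
`100·correct_c/true_c`; balanced accuracy is the arithmetic mean of the
per-stage recalls, with stages absent from the truth excluded (and a
warning raised). Per-fold seeds derive deterministically from the
configured seed.

**Band probing** re-filters held-out epochs into δ (0.5–4 Hz),
θ (6–8 Hz — the printed definition, leaving 4–6 Hz unassigned) and
α+β (8–12 Hz, truncated by the passband) using the same FIR machinery,
and passes them through the already-trained model; weights are untouched.

**Covariate-shift check**: a logistic-regression origin classifier on log
absolute band powers (11 bands per channel — absolute, not relative, so a
pure gain shift between devices remains visible), scored by 5-fold
cross-validation with contiguous per-set folds. Contiguous folds keep
temporally neighbouring (and, in the degenerate identical-sets sanity
case, duplicated) epochs on one side of each split; shuffled folds would
let the classifier anti-predict duplicated epochs and score below chance.
Accuracy ≈50% means the two sets are distributionally alike; near 100%
flags a strong shift.

## Synthetic cohort generator

The generator emulates exactly the properties the pipeline consumes:

* **Hypnogram** — a 5-state Markov chain `P = a·I + (1−a)·1πᵀ` with
  `a = 0.88` and π the clinical stage distribution (W 22.45%, N1 6.95%,
  N2 47.86%, N3 11.07%, REM 11.66%). Any such mixture leaves π stationary
  while raising every self-transition above 0.85, so stages occur in
  multi-epoch runs — the structure overlapping-window augmentation needs.
* **Signals** — per contiguous same-stage run (so same-stage neighbours
  are seamless), as sums of band-limited Gaussian noise shaped in the
  frequency domain; band power fractions are exact in expectation.
  Default spectra: W alpha-dominant (70% in 8–12 Hz), N1 theta-dominant,
  N2 theta plus a narrow 11.5–12 Hz spindle surrogate (true 12–14 Hz
  spindles are truncated by the passband), N3 delta-dominant (90% in
  0.5–4 Hz) at double amplitude (30 µV RMS vs 15–20 µV), REM mixed
  4–10 Hz. Apart from N3's amplitude, stages share the same RMS so stage
  identity is carried by spectral shape, not gain — the premise of the
  band-probing analysis. Channels share one source plus independent
  same-spectrum noise at 10:1 amplitude, giving clean-epoch correlations
  ≈ 1/(1+0.1²) ≈ 0.99.
* **Corruption** — a chosen fraction of epochs (drawn exactly, without
  replacement) has one channel replaced by 150 µV RMS artifact noise,
  band-limited to ≈0.5–10 Hz so its amplitude survives the preprocessing
  band-pass and stays detectable at the 40 µV rule threshold; a
  `rail_drift` variant produces clipped slow drift. Ground-truth indices
  are returned for evaluating the cleaning rule. No quantitative artifact
  statistics exist for the real recordings, so these defaults are chosen
  for testability, not fidelity.
* **Device shift** (optional) — a PSG rendering (the shared source) and a
  headband rendering (gain ×1.2 plus 5 µV in-band broadband noise) of the
  same underlying signal, for demonstrating the covariate-shift check.

What the generator does **not** emulate: K-complexes and true spindles,
ocular/muscle/cardiac artifacts with physiological structure, EOG/EMG
channels, non-stationarity within stages, inter-subject spectral
variability. Passing tests therefore demonstrate that the pipeline's
machinery is correct and can recover cleanly separable stage structure —
not that it reaches any particular accuracy on clinical recordings, where
stage spectra overlap heavily (most visibly for N1).

## Problem sizes and numerical choices

Desk-scale experiments use a 6-subject, 2-hour-per-subject cohort
(240 epochs each) and 30 training passes — sizes chosen so a full LOSO
experiment completes in minutes on one CPU while still exercising every
pipeline stage; the reference protocol (12 subjects, overnight recordings,
200 passes) is a configuration change, not a code change. Probabilities
are clipped at 10⁻⁷ before logarithms; softmax is computed with max
subtraction; the network trains in float32 (float64 available via
`ModelConfig.dtype`, used by the gradient-check tests); argmax ties
resolve toward the earlier stage in (W, N1, N2, N3, REM). EDF export
quantizes to 16 bits over a symmetric physical range scaled to the
signal's peak.

## Known limitations

* The bispectrum and harmonic-parameter feature definitions are plausible
  standard constructions pinned by tests, but other definitions matching
  the same group cardinalities exist.
* The cleaning grid search and overlap selection expose injected
  objectives rather than bundling the full deep-learning LOSO objective.
* The EDF writer covers continuous 2-channel µV signals with integer
  sample rates only.
* Training the reference 200-pass configuration on overnight cohorts is
  possible but slow in pure NumPy (hours, not minutes).
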