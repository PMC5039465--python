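# Methods note

This document records the model implemented by `mivote`, every default
parameter with its rationale, the scope of the synthetic generator, the
numerical choices, and the known limitations.

## Signal model

A trial is a 7-s epoch of 15-channel EEG sampled at 250 Hz, cue at
t = 3 s, labelled LH (left hand), RH (right hand) or F (foot). The
discriminative physiology is event-related desynchronization (ERD):
imagery attenuates the mu (~8–12 Hz) and beta (~18–32 Hz) rhythms over
the contralateral sensorimotor cortex — RH over C3, LH over C4, F over
the vertex Cz.

## Pipeline stages and parameters

### Surface Laplacian (`preprocessing.surface_laplacian`)

Hjorth small Laplacian: each center channel minus ¼ of each of its four
nearest neighbours (weights sum to the negated center weight, enforced).

- Centers C3, Cz, C4; neighbour map:
  C3 ← FC3, CP3, C1, C5; Cz ← FCz, CPz, C1, C2; C4 ← FC4, CP4, C2, C6.
- The default montage lists 15 channels: the 3 centers, their 10
  distinct neighbours (C1 and C2 are shared), and 2 midline background
  channels (Fz, Pz) that carry noise and take no part in the Laplacian.

### Band-pass filtering (`preprocessing.bandpass`)

Elliptic IIR, order 4, applied zero-phase (forward–backward,
`sosfiltfilt`) by default; a causal mode exists for streaming-style use.

- Sub-bands 8–18 Hz (mu and low beta) and 18–32 Hz (beta) feed the AR
  features; band edges are validated against Nyquist.
- Passband ripple **0.25 dB**, stopband attenuation 40 dB. Zero-phase
  application squares the magnitude response, doubling both numbers: the
  effective characteristic is ≤0.5 dB ripple / 80 dB attenuation, and a
  passband tone keeps ≥94 % of its amplitude. A 0.5 dB design would lose
  ~11 % of passband amplitude after the forward–backward pass.

### Analysis window (`preprocessing.extract_window`)

`start = anchor + offset`, `length` seconds (`round(length·fs)` samples).
Defaults: anchor 3 s (the cue), offset 0 (bounded to ±0.5 s), length 2 s
(bounded to 1–3 s). Windows that leave the trial raise an error naming
the computed sample range; sweeps record such cells as NaN.

### Spectral features (`spectral`)

Short-time FFT with 64-sample Hamming segments, hop 32 (50 % overlap);
at 250 Hz a segment spans 0.256 s. Per channel and band (default
8–34 Hz, half-open bin membership `[low, high)`): the mean amplitude
over segments × bins, and the circular mean of the phases. 3 channels ×
1 band × 2 quantities = 6 features. Zero-amplitude bins take phase 0 by
convention.

### Phase-space / AR features (`psr_ar`)

Each band-passed surrogate channel is embedded by time delays with
dimension m = 3 and delay τ = 6 samples, giving a trajectory matrix with
exactly M = N − (m−1)τ rows. An order-6 Burg AR model
(`statsmodels.regression.linear_model.burg`, sign convention
y(t) = Σ αᵢ y(t−i) + ε, mean removed) is fitted to each embedding
column; the 6 coefficients are averaged per column. 3 channels × 2
bands × 3 dimensions = 18 features; combined feature vector = 24.
A constant input yields zero coefficients with a warning rather than an
error.

### Feature selection (`selection.sffs`)

Sequential forward floating selection per class pair: add the argmax
candidate if it strictly improves the criterion J, then repeatedly
remove the argmax-removal feature while removal strictly improves J.
Criterion values are memoized on frozensets; ties break to the lowest
feature index for determinism; the J-trace is strictly increasing, which
guarantees termination. `max_features` defaults to 25.

The criterion is stratified 5-fold inner-CV accuracy of the pair's
binary classifier. The empty subset scores the majority-class rate (not
zero), so class-blind features can never beat the baseline and an
uninformative matrix selects nothing.

### Classification (`classification`)

Three binary classifiers, one per pair (LH/RH, LH/F, RH/F), each on its
own selected features:

- `multi-lda` (default): `LinearDiscriminantAnalysis(solver="lsqr",
  shrinkage=1e-6)` — the tiny shrinkage regularizes the pooled
  covariance when few features are selected.
- `multi-svm`: linear SVC, C = 1.0.
- `knn`: a single multi-class k-NN (k = 5) on the full feature vector,
  as a baseline that skips pairing and selection.

The vote table: LH iff both LH-capable pairs say LH; likewise RH and F;
the 2 of 8 inconsistent combinations are rejected as NONE. NONE counts
as an error (the accuracy denominator never shrinks).

### Evaluation (`evaluation`)

Stratified k-fold CV (default k = 9). Feature extraction is trial-local,
so it runs once; selection and fitting run inside each training fold
only (verified by a no-leakage test hashing the fitted coefficients).
The total trial count must divide by k and k may not exceed the smallest
per-class count; 216 balanced trials at k = 9 give 24 test / 192
training trials per fold.

- kappa = (Pr(a) − Pr(e)) / (1 − Pr(e)) with Pr(e) = 1/3 for three
  balanced classes.
- ITR = L·[p·log₂p + log₂N + (1−p)·log₂((1−p)/(N−1))] bits/min, with
  0·log 0 = 0, evaluated literally (p = 1/N gives 0, p = 1 gives
  L·log₂N).
- Sweeps: offset −0.5…0.5 s step 0.1 × window 1…3 s step 0.2
  (11 × 11 = 121 cells); frequency-band sweeps vary the FFT band with
  the AR bands fixed and vice versa. Invalid cells are NaN, never
  silently dropped.

## Synthetic generator scope

`mivote.synthetic.generate_session` emulates the statistical structure
the pipeline exploits and nothing more:

- Per channel: white + 1/f noise (σ = 2 µV, 70/30 mix).
- Per center electrode: a mu oscillator (frequency uniform in 9–12 Hz,
  random phase, amplitude 5 µV ± 10 % jitter) plus a beta oscillator
  (19–25 Hz) at half amplitude, bleeding at 50 % into the Laplacian
  neighbours.
- During imagery the class-mapped electrode's mu amplitude is scaled by
  √(1 − erd_depth) (so band power drops by `erd_depth`); beta is
  co-modulated at half depth. Transitions use 50-ms cosine ramps.
- Deterministic given the config seed.

It deliberately omits: eye/muscle artifacts, inter-trial
non-stationarity, volume-conduction mixing beyond the neighbour bleed,
ERS rebound after imagery, and any inter-subject variability. Results on
it characterize the pipeline, not human BCI performance.

## Verification summary

The test suite pins every stage to an independent oracle: a brute-force
indexing oracle for the embedding, an O(n²) tapered-DFT oracle (1e-9
relative) for the STFT, known-coefficient AR processes for Burg,
planted-feature instances (verified optimal by exhaustive search) for
SFFS, and exact identities for the metrics. End to end, on 60 trials per
class: ERD depth 0.8 gives ≥90 % 9-fold accuracy (measured 95.6 % at
seed 7, 96.7 % at seed 1), depth 0 gives chance level, accuracy is
monotone in depth, and the window-placement sweep peaks at offset 0 /
length 2 s when imagery occupies t ∈ [3, 5] s.

`scripts/acceptance.py` recomputes these numbers from scratch for any
seed. Its sweep uses a 5 × 5 grid (offsets ±0.4 step 0.2, windows 1–3 s
step 0.5, 4 folds, SFFS off) rather than the full 121-cell grid — a
runtime choice only; the full grid is available through
`evaluation.sweep_offset_window` defaults. At small trial counts
(≈20/class) the sweep argmax is dominated by fold noise; 60 trials per
class resolve it cleanly.

## Limitations

- Offline only; no online/streaming adaptation (causal filtering exists
  but latency handling does not).
- The GDF import path is a thin adapter over `mne` and is untested
  against real recordings in this repository (no GDF fixtures can ship).
- Circular-mean phase features are near-chance on the synthetic data
  (random per-trial phases carry no class information); they are kept
  because the feature definition includes them and SFFS discards them
  when unhelpful.
- The ITR formula is evaluated literally from its definition; it assumes
  uniform priors and symmetric errors.
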