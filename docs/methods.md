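# Methods

## Paradigm model

A selection presents `n_repetitions` (default 15) independent
*blocks*; each block intensifies every one of the 12 symbols exactly
once in uniformly random order. Blocks are concatenated without a gap:
consecutive onsets are separated by exactly one stimulus-onset
asynchrony (SOA = 100 ms flash + 75 ms blank = 175 ms), so onsets are
`k · 0.175 s` and a selection lasts 12 × 0.175 × 15 = 31.5 s. No
constraint is placed on symbol repeats across block boundaries — a
symbol ending one block may open the next; this is the simplest model
consistent with independent per-block randomization. Onset marks flash
*start*, and all epoching is referenced to it.

The target prior per flash is `1/n_symbols` for single-symbol flashing
and `2/(n_rows+n_cols)` for row/column flashing (each selection lights
the target's row once and column once out of `n_rows+n_cols`
intensifications). The row/column scheme exists for prior computation
and simulator contrasts only; decoding always uses single-symbol
schedules.

## Synthetic EEG

The generator emulates the recording conditions the decoder was designed
for: 250 Hz, 8 channels (Fz, Cz, P3, Pz, P4, PO7, PO8, Oz — the montage
is an assumption, configurable; the requirement is only "Pz and nearby"),
and a positive ERP ≈300 ms after each target flash.

* **Template** — a raised-cosine bump: smooth, non-negative, compactly
  supported, one width parameter (default 300 ms full width), peaking at
  300 ms. Real P300s have asymmetric rise/fall and accompanying N200;
  none of that is modeled, so template-shape-specific claims do not
  transfer to real data.
* **Amplitude model** — peak amplitude is
  `base · (prior/(1/12))^(−γ) · familiarity`, with `base` 5 µV, exponent
  γ = 0.5 (amplitude grows as targets get rarer; the anchor makes the
  default paradigm the unit case), and `familiarity` = 1.15 on the
  numbers display, 1 otherwise. The exponent and familiarity gain are
  free parameters chosen to reproduce the *qualitative* prior and
  display effects; no quantitative amplitude claim depends on them.
* **Topography** — fixed per-channel gains (0.4, 0.7, 0.8, 1.0, 0.8,
  0.6, 0.6, 0.5), parietal-midline dominant with Pz = 1. No volume
  conduction or inter-channel noise correlation.
* **Latency jitter** — Gaussian, SD 20 ms, truncated at ±3 SD, drawn per
  target flash.
* **Noise** — white (default), 1/f ("pink"), or AR(1), zero mean,
  per-channel SD 10 µV (realized SD calibrated exactly for the colored
  models). Non-target flashes evoke nothing. There are no blinks, EMG,
  line noise, or non-stationarities, which is the main reason simulated
  accuracies exceed typical human performance at the defaults.
* **Determinism** — signal jitter is drawn before background noise from
  the same generator, so two runs with the same seed and different
  amplitudes share their noise exactly; the difference of such runs
  equals the injected template train to machine precision (tested).

With 175 ms SOA and 800 ms epochs, a target flash bleeds into the epochs
of the four following flashes at fixed relative latencies; this overlap
is physical and left in place.

## Preprocessing

Third-order Butterworth bandpass, 0.1–25 Hz, designed in second-order
sections and applied to the *continuous* recording (keeping edge
transients out of epochs). Default is zero-phase forward–backward
filtering, which doubles the effective order and preserves the 300 ms
peak latency; a causal single-pass mode exists for online-realism
experiments (it delays the peak). Baseline correction defaults to off —
the 0.1 Hz high-pass already removes drift. Epochs are
`[onset, onset+800 ms)` at 250 Hz → 200 samples/channel, concatenated
channel-major into 1600-dim feature rows; no decimation.

## Decoding

Detectors score epochs continuously rather than emitting hard labels:
random forest and kNN report the target-class probability (fraction of
trees / neighbors), SVM and LDA their decision function. Defaults:
100 trees; linear SVM with C = 1 and standardized inputs; LDA with
automatic shrinkage (lsqr); kNN with k = 5 and standardized inputs;
seed 42. Class weighting defaults to balanced because each selection
yields 15 target vs 165 non-target epochs and an unweighted detector can
collapse to the majority class.

Evidence aggregation is the *mean score* per symbol over the first
`n_repetitions_used` flashes of that symbol, argmax over symbols, ties
broken to the lowest index. Mean continuous scores were chosen over
hard-vote counting because they degrade gracefully at few repetitions;
for one repetition the rule provably reduces to the argmax over that
block's 12 epoch scores (tested against brute-force enumeration).

The session protocol mirrors the intended use: a training session of 10
selections (all 1800 epochs labeled) fits the detector; test selections
are freshly simulated, so no epochs leak between sessions. Simulated
subjects differ by seed; the detector is calibrated on the primary
display and applied unchanged to both.

## State machine

`HomeState` is immutable; `apply_selection` returns a new state and
appends exactly one log record, which makes any logged sequence replay
to an identical state (property-tested). Digits-while-calling are
explicit no-ops; a completed call does *not* auto-return — hanging up
requires the `return` cell, the conservative reading of the display
design. The appliance command map is a configurable default; only the
phone-call entry is structural.

## Evaluation

Accuracy is `100 · correct/total`; per-subject tables carry
primary/secondary/average columns with a mean row, reported at two
decimals (half-up). Display contrast is mean secondary minus mean
primary, in percentage points. The information-transfer rate is the
Wolpaw formula (bits/selection × 60/T), with P = 1 handled as `log2 N`.
ITR is plumbing: the study protocol reports selection time and accuracy,
and ITR is the field's standard summary of the two.

## Problem sizes and numerics

Monte-Carlo checks use: 500 zero-amplitude trials for chance-level
calibration against the exact binomial 99% interval around 1/12; 200
default-condition trials for high-SNR recovery (≥95% at 15 repetitions)
and for the repetition-monotonicity curve (per-trial epoch scores are
computed once and re-aggregated at every truncation 1..15, which removes
between-depth sampling noise); 60 trials per noise level (σ = 40, 20,
10 µV) for SNR monotonicity, with a 2.5-standard-error slack on adjacent
comparisons. Filter contracts are checked against the designed
Butterworth frequency response; steady-state attenuation is measured by
projecting the filtered signal onto the stimulus frequency, because the
slow 0.1 Hz edge transient otherwise dominates the 50 Hz residual.

EDF export quantizes to 16 bits over a symmetric per-channel range and
zero-pads the final one-second record; the true sample count travels in
the event sidecar and reading (via mne's EDF parser) trims the padding.
Round-trip error is bounded by range/65534 per sample.

## Known limitations

Simulated performance at the defaults saturates near 100%, above the
~92% human average the paradigm was designed around, because the noise
model is clean and stationary. The generator supports no artifacts,
32-channel montages, or inter-channel correlation. Dynamic stopping
(adaptive repetitions) and deep-learning detectors are out of scope.
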