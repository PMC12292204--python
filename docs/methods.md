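# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind `eegcam`, and what its green tests do and do not establish.

## 1. The classification problem

Epoched task EEG (60 channels × 320 samples, −80…1200 ms at 250 Hz, MSIT
and Sternberg conditions) is classified at the *trial* level into
non-carriers (N) vs. single-risk carriers (A+P−) of Alzheimer's-related
genotypes. The dual-risk group (A+P+) never enters training; after each
cross-validation iteration the trained model predicts its trials and the
fraction predicted as risk (its sensitivity) measures generalization. The
premise being probed is neurophysiological: risk carriers show additional
θ (4–8 Hz) and α (8–13 Hz) oscillatory power over parietal and temporal
cortex, non-carriers more frontal activity.

## 2. Architecture

Seven layers, ~35k parameters:

| stage | operation | shape out |
|---|---|---|
| 1 | pointwise conv, S=16 spatial filters over 60 channels (+bias) | (N,16,1,320) |
| 2 | depthwise temporal conv, D=2 kernels of length L=64 per demixed channel, valid, no bias | (N,32,1,257) |
| 3 | ReLU | (N,32,1,257) |
| 4 | batch norm (ε=10⁻⁵, momentum 0.1) | (N,32,1,257) |
| 5 | global average pool over time | (N,32) |
| 6 | dense | (N,2) |
| 7 | softmax (implemented as log-softmax feeding NLL) | (N,2) |

Decisions where the design was open:

- **Grouping of stage 2.** The temporal convolution is truly depthwise
  (groups = S = 16), which is what makes each feature map attributable to
  exactly one demixed channel — the property the relevance reconstruction
  relies on. A general grouped convolution (any divisor of S) is
  implemented and configurable, but relevance mapping refuses non-depthwise
  configurations rather than produce an ill-defined attribution.
- **Initialization**: uniform fan-in scaling, zero biases, seed-controlled;
  batch-norm γ=1, β=0. Conventional and reproducible.
- **Biases**: on the pointwise stage, none on the depthwise stage (both
  configurable).
- **No input normalization**: the model consumes raw µV; batch norm absorbs
  scale. A scale-equivariance property (input ×a with compensated running
  statistics ⇒ identical relevance) is tested; it is exact only as the
  batch-norm ε becomes negligible against the rescaled variance.

All linear algebra is numpy; the grouped convolutions and their gradients
use FFT convolution (`scipy.signal.fftconvolve`), verified against
finite-difference gradients (relative error < 10⁻⁸) and a nested-loop
forward oracle.

## 3. Training and cross-validation

Adam (β₁=0.9, β₂=0.999, ε=10⁻⁸), lr 10⁻³, batch 64, NLL loss, ≤200 epochs.
Early stopping: "improve" means *strictly greater* validation binary
accuracy than the best seen; ties do not reset patience (20); the best
epoch's weights are restored. The validation set used for early stopping is
the same held-out-subject set used for fold metrics — an optimism that is
inherent to the protocol described and is noted here rather than hidden.

Leave-p%-subjects-out CV: p defaults to 0.20 (a conventional value that
leaves ≥3 validation subjects per group at the study's cohort sizes),
stratified *within* each training group so both classes always appear in
validation (otherwise AUC/κ are undefined). Each fold seed (42…141)
deterministically spawns three sub-seeds — subject split, weight
initialization, batch shuffling — so a fold is exactly reproducible. Folds
with a single-class validation set are flagged invalid, logged, and
excluded from summaries but never dropped from the results file. The "ALL"
condition pools MSIT and STMT trials of the same subjects under the same
splits; "MSIT"/"STMT" filter trials, not subjects.

Metrics are self-contained: rank-based ROC AUC (midrank tie handling),
Cohen's κ from argmax predictions at the softmax 0.5 threshold, sensitivity
tp/(tp+fn) with A+P− as the positive class. κ with fully degenerate
marginals is reported as 0 with a warning. Landis–Koch bands are applied to
κ rounded to two decimals, left-closed ([0.21, 0.40] → "fair"). Note that a
published summary in this line of work tabulates κ = 2·AUC − 1 exactly,
suggesting derivation from AUC; this package always computes the standard
confusion-matrix κ, so the two will differ whenever the threshold matters.

## 4. Relevance reconstruction

The class-activation-style map uses only quantities the architecture
exposes:

1. per feature map k: r_k(τ) = w_{c,k} · a_k(τ), with a_k the rectified
   post-batch-norm activation (a pre-batch-norm variant is available behind
   a flag; post-BN is the default because it is what the read-out actually
   weighs);
2. per demixed channel s: sum of its D maps' r_k, linearly interpolated
   from length 257 to 320 (the simplest monotone upsampling);
3. channel × time map: each demixed channel's temporal relevance is
   redistributed over input channels c proportionally to
   |W_pointwise(s,c)| (row-normalized; an all-zero row falls back to
   uniform);
4. negative totals are clipped (the display convention is excitatory
   evidence only) and the map is normalized to sum 1. If no positive
   evidence remains (e.g. the target class has zero dense weights), the
   documented fallback is the uniform map.

The *localization score* of a map is its total mass on a named channel set;
the dominant region of a mean map is the region with the highest mass **per
channel** (density) — raw mass would favor the 23-channel frontal region
over the 6-channel temporal region by construction.

## 5. Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, nothing
more:

- **Cohort bookkeeping**: 21/18/12 subjects (N/A+P−/A+P+); per-group trial
  totals default to the study's counts (N: 3176 MSIT + 2442 STMT = 5618,
  A+P−: 4871, A+P+: 3102) and are distributed across subjects by largest
  remainder, so group totals are exact and subjects differ by at most one
  trial. A `scale` factor shrinks totals for desk-scale runs.
- **Background**: Gaussian 1/f^χ noise (spectral synthesis), χ = 1,
  normalized to 10 µV RMS per channel. Verified by periodogram slope fits.
- **Signatures**: random-phase sinusoids with frequency drawn uniformly in
  the band per trial and independent phases per channel, added to all
  channels of the target region(s). Amplitudes are hierarchical:
  population mean (defaults 2–6 µV; "high-SNR" experiments use 12 µV ≈ 3×
  the θ/α-band background RMS) + per-subject Gaussian offset (SD 1 µV) +
  per-trial jitter (SD 1 µV), truncated at 0. The subject offset is what
  makes subject-wise splits genuinely harder than trial-wise splits.
  Defaults: A+P− θ+α over parietal+temporal; N α over frontal; A+P+ the
  risk signatures at 0.75× amplitude ("similar yet differing").
- **Artifacts**: ocular — a blink-like Gaussian transient (σ = 0.1 s, so
  spectral content < 4 Hz) on frontal channels with weights decaying from
  the two eye positions; EMG — a >20 Hz high-passed noise burst (~0.3 s)
  confined to temporal channels. Default rate 5% of trials each.

What the generator does **not** model: event-related-potential morphology,
volume conduction/field spread, non-stationary rhythms, realistic artifact
topographies beyond the two stereotypes, age/sex covariates. A green
recovery test therefore establishes that the pipeline can detect and
localize band-limited regional power differences under subject-level
variability — not that it would reach any particular performance on real
recordings. The study's real-data headline numbers (AUC ≈ 0.61, κ ≈ 0.22)
come from a request-only dataset and are deliberately *not* regression
targets of this package.

- Effect sizes of the real θ/α differences are unknown; the signature
  amplitudes are calibration knobs chosen once (above), not estimates.

## 6. Scaled-down experiment worlds

The acceptance-level experiments shrink only *runtime*, never semantics:

- planted-signal recovery and null calibration: the study's group sizes
  with 10 trials/subject/task and 10 CV iterations; training capped at
  30/12 epochs (patience 6/4) — at high SNR early stopping fires well
  before the cap, and at null the AUC is insensitive to training length;
- localization recovery: 20 runs cycling frontal/parietal/temporal plants
  on 8/8/6-subject cohorts, 40 epochs without early stopping (best-epoch
  weights are still restored);
- generalization direction: 20 seeds, 8/8/6 subjects, A+P+ at 0.75×
  amplitude;
- training-free property tests use a miniature geometry (60 ch × 80
  samples at 125 Hz, kernel 16) that keeps every architectural relation
  (valid-conv lengths, depthwise grouping) intact.

## 7. Numerical notes and edge cases

- Sample SD (n−1) everywhere; a single fold reports SD = 0.
- Periodogram band power: boxcar window, constant detrend, bands
  [f_lo, f_hi) — δ 1–4, θ 4–8, α 8–13, β 13–30 Hz — so band powers
  partition variance (Parseval) up to the DC bin.
- Topographic maps use inverse-distance-weighted interpolation (power 2) on
  the unit disc, exact at electrode positions, masked outside the disc.
  This is a rendering choice; no quantitative claim depends on it.
- Patience 0 stops at the first epoch without strict improvement; a NaN
  training loss aborts with a diagnostic rather than continuing silently.
- The montage omits FCz (the usual online reference), yielding exactly 60
  canonical 10-10 labels; FC electrodes are classed frontal, FT/TP/T
  temporal, C/CP central, P parietal, PO/O occipital.

## 8. Known limitations

- No nested hyperparameter tuning; the early-stopping validation set is the
  reported validation set (see §3).
- Relevance maps are qualitative attributions, not causal claims; the
  localization test quantifies them only on planted synthetic signals.
- The numpy training loop is single-threaded-friendly but not fast; the
  full 100-iteration protocol at full trial counts is hours of CPU, which
  is why tests and the acceptance script run scaled-down worlds.
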