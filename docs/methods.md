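# Methods

This note records the models implemented by `stressfuse`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## ECG preprocessing

The chain is notch → band-pass → z-score → R-peak detection → heartbeat
relocation → rasterization.

* **Filters.** Zero-phase filtering throughout (`filtfilt`), so R-wave
  positions are not displaced: an IIR notch at 50 Hz with quality
  factor 30 against mains interference, then a 4th-order Butterworth
  band-pass at 0.5–50 Hz against baseline wander, electrode drift and
  muscle noise. The filter family and order are standard ECG practice;
  nothing downstream is sensitive to them as long as phase is preserved.
* **Standardization** is the per-record z-score; it removes amplitude
  scaling between recordings and makes the detection threshold and the
  clipping thresholds scale-free.
* **R-peak detection.** A sample is a peak when it is the maximum of a
  centered 600 ms window and exceeds `threshold_frac` (default 0.5)
  times the global maximum; peaks closer than a 250 ms refractory
  interval are merged keeping the larger. 250 ms is the physiological
  floor for inter-beat intervals (240 bpm); the 600 ms window still
  separates beats at 120 bpm (500 ms spacing exceeds the 300 ms
  half-window).
* **Relocation.** The excerpt is re-cut at `R₁ − T₁/2` and `R_N + T₂/2`
  (midpoints floored; indices 0-based). `T₁` comes from the short-term
  autocorrelation of the reversed 2 s preceding `R₁`, `T₂` from the 2 s
  following `R_N`. The autocorrelation `acf[k] = Σ x[n]x[n+k]` is
  normalized by `acf[0]` and center-clipped at α = 0.1, β = −0.1.
* **Reading the first harmonic.** After skipping the contiguous lag-0
  run, the period is the lag of the *global maximum* of the clipped
  series — not the first surviving run. With realistic beat morphology
  the R spike cross-correlates with the P and T bumps of the adjacent
  beat, producing satellite runs (normalized height ~0.15–0.27, well
  above α) at lags far shorter than the beat period; the first-run
  reading locks onto those satellites, while the beat-to-beat peak is
  always the largest surviving value. Because the biased short-term
  autocorrelation decays with lag, the fundamental also dominates its
  own multiples, so a strictly periodic signal with `max_lag ≥ 2P`
  yields `P`, not `2P`.
* **Rasterization** is deterministic column-span drawing: each pair of
  adjacent samples fills the vertical pixel span it covers, amplitude
  min–max scaled per segment, into a 230×307 grayscale matrix
  (replicated to three channels at the network input). A constant
  segment maps to the middle row. Plot styling (line width, margins)
  does not enter any quantitative result.
* **Excerpt context.** Relocation needs 2 s of recording on each side
  of the boundary R waves. `relocate_heartbeat` rejects records without
  it; the `preprocess_ecg` convenience chain instead relocates around
  the first/last detected peaks that *have* the context, treating the
  record edges as the surrounding recording from which the excerpt was
  cut.
* **I/O.** ECG input is one-column CSV with the sampling rate in the
  header (`fs=<Hz>`). Binary waveform containers are out of scope; no
  reader for them is bundled.

## Voice preprocessing

All audio is resampled to 16 kHz, fixing the frame geometry at a
480-sample (30 ms) Hamming window with a 240-sample (15 ms) hop — for a
30 ms window, "15 ms overlap" and "15 ms hop" coincide. The frame count
is `(len − 480) // 240 + 1` (last partial frame dropped). Pre-emphasis
is `y[n] = x[n] − 0.97·x[n−1]`. Per-frame *power* spectra are projected
through a 64-band triangular Mel bank spanning [0, fs/2] built on the
HTK mapping `m = 2595·log10(1 + f/700)`; 64 bands give a
well-conditioned image for a clip of a few seconds. Log compression is
`log(1 + E/ε)` with ε = 1e−10, which maps silence exactly to zero.
The spectrogram image is min–max scaled and bilinearly resized to
230×307 with the lowest band at the bottom row.

## Face frames

Face detection is prior art and stays behind an interface: anything
returning a bounding box (and optionally eye landmarks) per frame plugs
in, and a deterministic stub detector replays the synthetic generator's
ground-truth geometry. Alignment is a 2-point similarity transform of
the eye landmarks onto a fixed canonical template; box-only detections
are cropped and resized. Frames with no detection reuse the nearest
detected frame's geometry, so output length always equals input length.

Clip sampling: a seeded random contiguous 64-frame window at training
time, the central window at evaluation; sequences shorter than 64 loop
cyclically (looping preserves the temporal statistics that zero-padding
would destroy). Augmentation rescales to 224×270, takes one 224×224
crop shared by all frames of the clip (random offset at training,
centered at evaluation), and flips horizontally with probability 1/2 at
training only. Video input is a directory of ordered PNG/JPEG frames;
compressed video containers are out of scope.

## Networks

The stack is pure numpy with explicit backpropagation (verified against
central differences to ~1e−9 in the test suite). All trainable tensors
are initialized from a uniform distribution (Glorot-scaled); each layer
draws from a generator seeded by `(master_seed, crc32(layer_name))`, so
adding or removing one module never perturbs another module's
initialization — this is what makes the attention ablation exact.

* **Temporal attention (TAM).** Squeeze `z_t = mean(u_t)` over channel
  and space, excite `S = σ(W₂·ReLU(W₁·z))`, scale `out_t = S_t·u_t`.
  The reduction ratio defaults to r = 4 (no published value); a
  non-integer `T/r` rounds to `max(1, round(T/r))`. Every gate is a
  sigmoid output, so the module is a strict per-frame contraction and
  all gates lie strictly inside (0, 1). The module sits after the first
  convolution+pooling stage of the video net, where it controls the
  proportion of temporal information the initial layers pass upward; a
  single insertion point is used, configurable in principle.
* **Backbones.** `tiny` (default, desk scale): a deterministic
  downsampling stem (temporal stride 4, block-average spatial pooling)
  followed by two basic residual stages (images) or two
  inception-style 3D modules (video), global average pooling, and a
  3-way head. `full`: the published stage plans — 3+4+6+3 bottleneck
  blocks with widths (64, 128, 256, 512)×4 for the 50-layer residual
  net, and nine inception modules with the published branch widths for
  the inflated-inception video net. Full variants are built without
  batch normalization and with average pooling between stages, and are
  intended for structural fidelity and forward passes, not desk-scale
  training. The inception pool branch uses a self-adjoint 3×3×3
  zero-padded average filter so its backward pass is the same filter.
* **Training.** Adam with cross-entropy over the three stages; a
  stratified 80/20 train/validation split inside the non-test portion
  of each fold; augmentation active only in train mode; the weights of
  the best validation epoch are returned. The published recipe (batch
  32 / 80 epochs / lr 1e−4 for images; batch 1 / 30 epochs / lr 1e−2
  for video, one 3×64-frame clip per step) is preserved in the config
  defaults; the desk-scale experiment shrinks this to batch 16 / 45
  epochs / lr 3e−3 (images) and batch 8 / 60 epochs / lr 5e−3 (video),
  sizes at which the tiny variants converge reliably in minutes on one
  CPU. With `lr = 0` the optimizer provably leaves weights unchanged.

## Fusion

The three posteriors are the columns of `M` (order: voice, face, ECG;
rows: calm, control, experimental). `M` is validated nonnegative with
unit column sums; for such matrices the largest-magnitude eigenvalue is
exactly 1, so no complex-arithmetic branch is exposed. The Perron
eigenvector is sign-fixed to the nonnegative orthant and L1-normalized
(weights read as stage proportions — no normalization was prescribed).
When the top eigenvalue is numerically repeated (e.g. all columns
uniform), the eigenvector is not unique and power iteration from the
uniform vector selects the symmetric fixed point. The decision is the
largest absolute weighted row sum; exact ties break toward the earlier
stage in (calm, control, experimental) order for determinism. Binary
collapse maps both stress-inducing stages to "stress"; single-modality
binary decisions use the same argmax-then-collapse path so they are
comparable with the fused one.

A property worth knowing: the decision is *not* equivariant under
relabeling the stages. A stage permutation permutes only the rows of
`M` (columns are modalities), and `P·M` is not similar to `M`, so the
principal eigenvector does not permute along — about 7% of random
stochastic matrices change their decision under relabeling. Unanimous
posteriors are equivariant (the shared basis vector stays the Perron
vector), and that special case is what the tests assert.

## Synthetic data

The generator emulates the stress physiology the system keys on, with
exact ground truth by construction:

* **ECG**: Gaussian R spike (σ = 12 ms) flanked by smaller P and T
  bumps (amplitudes 0.15 and 0.30), placed at per-class intervals —
  calm 60–75 bpm with 15 ms R-R jitter; control 90–110 bpm / 40 ms;
  experimental 100–120 bpm / 50 ms — plus white noise at 20 dB SNR and
  optional 50 Hz hum. A parametric template rather than a physiological
  simulator, because R positions must be exact ground truth.
* **Voice**: a harmonic tone at a class-dependent fundamental (calm
  120 Hz, control 190 Hz, experimental 230 Hz, ±5% per sample) with a
  class-dependent spectral tilt (stress tilts flatter, i.e. more
  high-frequency energy), syllable-rate amplitude modulation, and
  noise.
* **Video**: a textured face patch whose brightness oscillates at a
  class-dependent frequency (calm 0.5 Hz, control 2 Hz, experimental
  3 Hz) over a static background, with exact per-frame boxes and eye
  landmarks for the stub detector. Frequencies stay below the Nyquist
  limit of the temporally strided tiny network (7.5 frames/s).
* **Labels**: three stages, with control and experimental sharing
  stress physiology but differing slightly, mirroring a
  label-then-collapse evaluation; the default class mix follows a
  531:740 calm:stress ratio with the stress share split evenly.

Classes are separable by construction — a single threshold on the true
mean R-R interval separates calm from stress exactly — so an end-to-end
failure indicates a pipeline bug, not data ambiguity. The flip side:
passing on this data says nothing about accuracy on real recordings,
which carry inter-subject variability, overlapping class distributions,
detector errors, and session artifacts none of which are modeled here.

## Evaluation harness

Stratified k-fold cross-validation (default k = 10; the desk-scale
experiment uses k = 3 over n = 60 so three networks per fold train in
about two minutes total); within each fold's non-test portion, a
stratified 80/20 train/validation split (falling back to an
unstratified split only when the validation set would be smaller than
the class count). "Stress" is the positive class for
precision/recall/F1. Confusion matrices are reported both as raw counts
(rows = actual, columns = predicted) and column-normalized so each
predicted-label column sums to 1; metrics recomputed from the stored
raw counts agree with the reported ones to 1e−12 by construction.
Metrics are reported both pooled over folds and averaged across folds,
since either convention is defensible. Stage timings (preprocessing /
feature extraction / fusion) are logged to a separate `timing.json`:
they are hardware-dependent, never asserted, and keeping them out of
`report.json` makes the report a pure function of the master seed —
reruns are bit-identical.

## Known limitations

* Real-data accuracy is unvalidated; the study dataset is private and
  the synthetic generator is deliberately separable.
* No bundled face detector; real video requires an external detector
  behind the provided interface.
* The numpy networks are CPU-oriented; full-variant training at
  published scale is out of scope.
* Single-lead ECG only; no HRV features, no beat classification, no
  streaming acquisition.
* The R-R recovery guarantees are stated for (near-)periodic excerpts;
  under heavy beat-to-beat jitter the autocorrelation reads the local
  *average* period, which can differ from any single interval.
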