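# Methods

## Measurement model

The pipeline treats a dyadic session as four per-participant sensor streams
with non-uniform timestamps: skeletal joint positions (17 upper-body joints
× x, y, z in meters, sensor-centered, nominal 30 Hz), facial blendshape
activations (52 channels in [0, 1], deviation from the neutral pose), head
rotation (pitch/yaw/roll in degrees) and normalized 2-D point of gaze.
Lower-body joints are excluded because markerless depth trackers estimate
them poorly.

### Preprocessing

1. **Interpolation.** Each stream is linearly interpolated onto an exact
   30 Hz grid anchored at session start. Grid frames whose bracketing valid
   source samples are more than `max_gap_s = 0.2 s` apart are marked
   invalid rather than bridged: interpolating across a dropout would
   fabricate motion, and the per-window validity rule below is the intended
   mechanism for handling missing data. No extrapolation occurs beyond the
   first/last valid sample.
2. **Filtering.** Body coordinates pass through a second-order Butterworth
   low-pass at 6 Hz applied forward and backward (`filtfilt`) per
   contiguous valid run. The bidirectional pass is zero-phase by
   construction and squares the magnitude response, so the −3 dB point
   becomes an amplitude ratio of exactly 0.50 at the cutoff — asserted in
   the tests. Runs shorter than three filter startup lengths (45 frames)
   pass through unfiltered with a log entry. Facial streams are
   interpolated and downsampled but not low-pass filtered by default
   (`filter_faces` enables it), mirroring the asymmetric treatment of the
   two sensors in the measurement protocol this package follows.
3. **Downsampling.** Synchrony inputs are brought to 10 Hz by linear
   interpolation on the uniform grid; a target frame is invalid when either
   bracketing source frame is.

### Extent of movement

Bodily extent is the per-frame Euclidean displacement of each joint
(meters per 1/30-s interval); the composite is the mean over the 17
joints. A composite frame is valid only when the whole skeleton frame is
valid, so the composite's scale cannot drift with partial dropouts — this
also makes frame-then-joint and joint-then-frame averaging identical.
Facial extent first averages mirrored left/right blendshape pairs
(18 pairs; `jawLeft/jawRight` and `mouthLeft/mouthRight` encode sideways
motion, not mirrored expressions, and are never merged), then drops
channels with variance below `low_variance_threshold = 1e-4` (untracked or
spuriously constant regions), then averages the survivors.

### Windowed lagged cross-correlation

Sessions are tiled into consecutive non-overlapping 100-s windows from
t = 0 (the minimal reading of "each 100-s interval"); the trailing partial
window is dropped. A window is kept only if ≥ 90% of its frames are valid
for *both* partners (logical AND — the conservative pairing). Within each
kept window, the Pearson correlation is computed over the jointly valid
overlapping samples at every lag of a symmetric 0.1-s grid (±5 s body,
±1 s face). The shift stays inside the window, so overlap shrinks with
|lag|; cells with fewer than `min_overlap_samples = 50` samples (5 s at
10 Hz) are missing rather than noisy. Positive lag means the second
participant trails the first. Five summaries are computed over all
non-missing cells jointly (windows and lags together; the per-lag profile
is retained so a per-lag-first aggregation remains recoverable): mean,
absolute mean, non-negative mean (missing if no cell is ≥ 0), maximum, and
the signed value of the largest magnitude. Missing summaries propagate as
missing features, never as zeros.

Joint angles (10, in degrees) are the arccos of the normalized dot product
of the two bone vectors at a middle joint. The ten triples — left/right
elbow, shoulder, wrist and hand, plus neck and spine — cover every angle
the protocol names and are configurable. Angles are invariant to rigid
transforms and uniform scaling; displacements to rigid transforms — both
asserted at 1e-9.

## Candidate features

`FEATURE_NAMES` enumerates 878 features deterministically: five synchrony
summaries × (body composite + 17 joints + 10 angles + face composite + 52
blendshape channels) = 405; six statistics (mean, SD, gradient mean/SD,
signed gradient max, signed second-gradient max) × 3 coordinates × 17
joints = 306; per-joint 0.1-s displacement mean/SD (computed from the
10 Hz series, a coarser quantity than the 30 Hz extent) = 34; four angle
statistics × 10 = 40; head-rotation mean/SD and gradient mean/SD = 12;
mean/SD per merged facial item = 68; gaze mean/SD = 4; per-stream validity
percentage and longest missing run = 8; gender = 1. Gradients are first
differences in per-second units over pairs of valid frames. The published
block list this layer mirrors prints a total of 827 that cannot be
reconstructed from the blocks themselves; the package asserts its own
documented count instead. Blendshape left/right pairs are merged in the
mean/SD block (consistent with the facial-extent definition) but kept
separate in the synchrony block, where individual lip-corner channels are
informative.

Feature columns missing in more than half the cohort are dropped with a
log entry; remaining missing cells are median-imputed (logged). Observed
cells are never modified. Synchrony features are dyad-level and identical
for both members.

## Classification protocol

Labels are a median split of the 8-item attraction composite (ties go low:
"high" means strictly above the median). The 70/30 partition and the five
folds are stratified by label and, by default, grouped by dyad so both
members land on the same side of every split — synchrony features are
shared within a pair and would otherwise leak; a participant-level mode
reproduces the plain protocol. Selection runs on training rows only: CFS
greedy forward search maximizing merit
`k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` (point-biserial feature–label and
pairwise feature–feature correlations, both absolute), stopping when no
addition improves merit, followed by linear soft-margin SVM-RFE on the
surviving set, eliminating the smallest-squared-weight feature one at a
time down to 23 (identity when fewer survive CFS).

Both classifiers use fixed documented hyperparameters: random forest with
500 trees, entropy criterion, depth 10, `max_features` 20 (clamped to the
selected-feature count when smaller), min 7 samples per leaf, seed 30; MLP
with one hidden layer of 50 logistic units, L2 penalty 0.03, Adam
(β₁ 0.9, β₂ 0.999, ε 1e−8), constant learning rate 0.001, ≤ 200
iterations, no early stopping, seed 30, standardized inputs (training
statistics only). Reported numbers: per-fold accuracies with their mean
and SD, test accuracy, confusion counts, sensitivity/specificity with
"high" positive, and the majority-class frequency of the test labels as
baseline.

## Synthetic dyad generator

The generator exists because no public corpus pairs skeletal and
blendshape streams for interacting dyads. It emulates exactly the
statistical structure the analysis assumes:

- **Movement drive.** A shared band-limited Gaussian process g (white
  noise filtered at `drive_bandwidth_hz = 1 Hz`, well below the 6 Hz
  cutoff) plus independent matched-variance smooth noises:
  drive_A = c + g(t) + e_A, drive_B = c + α·g(t−τ) + √(1−α²)·e_B, clipped
  at zero (baseline c = 1, SD 0.3 keeps clipping negligible). The drives'
  lagged correlation peaks at τ with height monotone in α (≈ α/√2 under
  this asymmetric-variance construction; the acceptance check compares the
  pipeline estimate against a Monte-Carlo evaluation of this same model,
  not against α itself).
- **Skeleton.** Joint displacement magnitude is *exactly* drive ×
  `displacement_scale_m` (default 0.004 m per frame ≈ gentle gesturing)
  along a smooth random direction field, so the extent series inherits the
  drive's coupling analytically. Positions start from a seated-adult
  template ~2 m from the sensor.
- **Face.** Sparse attack–sustain–decay pulses (raised-cosine flanks,
  1.5 s) on eight expression groups; partner B mimics each of A's events
  with probability α at lag τ and adds independent events at rate (1−α)
  to keep rates matched; mirrored pairs share a pulse with ~5% asymmetry
  noise; values clip to [0, 1]. Body coupling applies only when the dyad's
  condition rendered the body, facial mimicry only when faces were
  rendered (2×2 design, conditions and gender balanced by construction).
- **Sensor artifacts.** Truncated-normal timestamp jitter (4 ms, bounded
  below half a frame so time stays monotone) and two-state Markov dropout
  (default 3% of frames, mean run 5) whose runs are deleted from the
  stream.
- **Latent attraction.** One z-scored latent per dyad scales movement
  amplitude and facial event rate (factor 1 + 0.25·d·z at effect size d)
  and centers the questionnaire items (item mean 4.5 + 0.9·z, item noise
  SD 0.5, discretized by rounding and clamping to 1..7 — the simplest
  monotone mapping). Observer personality items are the self items plus
  observer noise, so zero noise yields profile correlation exactly 1.
  The ground-truth class is the median split of the latents.

Seeds flow through one hierarchy (cohort → dyad → stream), so identical
(config, seed) pairs are bit-identical and single dyads reproduce in
isolation.

What the generator does **not** emulate: real sensor noise spectra beyond
jitter + dropout, posture constraints (joints drift as a random walk
rather than respecting bone lengths), speech-coupled facial dynamics,
condition-dependent questionnaire shifts, or any nonstationarity across a
session. Passing tests therefore demonstrate that the pipeline recovers
the structure it claims to measure, not that real interactions carry that
structure.

## Problem sizes and numerical choices

Default synthetic sessions last 300 s (three 100-s windows); the
replicated acceptance checks use 120-s sessions and the cohort size of 124
dyads (248 participants) matching the study design, with 10 effect and 4
null replicates for the end-to-end detection check and 100 replicates for
the drive-level Monte-Carlo oracle — sizes chosen so the full suite runs
comfortably on one CPU while keeping every statistical band at its stated
strength (≥ 90% of replicates; 3 standard errors). Correlation cells use
population moments; statistics blocks use population SDs. Ties in the
CFS greedy step resolve to the lowest feature index; the elimination order
of SVM-RFE is recorded for audit. Degenerate inputs (constant labels,
all-invalid windows, empty test sets) raise typed errors or propagate
missing values; they are never silently zero-filled.

## Known limitations

- The 10 angle triples and the on-disk CSV schemas are artifact-defined;
  the measurement protocol this package follows does not specify them.
- CFS merit can keep growing slowly on pure-noise features (√k gain
  against diluting r̄_cf), so the noise-floor guarantee is "merit near
  zero", not "subset of size ≤ 2".
- The MLP's fixed optimization budget (constant 0.001 learning rate, 200
  iterations, tolerance-based plateau stop) underfits small hard
  nonlinear problems; the tests document this with a large-sample XOR
  task.
- Whether anti-alias filtering should precede the facial 10 Hz
  downsampling is left configurable (`filter_faces`), defaulting to off.
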