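# Methods

## Data model and kinematics

A pen stream is a time-ordered sequence of digitizer samples
(t, x, y, p, Az, Alt, pen_down) at a nominal 125 Hz. Invariants enforced on
construction: strictly increasing t, p ≥ 0 with p = 0 on every in-air
sample, Alt ∈ [0, 90]°, Az ∈ [0, 360)°.

Velocity and acceleration are first-order finite differences:
v_x(i) = (x(i+1) − x(i))/Δt_i, v(i) = √(v_x² + v_y²), and
a_x(i) = (v_x(i+1) − v_x(i))/Δt_i, a(i) = √(a_x² + a_y²) — note the
*signed component* velocities feed the acceleration, not the speed
magnitude, so curvature contributes. Conventions where the method
description is silent:

* the derivative over [t_i, t_{i+1}] is assigned to sample i, and the tail
  is padded by replication so every kinematic series matches the stream
  length (one padded value for velocity, two for acceleration) — this keeps
  pointwise rendering a 1:1 mapping;
* Δt comes from timestamps when the file has them, otherwise 1/125 s;
* kinematics run over the full sequence including in-air samples, with no
  special treatment at pen-state transitions — the in-air gesture is part
  of the signal;
* coordinates and pressure stay in raw tablet/device units; no physical
  calibration is attempted.

The canonical file format is a UTF-8 TSV with header
`t_ms x y p az alt pen_down` and `# subject_id=… / # label=…` comment
lines; floats are written at full repr precision, so times on a regular
millisecond grid round-trip exactly. A configurable headerless
space-separated dialect is provided for foreign exports; when a dialect has
no time column, t is synthesized as index/125.

## Hybrid images

Rendering maps the bounding box of the **full** trajectory (pen-down and
in-air) into a 512×512 canvas with a 5% margin, aspect ratio preserved,
centered, y flipped so tablet "up" is image "up". Using the full-gesture
box for every view keeps all views of one subject in register, which the
three-channel composite requires.

Gray encoding: population min–max normalization per parameter, clipped to
[0, 1], then g = ⌊255·(1 − v̂) + 0.5⌋ (round-half-up; midpoint → 128). Low
values are white, high values black; the background is white (255). The
population scope is the whole cohort by default, matching the study
protocol; note this leaks the test subjects' value range into training
images, so a `train_only` scope is provided for leakage-free variants. If a
parameter is constant across the population (max = min) the stats are
flagged degenerate, everything maps to white, and the image carries the
flag — a fail-soft chosen for synthetic edge cases.

Strokes: each rendered sample is stamped as a disk of radius stroke/2
(default stroke 3 px) at its own gray; consecutive rendered samples are
joined by a capsule — every pixel whose center lies within stroke/2 of the
segment — at the rounded mean of the endpoint grays. Overlaps resolve to
the darkest value, which makes the rendering order irrelevant and gives a
clean monotonicity property: raising parameter values never lightens a
pixel. A dots-only mode exists for ablation. Pen-up inclusion per view:
pressure renders pen-down only (in-air pressure is identically zero and
would draw a spurious white-coded trace); velocity and acceleration render
the full gesture; altitude renders the full gesture by default and is
configurable, since pen inclination is captured in the air as well.

## Feature extraction

The extractor is the classic 5-conv/3-fc AlexNet layout (11/5/3/3/3
kernels; pooling after stages 1, 2, 5; fc6/fc7 at 4096), implemented
directly on numpy via im2col + GEMM. Tap points: Conv1…Conv5 after the
ReLU (and after the following max-pool for Conv1/Conv2/Conv5) and fc7
after its ReLU — the pooled read-out is the conventional "off-the-shelf"
descriptor and bounds SVM input dimension. Descriptor dimensions at input
224: 46656 / 32448 / 64896 / 43264 / 9216 / 4096. Flattening is
channel-major and frozen.

Preprocessing: bilinear resize to 224² (227 selectable), grayscale
replicated to three channels, scaled to [0, 1], normalized with the
standard ImageNet channel statistics.

Weights: `random_seeded` draws He-initialized weights (σ = √(2/fan_in),
zero biases) from a seeded generator, cached per (input size, mode, seed);
equal seeds give bit-identical features across processes. Random
convolutional features act as structure-preserving random projections —
sufficient for the pipeline's calibration and signal-detection properties
on synthetic cohorts, and the honest default given that no trained
parameter set is distributed with the package; `pretrained` raises a
descriptive error rather than silently substituting. Discrimination claims
about real clinical data would require an actual pretrained network.

## Classification protocol

Default protocol (generalizable via arguments): 10 repetitions; per
repetition an independent draw of 30 of the 45 HC (no constraint that the
draws cover all 45), split 20 train / 10 test, plus 20/10 of the 30 AD;
the SVM is an RBF-kernel SVC. Grid search: C ∈ {10⁻²…10³},
γ ∈ {10⁻⁵…10} in decades plus scikit-learn's variance-scaled `scale`
heuristic; stratified 5-fold CV on the training split with a
repetition-derived fold seed; selection by mean validation accuracy, ties
broken toward smallest C then smallest γ (numeric γ before `scale`); the
winner is refit on the full training split. Features are z-scored with
train-only statistics — RBF kernels are scale-sensitive and conv
activations heavy-tailed. Implementation note: the CV loop evaluates
candidates through a single precomputed pairwise squared-distance matrix
per repetition (K = exp(−γD)), which is mathematically identical to
refitting an RBF SVC per candidate and roughly 30× faster at these sample
sizes; the fold count is capped at the smallest per-class training count
so tiny configurations remain stratifiable.

Metrics use AD as the positive class: sensitivity = 100·tp/(tp+fn),
specificity = 100·tn/(tn+fp), accuracy = 100·(tp+tn)/n. Aggregation
reports the mean and the *population* (ddof = 0) standard deviation over
repetitions.

Fusion: hard majority vote over an odd number of experts; every expert in
a scheme shares the sampling plan and the per-repetition CV seed so
decisions align subject-by-subject. Odd counts are enforced at scheme
construction instead of inventing a tie rule. Low-level fusion composes
(pressure, altitude, velocity) — order configurable — into the three input
channels of one image and runs a single expert.

## Synthetic cohorts

The generator emulates the acquisition setting: an Archimedes spiral
r(θ) = gap·θ (4 turns, gap 30 units/rad) traversed at 125 Hz with

* Ornstein–Uhlenbeck angular speed (mean 2 rad/s, relative sd 8% for HC,
  reversion 2 s⁻¹), giving smooth speed fluctuation;
* radial tremor A·sin(2πft + φ) with f ~ U[4, 7] Hz — the classic action-
  tremor band — A = 0.5 units for HC;
* AR(1) pressure noise (ρ = 0.95) around a drifting mean (600 − 2t device
  units, sd 25 for HC), clipped at 0; AR(1) altitude around 55° (sd 2°);
  slowly drifting azimuth;
* a Poisson number of in-air excursions (rate 0.5 for HC; exponential
  durations, mean 0.25 s, shifted apart so each stays a distinct run)
  during which pen_down is false, pressure is 0, and angular speed is
  inflated 2.5× — in-air motion is faster than on-paper motion.

The AD profile at effect size ε adds ε·Δ to six HC parameters:
tremor_amp +2.5, speed_jitter_sd +0.22, pressure_mean −250,
pressure_sd +45, penup_rate +3.5, alt_sd +6. The deltas echo the
qualitative contrasts the hybrid images are designed to expose — lighter,
broken, more variable pressure traces and fast in-air bridges — and were
fixed once as "clearly separable at ε = 1"; they are configuration, not
claims about real AD effect sizes. At ε = 0 the two classes are drawn from
the identical distribution. Per-subject seeds are spawned from the cohort
seed, so a subject's stream is independent of cohort composition.

What passing tests on these cohorts show: that the pipeline is correctly
plumbed (calibrated at null, monotone in effect size, able to detect a
strong dynamic contrast through the image/feature/SVM/fusion chain). What
they cannot show: clinical validity — the generator is not a neuromotor
model of handwriting (no sigma-lognormal strokes, no fatigue, no cognitive
load structure, one spiral per subject, binary labels only).

## Problem sizes and tolerances

The verification suite runs the full study geometry — 45 + 30 subjects,
three views, Conv3 descriptors, 10 repetitions — for the headline fusion
run and the permuted-label null, and a 3-seed × 3-ε sweep for effect-size
monotonicity; the sweep uses a reduced 3×3 grid (C ∈ {1, 10, 100},
γ ∈ {10⁻⁵, 10⁻⁴, scale}, the decades adjacent to 1/dim where RBF kernels
on standardized 64896-dim descriptors are non-degenerate). Kinematics are
checked against independently coded finite differences at 1e-9 relative;
rasterization against per-pixel capsule enumeration, exactly; voting
against exhaustive enumeration, exactly. Accuracy at ε = 0 is asserted
within the binomial chance band [35, 65]% for 20-subject test sets, and
near the accuracy ceiling (ε ≥ 0.5 saturates around 98%) monotonicity is
assessed on seed-averaged means under the full 10-repetition protocol,
where the estimate's noise is small relative to the band.

## Known limitations

* No pretrained weights ship with the package; random-projection features
  are weaker than ImageNet features and the synthetic contrasts are tuned
  to be detectable regardless.
* Population-scope normalization replicates the study protocol but leaks
  test-range information; use `train_only` for honest generalization
  estimates on real data.
* Whether altitude images should include in-air samples is an open choice
  (default: include); pressure excludes them by necessity.
* The HC subsample is drawn independently per repetition; coverage of all
  45 HC across the 10 repetitions is not enforced.
* Azimuth is recorded and round-tripped but never rendered as a view.
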