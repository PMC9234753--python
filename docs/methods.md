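# Methods

This note documents the models, numerical conventions and design choices
behind the package: what the pipeline computes, what the synthetic
generator does and does not emulate, and the behaviors a careful user
should know about.

## 1. Analysis pipeline

### Window and decimation

The nonlinear stage analyzes the **first 12,000 pre-decimation samples**
(120 s at 100 Hz) of each AP heel channel; a 5-minute trial provides that
window with margin, and the fixed window keeps plot sizes and radii
comparable across participants. Decimation is **plain stride sampling**
(every 10th sample, output length ⌊N/10⌋): no anti-alias filter is applied,
deliberately — the nonlinear measures are meant to see the raw signal, and
low-pass filtering would itself alter recurrence structure. Spatiotemporal
metrics, in contrast, use the full-rate recording (they need event timing
at 10 ms resolution).

### Spatiotemporal metrics

Heel strikes are detected as local maxima of heel-minus-sacrum AP position
(a marker-only convention; subtracting the sacrum removes common-mode body
motion). For localization only, the channel is smoothed with a 0.15 s
Savitzky-Golay window (order 2); peaks must be separated by at least 0.4 of
the dominant cycle (FFT estimate) and exceed a 25% prominence of the signal
range. On the synthetic generator this recovers ≥99% of ground-truth events
within ±2 samples. Users with force-plate events can bypass detection by
constructing `GaitEvents` directly.

Per side: step time = time from contralateral to ipsilateral strike; step
length = AP marker displacement between those strikes **plus belt travel**
(belt speed × step time), since treadmill marker coordinates are
body-relative; step width = |ML separation of the two heels at their
respective strikes|. Summaries average the **first 200 steps** per side;
when fewer are available all are used and a warning is recorded. Steps with
negative computed length are excluded and counted in the log (they indicate
event or marker errors).

### Delay embedding

τ is the first interior minimum of the average mutual information (AMI)
profile, estimated from a **16-bin equal-occupancy** joint histogram over
lags 0–50 (5 s at 10 Hz). Equiprobable bins stabilize the estimate on the
strongly non-Gaussian amplitude distribution of cyclic signals; if no
interior minimum exists (e.g. white noise) the global minimum over positive
lags is used with a warning. EMB is chosen by false nearest neighbors with
Kennel-style constants: distance-growth ratio threshold `rtol = 15`,
attractor-size threshold `atol = 2`, acceptance when the false fraction
falls below **1%**, `max_dim = 10` (returned with a warning when never
reached, as happens for white noise). Across legs the pair uses
**max(τ_L, τ_R)** and **max(EMB_L, EMB_R)**; the per-leg values are kept in
the report. The max-τ rule mirrors the stated max-EMB rule; both per-leg
values are logged so the choice is auditable.

A caution: exactly commensurate sinusoids (e.g. 1 Hz sampled at 10 Hz take
only 10 distinct values) degenerate both AMI and FNN; test fixtures use
incommensurate frequencies.

### Cross-recurrence quantification

Distances are **Euclidean**; recurrence is a **closed ball** (d ≤ ρ). The
radius is calibrated by bisection on [0, max distance], exploiting the
monotonicity of RR in ρ, and returns the radius whose achieved RR is
*closest* to the 2.5% target (ties toward the smaller radius), with a
0.05-pp acceptance tolerance and 60 iterations. On 1,200-point trajectories
(~1.4 M cells) the achieved RR equals the target to plot granularity
(<10⁻⁴ pp). Calibration can fail only when heavy distance ties make the
target rate unreachable (tiny or strongly degenerate trajectories); the
error reports the final bracket. Cross plots have no line of identity, so
the RR denominator is all n_x·n_y cells.

Diagonal lines are maximal runs along i−j = const with **min_line = 2**;
border-touching runs count at their observed length. %DET is the
percentage of recurrent points on such lines; MeanL their mean length in
post-decimation samples (0.1 s each). The radius is reported in mm of
embedded heel-position space.

One behavior worth understanding: at a very sparse fixed RR the threshold
slices through the "soft edges" of recurrence bands, where the embedded
orbit moves at varying speed, leaving isolated recurrent cells. Even a
noiseless periodic limb pair therefore shows %DET below 100% at RR 2.5%
(~95% for the asymmetric gait waveform; ~98% for a pure sinusoid pair). At
a moderate, non-sparse radius every recurrence of a deterministic pair
falls on a diagonal line and %DET reaches 100% to numerical tolerance; the
test suite asserts the deterministic limit in that regime. This is a
property of fixed-RR sparsification, not of the implementation.

### Cross sample entropy

Both series are standardized (zero mean, unit SD), so the tolerance
r = 0.25 means 0.25·SD of each series; this follows the per-series-SD
convention of the sample-entropy family. Matching uses **Chebyshev**
distance with **strict inequality** (< r), template length m = 3, and the
same n − m start indices for both template lengths, making
cSE = −ln(A/B) a true conditional probability (0 ≤ A ≤ B). Self-match
exclusion does not arise in cross comparison. The logarithm is natural; the
value is reported unitless. Zero matches at either length raise an explicit
error (with the advice to increase r) rather than returning 0 or infinity.

cSE is *not* strictly monotone in r point-to-point — A/B is a ratio of two
increasing counts and can wiggle (measured on a gait fixture: 0.184, 0.156,
0.156, 0.164 at r = 0.15/0.25/0.4/0.6). It does fall from tight to loose
tolerance and vanishes once r exceeds the signal range; the tests assert
that real behavior.

### Group statistics

Each outcome column is Shapiro-Wilk tested **within each group**; if either
group rejects normality at α = 0.05 (or is constant, which cannot be
treated as normal data), the variable goes to a Mann-Whitney U test —
min(U₁, U₂) convention, exact p when both groups have ≤12 tie-free
observations, normal approximation with tie correction otherwise — else to
a classic **pooled-variance** t-test with df = n₁+n₂−2 (the pooled form is
what reproduces integer df = 16 for 9 + 9 groups). All tests are two-sided;
no multiplicity correction is applied, and report consumers should read
p-values per variable.

## 2. Synthetic gait generator

### What it emulates

100 Hz body-relative marker traces of steady treadmill walking at ~1.1 m/s
with a 0.86 Hz stride (0.58 s steps). Each heel's AP coordinate follows an
asymmetric two-harmonic cyclic waveform

x(t) = A·(1 + a(t))·[sin φ(t) + 0.3·sin(2φ(t) + 0.8)] + s(t) + ε(t)

with A = 350 mm, where

- φ_R(t) = 2π·0.86·t and **φ_L = φ_R + π + δ(t)**: the left limb runs
  near anti-phase with a slowly drifting relative phase δ(t), an AR(1)
  process with stationary SD 0.05 rad ("healthy") and per-sample
  coefficient 0.992 (decorrelation ≈ 1.2 s, i.e. the drift persists across
  strides). **phase_jitter_sd is the coupling knob**: the "exo_like" preset
  doubles it to 0.10 rad and changes nothing else.
- a(t): per-leg multiplicative amplitude modulation, AR(1) with SD 0.03 and
  coefficient 0.995 — stride-to-stride excursion variability.
- s(t): a **common-mode** postural-sway AP component, 12 mm at 0.10 Hz
  (incommensurate with the stride), shared by both heels and the sacrum.
- ε(t): white measurement noise, SD 3 mm.

ML heel coordinates sit at ±80 mm with per-stride placement noise realizing
a 0.16 ± 0.01 m step width; the sacrum bobs 5 mm at step frequency on top
of the shared sway. Ground-truth heel strikes are the per-cycle maxima of
each leg's noise-free cyclic waveform (the phase crossing of the waveform's
peak phase). Identical config + seed gives bit-identical output.

### Why these ingredients

Each term exists because a measurable property of real gait demands it:

- the **second harmonic with nonzero phase** (waveform asymmetry — fast
  swing, slower stance-like segment) is what produces realistic cross
  sample entropy: a time-symmetric waveform is so self-predictable that
  cSE stays near 0.08 regardless of noise, far below the ~0.16 seen in
  unassisted walking;
- **AR(1) relative-phase drift** (rather than white jitter) produces the
  finite diagonal-line structure of real plots — coordination is lost and
  regained over strides, not per sample;
- the **common sway** enriches each leg's state-space geometry so FNN
  selects dimension 4 (as observed for heel trajectories) while barely
  touching the inter-limb alignment, since it cancels in the relative
  coordinate;
- amplitude modulation and measurement noise set the residual speckle level
  of the plot (%DET ≈ 90%).

### Calibration

Defaults were calibrated once, as part of the generator's design, so the
full pipeline on the healthy preset lands at unassisted-walking scale
across seeds: %DET ≈ 90–92%, MeanL ≈ 9–10 points, cSE ≈ 0.155, τ = 3,
EMB = 4, step time 0.58 s, step length ≈ 0.64 m, step width 0.16 m. The
coupling knob is validated by a monotonicity property: over
phase_jitter_sd ∈ {0.02, 0.05, 0.1, 0.2, 0.4} (20 seeds each), median
MeanL is strictly decreasing and median cSE strictly increasing.

### What it does not emulate

Real heel trajectories contain long-range correlated stride-time
fluctuations, asymmetries between dominant and non-dominant legs, foot
clearance and double-support structure, soft-tissue artifact, and
non-stationary drift (fatigue, attention). The generator's variability is
stationary and Gaussian in all components. Consequently, passing tests
demonstrate that the *pipeline* recovers known coupling structure and its
direction of change — not that the generator is a biomechanical model, nor
that effect sizes on real data will match the synthetic ones. EMB on the
synthetic trials concentrates at 4 rather than spreading over 4–6 as in
human cohorts, because the generator has exactly one extra slow degree of
freedom per leg.

## 3. Numerical choices and degenerate inputs

- Radius bisection: 60 iterations, tolerance 0.05 pp; target 100% returns
  the maximum distance directly.
- AMI requires max_lag < n/2 and a non-constant series; FNN requires
  τ·max_dim < n. Constant series raise degenerate-input errors everywhere
  rather than producing NaNs.
- Trials shorter than the 12,000-sample window are analyzed whole; a trial
  too short to embed raises an error naming the required minimum.
- `decimate` truncates to a multiple of the factor before striding, so the
  output length is exactly ⌊N/factor⌋.
- Heel-strike alternation violations are an error listing the offending
  indices, never silently repaired.
- In the group table, a constant column within a group routes that variable
  to the nonparametric test (Shapiro-Wilk is undefined on constants).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipelines contain no hidden stochasticity, so
  every report is byte-reproducible.

## 4. Problem sizes

Default analyses use 1,200-point decimated series (≈1,188 embedded points;
~1.4 M-cell plots). A full per-trial pipeline takes ~0.3 s on one CPU; the
18-trial synthetic study a few seconds; the complete test suite
(including the 100-run coupling-knob grid) about 40 s.
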