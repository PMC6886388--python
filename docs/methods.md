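# Methods

## Model

A movement toward a phonetic target is modelled as the response of a
critically damped N-th order linear system. Within one target interval of
duration `d`, with rate parameter λ > 0 and linear target `x(t) = m·t + b`,

    y(t) = x(t) + e^(−λt) · Σ_{k=0}^{N−1} c_k t^k ,

which is the general solution of `(d/dt + λ)^N (y − x) = 0`. The polynomial
coefficients are fixed by the state at the interval onset. We compute them
with the recursion

    c_k = (y⁽ᵏ⁾(0) − x⁽ᵏ⁾(0)) / k!  −  Σ_{j=1}^{k} (−λ)ʲ/j! · c_{k−j} ,

which is algebraically identical to the textbook initial-condition solution
but uses running factorial ratios only — no explicit `k!·λᵏ` products — and
is numerically exact (≤ 1e−9 relative against an independent linear solve)
up to the supported order cap of 32. For N = 3 it reduces to the familiar
qTA forms `c_0 = y(0) − b`, `c_1 = y'(0) + c_0λ − m`,
`c_2 = (y''(0) + 2c_1λ − c_0λ²)/2`.

**State transfer.** At each interval boundary, displacement and derivatives
1..N−1 are evaluated analytically at the outgoing interval's end and become
the incoming interval's initial conditions, with local time reset to zero.
The trajectory is therefore C^(N−1) at boundaries (verified to 1e−6
relative), while the N-th derivative jumps whenever the target changes.
Cross-boundary momentum matters: with velocity transfer the movement after
a fast movement is measurably larger and later-peaking than with velocity
reset, and the test suite asserts this.

**Assumptions.** Critical damping (no oscillation), a single shared λ per
sequence by default (per-target λ is supported), deterministic dynamics
(noise belongs to the synthetic-data generator), and forward simulation
only — no parameter estimation from trajectories.

**Sampling.** Default dt = 1 ms, fine enough that turning-point and
peak-velocity discretization error is far below the analysis tolerances
(sweeps recomputed at dt = 0.5 ms agree within 0.5% plus one grid step in
duration). Interval durations are snapped to the dt grid; each interval owns
its end sample, and the output grid is strictly uniform.

## Kinematic measurement

Real measurements can only use visible landmarks, so all kinematics are
taken from turning points (strict local extrema of displacement; plateaus
count once at their first sample; endpoints are never turning points),
regardless of the target intervals that generated the trajectory:

* displacement — height difference between bounding turning points;
* movement duration — time between them;
* peak velocity — signed extremum of the analytic first derivative between
  them (model velocity is never smoothed);
* vp/d — |peak velocity| / |displacement|, undefined below a displacement
  floor of 1e−9 rather than infinite.

**Sweep protocol.** The standard simulation holds y₀ = 85, static targets
80/100/80, d1 = 0.2 s, d3 = 0.3 s fixed, and sweeps the middle interval d2
over 10..400 ms in 1 ms steps (the movement of interest is the rise toward
the middle target, bounded by the first two turning points). Sweep points
whose trajectory lacks two turning points (very short d2 at high order and
low λ) are omitted and reported.

**Critical point.** The plateau of the peak-velocity-vs-displacement curve
is detected by scanning successive sweep points in increasing displacement
order and returning the first point where
Δ(peak velocity)/Δ(displacement) < 1 (threshold configurable; +∞ returns the
first point; a never-met criterion raises a no-plateau error carrying the
smallest observed slope). Because this is a finite difference on the sweep
grid, critical-point coordinates inherit grid-level uncertainty of a few
per cent; the reported "critical duration" is the *measured*
turning-point-to-turning-point duration (in ms), not the intended d2 — the
landmark-only philosophy applied consistently. Published values of these
critical points evidently used a coarser, unstated sweep grid: our order-6
and order-10 critical durations and peak velocities agree with the printed
table to ~1–3%, displacements to ~5–8%, while the printed order-2 column is
not reproducible under its stated λ values at all — its (2, 23) peak
velocity equals the saturated-peak value `Δλ/e` computed with λ = 21
exactly, whereas the neighbouring cells match their stated λ to four
digits. We keep the stated λ values and our stated grid rather than adjust
either toward the print.

**vp/d regression.** Ordinary least squares of |peak velocity| on
|displacement| (statsmodels), with an intercept by default and a
through-origin variant, plus an optional displacement cap that reproduces
the range-restriction (truncation-bias) analyses: for the 10th-order,
λ = 65 sweep, the cap-5 slope exceeds the cap-11 slope under both fit
variants, and the property holds across other (order, λ) pairs. Of the two
published slope values, the cap-5 slope (17.143) is matched by the
through-origin fit (+1.0%) and the cap-11 slope (14.198) by the
with-intercept fit (−3.6%); the companion script reports both variants for
both caps.

## Minimum-time bounds

`T_m = 2·√(D/U)` with U the theoretical peak-acceleration (muscle-force)
parameter, in the data's own distance units. Fitting U to a (T, D) cloud
uses least squares in D given T: since `D = U·T²/4` is linear in U, the
optimum is closed-form (`U = ΣD·T²/4 / Σ(T²/4)²`); a generic nonlinear
optimiser would add nothing for a single linear parameter. A duration-cap
filter is provided (rather than hard-coded) for ceiling-effect exclusion of
slow movements whose displacements no longer parallel any time bound.

## Formant pipeline

Tracks are plain CSV/TSV (time + f1/f2/... columns, Hz); zero or negative
samples are gaps, never 0 Hz. Processing order matters and is fixed:
semitone conversion (`st = 12·log₂(f/1 Hz)`), spike trimming, zero-phase
low-pass smoothing of the *displacement* contour at 20 Hz (4th-order
Butterworth, `sosfiltfilt`, so extrema do not shift), then differentiation —
the velocity itself is never smoothed, so peak-velocity magnitudes are not
attenuated. Trimming replaces isolated single-sample excursions that jump
more than a threshold (default 1 st) away from both neighbours in the same
direction; this is a conservative stand-in for the original (unpublished)
trimming rules and deliberately cannot touch multi-sample rises.
Demarcation places syllable boundaries at the chosen extremum type (F1
minima, F2 minima, or F2 maxima) of the smoothed contour; the opposite
extremum inside each syllable splits onset from offset ramp; syllables
without exactly one interior opposite extremum are dropped rather than
guessed. The original study's manual seed-and-correct boundary loop is out
of scope; demarcation here is fully automatic.

## Synthetic data

The generator drives the model itself with alternating consonant/vowel
semitone targets (defaults: ~300 Hz and ~700 Hz, an F1 alternation of
glide–open-vowel syllables; 5 syllables of 180 ms; order 3; λ = 40; 200 Hz
sampling) and adds i.i.d. Gaussian noise on the semitone scale (default
0.2 st — a plausible formant-tracker jitter magnitude). Each track carries
exact ground truth: target boundaries, noiseless turning-point times
("landmarks"), and per-movement displacement/peak velocity. Because
trajectory extrema lag target switches by the approximation delay, the
landmarks — not the target boundaries — are what a demarcation step can
recover, and recovery is tested against them (≤ 10 ms noiseless;
displacement means within 2%). With 0.3 st noise, measured displacement
stays within 5% of truth on average and peak velocity carries a small
positive bias (residual passband noise in the unsmoothed derivative),
bounded by 10% in the tests and measured at ~3% under default settings.

Two seeded end-to-end experiments capture the package's central scientific
content:

* **Stiffness ranking** (`rank_stiffness_experiment`): two datasets with
  identical, long syllable durations (0.18–0.26 s) and ±3 st vowel-target
  jitter, λ = 40 vs 55; through-origin vp/d slopes rank the λs correctly in
  ≥ 95% of replicates. The long durations are essential: vp/d discriminates
  stiffness only when movements approximately attain their targets. In the
  truncation regime vp/d degenerates toward a pure duration effect
  (≈ 1/duration, λ cancelling), which is precisely the artifact the next
  experiment isolates — so the regime restriction is itself a finding the
  generator makes visible, not a convenience.
* **Truncation bias** (`truncation_bias_experiment`): long-syllable
  (0.15–0.25 s, "stressed") vs short-syllable (0.07–0.12 s, "unstressed")
  datasets at identical λ = 40; the short set fits a steeper vp/d slope in
  ≥ 95% of replicates — higher apparent stiffness with no stiffness
  difference in the generator.

What the generator does not emulate: LPC tracking artifacts beyond
single-sample spikes, coarticulatory target reassignment,
amplitude-dependent noise, or speaker variability. Passing tests therefore
demonstrate correctness of the measurement machinery and the in-model
mechanisms, not field validity on recorded speech.

## Numerical choices and limitations

* Order cap 32 (tested through 14); derivative chain via the exact
  polynomial recurrence `q_{k+1} = q_k' − λ·q_k`.
* Ties/degenerate inputs: displacement plateaus count one turning point at
  their first sample; movements below the displacement floor have undefined
  (not infinite) vp/d; all-zero displacement clouds fit U = 0 with a
  warning.
* Durations are reported in seconds internally and milliseconds in
  table-style outputs.
* The critical-point detector is grid-based by design; for publication-grade
  comparisons at coarse grids, refine the d2 grid rather than the
  threshold.
* TextGrid export writes the (trivial) Praat text format directly.
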