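# targetapprox

Simulation and kinematic analysis of speech movements as **target
approximation (TA) dynamics**, with a formant measurement pipeline.

## The problem

Speech articulators (and the formant trajectories they produce) move toward
successive phonetic goals but rarely reach them: under time pressure,
movements are cut short (*undershoot*). Two kinematic summaries are standard
in the speech motor-control literature:

* the **vp/d ratio** — peak velocity over movement displacement, usually
  estimated as the slope of a linear regression of peak velocity on
  displacement across movements, and conventionally read as an index of
  gestural *stiffness*;
* the **minimum-time bound** — Nelson's relation `T_m = 2·√(D/U)` giving the
  shortest time a frictionless movement of distance `D` can take under peak
  acceleration `U`.

A puzzling, repeatedly observed pattern is that *unstressed* syllables show
higher measured vp/d than *stressed* ones, as if less prominent syllables
were produced with greater stiffness. This package implements the modelling
apparatus that explains that pattern as a **truncation artifact**: when
movements are cut short, measured vp/d points are confined to the steep
lower-left part of the peak-velocity-vs-displacement function, and a linear
fit over that restricted range is steeper — with no stiffness difference at
all.

## The model

Each phonetic target is a linear forcing function `x(t) = m·t + b`. Within
one target interval the trajectory follows a critically damped N-th order
linear system with rate (stiffness) parameter λ:

    y(t) = x(t) + e^(−λt) · Σ_{k=0}^{N−1} c_k t^k

The coefficients `c_k` are fixed by the state at the interval onset
(`c_0 = y(0) − b`, `c_1 = y'(0) + c_0·λ − m`, and a recursion for k ≥ 2).
At every target boundary the **full state** — displacement and derivatives
up to order N−1 — transfers to the next interval, so trajectories are
C^(N−1)-smooth and momentum carries across movement boundaries. The
third-order case is the familiar qTA model of pitch-target approximation;
the order is variable here (tested through N = 14 and capped at 32).

Modules:

| module | contents |
| --- | --- |
| `targetapprox.model` | closed-form trajectory generation, state transfer |
| `targetapprox.kinematics` | turning points, per-movement measures, vp/d regressions, d2 sweeps, critical-duration detection |
| `targetapprox.bounds` | minimum-time bound `T_m = 2√(D/U)` and the closed-form least-squares fit of `U` |
| `targetapprox.formants` | semitone conversion (re 1 Hz), 20-Hz zero-phase smoothing, spike trimming, extremum-based syllable demarcation, measurement tables, TextGrid export |
| `targetapprox.synth` | synthetic multi-syllable track generator with exact ground truth, plus seeded end-to-end experiments |
| `targetapprox.cli` | `targetapprox` command with `simulate`, `measure`, `sweep`, `fit-bounds`, `synth`, `reproduce-table5`, `reproduce-fig12` |

## Worked example

Simulate a three-movement sequence (start at rest at 85; static targets
80 → 100 → 80; intervals 0.2 / 0.1 / 0.3 s) with a 10th-order system at
λ = 65, and measure the middle movement from its visible landmarks:

```python
import numpy as np
from targetapprox import (BoundaryState, ModelConfig, TargetSpec, simulate_sequence,
                          find_turning_points, measure_movement,
                          run_d2_sweep, critical_point)

cfg = ModelConfig(order=10, lam=65.0, dt=0.001)
targets = [TargetSpec(0, b, d) for b, d in ((80, 0.2), (100, 0.1), (80, 0.3))]
traj = simulate_sequence(targets, cfg, BoundaryState.at_rest(85.0, 10))

tps = find_turning_points(traj.y)
mm = measure_movement(traj, tps[0], tps[1])
print(f"measured duration : {mm.duration*1000:.1f} ms (intended d2 = 100 ms)")
print(f"displacement      : {mm.displacement:.2f} (ideal 20)")
print(f"peak velocity     : {mm.peak_velocity:.1f}")
print(f"vp/d ratio        : {mm.vpd:.2f} 1/s")

cp = critical_point(run_d2_sweep(10, 65.0, np.arange(0.010, 0.4001, 0.001)))
print(f"critical point    : {cp.duration_ms:.1f} ms, displacement {cp.displacement:.1f}, "
      f"peak velocity {cp.peak_velocity:.1f}")
```

prints

```
measured duration : 143.0 ms (intended d2 = 100 ms)
displacement      : 14.07 (ideal 20)
peak velocity     : 170.0
vp/d ratio        : 12.08 1/s
critical point    : 146.0 ms, displacement 14.4, peak velocity 170.5
```

The measured movement lasts 43 ms longer than the target interval that
produced it (the high-order system responds sluggishly, and the turning
point carries into the next interval) and attains only 14 of the ideal
20 units of displacement — undershoot, quantified from visible landmarks
only. The critical point is where peak velocity effectively stops growing
with displacement (incremental gain < 1 per unit): beyond ~146 ms this
10th-order, λ = 65 system gains displacement without gaining peak velocity.

The same analyses are available from the shell, e.g.

```sh
targetapprox reproduce-table5          # 3x9 critical-duration table
targetapprox reproduce-fig12           # capped vp/d regression slopes
targetapprox synth --seed 1 --out track.csv
targetapprox measure track.csv --out measures.csv
```

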