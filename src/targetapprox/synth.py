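"""Synthetic formant-track generation with known ground truth.

Emulates the alternating rise/fall formant trajectories of repeated CV
syllable sequences (e.g. [wawawawawa]) by driving the target approximation
model with alternating semitone targets, then adding i.i.d. Gaussian
measurement noise on the semitone scale.  Because the generator is the
forward model itself, every generated track carries exact ground truth
(boundary times, per-movement displacement and peak velocity measured on the
noiseless trajectory), which makes the measurement pipeline testable without
any recordings.

What this emulates: smooth TA dynamics, syllable-rate alternation,
measurement noise.  What it does not: LPC tracking artifacts (beyond
single-sample spikes, available separately for trim tests), coarticulatory
target reassignment, or amplitude-dependent noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .kinematics import find_turning_points, measure_movement
from .model import BoundaryState, ModelConfig, TargetSpec, simulate_sequence

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_track",
    "pipeline_vpd_slope",
    "rank_stiffness_experiment",
    "truncation_bias_experiment",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration for one synthetic multi-syllable track.

    Each syllable contributes two target intervals: an onset ramp toward the
    vowel target (``high_st``) and an offset ramp back toward the consonant
    target (``low_st``), each lasting half the syllable duration.  Default
    heights are semitone values of roughly 300 Hz and 700 Hz, a [w]-to-[a]
    F1 alternation.  ``noise_sd`` is additive Gaussian noise on the semitone
    scale (default 0.2 st).
    """

    n_syllables: int = 5
    low_st: float = 98.75  # ~300 Hz
    high_st: float = 113.42  # ~700 Hz
    syllable_durations: tuple[float, ...] | None = None  # default 0.18 s each
    order: int = 3
    lam: float = 40.0
    noise_sd: float = 0.2
    height_jitter_st: float = 0.0  # uniform +/- jitter on the vowel target per syllable
    fs: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_syllables < 1:
            raise ValueError("need at least one syllable")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        durs = self.syllable_durations
        if durs is None:
            durs = (0.18,) * self.n_syllables
        durs = tuple(float(d) for d in durs)
        if len(durs) != self.n_syllables:
            raise ValueError("need one duration per syllable")
        if any(d <= 0 for d in durs):
            raise ValueError("syllable durations must be positive")
        object.__setattr__(self, "syllable_durations", durs)


@dataclass
class GroundTruth:
    """Exact generator-side record for one synthetic track.

    ``boundaries`` are target-interval end times; ``landmarks`` are the times
    of the noiseless trajectory's turning points.  The landmarks, not the
    target boundaries, are the observable truth a demarcation step can
    recover: the trajectory extrema lag the target switches by the
    approximation delay.
    """

    boundaries: np.ndarray
    landmarks: np.ndarray
    movement_displacement: np.ndarray  # per movement, from noiseless turning points
    movement_peak_velocity: np.ndarray
    movement_duration: np.ndarray
    spec: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "boundaries_s": self.boundaries.tolist(),
            "landmarks_s": self.landmarks.tolist(),
            "movement_displacement_st": self.movement_displacement.tolist(),
            "movement_peak_velocity_st_s": self.movement_peak_velocity.tolist(),
            "movement_duration_s": self.movement_duration.tolist(),
            "spec": self.spec,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_track(spec: SyntheticSpec):
    """Simulate one noisy multi-syllable semitone track plus its ground truth.

    Returns ``(track, truth)`` where ``track`` is a
    :class:`~targetapprox.formants.SemitoneTrack` sampled at ``spec.fs`` and
    ``truth`` is a :class:`GroundTruth`.  Reproducible: the same spec (seed
    included) always yields the identical track.
    """
    from .formants import SemitoneTrack

    rng = np.random.default_rng(spec.seed)
    jit = rng.uniform(-spec.height_jitter_st, spec.height_jitter_st, spec.n_syllables)
    targets = []
    for d, dj in zip(spec.syllable_durations, jit):
        targets.append(TargetSpec(0.0, spec.high_st + dj, d / 2.0))
        targets.append(TargetSpec(0.0, spec.low_st, d / 2.0))
    dt = 1.0 / spec.fs
    config = ModelConfig(order=spec.order, lam=spec.lam, dt=dt)
    initial = BoundaryState.at_rest(spec.low_st, spec.order)
    traj = simulate_sequence(targets, config, initial)

    # ground-truth kinematics from the noiseless trajectory's turning points
    tps = find_turning_points(traj.y)
    disp, pkv, dur = [], [], []
    marks = [0] + tps if tps and tps[0] != 0 else tps or [0]
    for a, b in zip(marks[:-1], marks[1:]):
        mm = measure_movement(traj, a, b, allow_start=True)
        disp.append(mm.displacement)
        pkv.append(mm.peak_velocity)
        dur.append(mm.duration)

    noisy = traj.y + rng.normal(0.0, spec.noise_sd, size=traj.y.shape)
    track = SemitoneTrack(
        t=traj.t,
        st=noisy,
        meta={"synthetic": True, "seed": spec.seed, "lam": spec.lam, "order": spec.order},
    )
    truth = GroundTruth(
        boundaries=traj.boundaries.copy(),
        landmarks=traj.t[tps],
        movement_displacement=np.asarray(disp),
        movement_peak_velocity=np.asarray(pkv),
        movement_duration=np.asarray(dur),
        spec=asdict(spec),
    )
    return track, truth


def pipeline_vpd_slope(track, fit_intercept: bool = True, cutoff: float = 20.0,
                       mode: str = "f1min") -> float | None:
    """Run the full measurement pipeline on a track and return the vp/d slope.

    trim -> zero-phase low-pass -> demarcate -> per-movement measurement ->
    OLS of |peak velocity| on |displacement|.  Returns None when the track
    yields fewer than two usable movements.
    """
    from .formants import demarcate, measure_syllables, smooth_track, trim_track
    from .kinematics import vpd_regression

    smooth = smooth_track(trim_track(track), cutoff=cutoff)
    try:
        dem = demarcate(smooth, mode=mode)
    except ValueError:
        return None
    table = measure_syllables(smooth, dem)
    ok = table[~table["excluded"] & np.isfinite(table["vpd"])]
    if len(ok) < 2:
        return None
    reg = vpd_regression(
        (ok["displacement_st"].to_numpy(), ok["peak_velocity_st_s"].to_numpy()),
        fit_intercept=fit_intercept,
    )
    return reg.slope


def _replicate_seeds(seed: int, n: int, streams: int):
    ss = np.random.SeedSequence(seed)
    state = np.random.default_rng(ss).integers(0, 2**31 - 1, size=(n, streams))
    return state


def rank_stiffness_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    lam_low: float = 40.0,
    lam_high: float = 55.0,
    duration_range: tuple[float, float] = (0.18, 0.26),
    height_jitter_st: float = 3.0,
    noise_sd: float = 0.2,
) -> float:
    """Fraction of replicates in which vp/d ranks two stiffness levels correctly.

    Each replicate draws one set of five syllable durations, generates one
    dataset per stiffness level with those same durations, and compares
    through-origin vp/d regression slopes.  The durations are long enough for
    near-target attainment and the vowel targets carry amplitude jitter:
    vp/d discriminates stiffness only in this regime.  When movements are
    instead truncated, vp/d approaches a pure duration effect and the
    ranking degrades -- which is precisely the truncation artifact probed by
    :func:`truncation_bias_experiment`.
    """
    seeds = _replicate_seeds(seed, n_replicates, 3)
    correct = total = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(seeds[r, 0])
        durs = tuple(rng.uniform(*duration_range, 5))
        slopes = []
        for lam, s in ((lam_low, seeds[r, 1]), (lam_high, seeds[r, 2])):
            spec = SyntheticSpec(
                n_syllables=5, syllable_durations=durs, lam=lam, order=3,
                noise_sd=noise_sd, height_jitter_st=height_jitter_st, seed=int(s),
            )
            track, _ = generate_track(spec)
            slopes.append(pipeline_vpd_slope(track, fit_intercept=False))
        if None in slopes:
            continue
        total += 1
        correct += slopes[1] > slopes[0]
    if total == 0:
        raise RuntimeError("no usable replicates")
    return correct / total


def truncation_bias_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    lam: float = 40.0,
    long_range: tuple[float, float] = (0.15, 0.25),
    short_range: tuple[float, float] = (0.07, 0.12),
    noise_sd: float = 0.2,
) -> float:
    """Fraction of replicates in which truncation inflates the vp/d slope.

    Generates, per replicate, a long-syllable ("stressed") and a
    short-syllable ("unstressed") dataset with the *same* stiffness, and
    compares fitted vp/d slopes.  Shorter syllables truncate the movements,
    which restricts the displacement range and steepens the fitted slope --
    an apparent stiffness difference with no stiffness difference in the
    generator.
    """
    seeds = _replicate_seeds(seed, n_replicates, 3)
    higher = total = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(seeds[r, 0])
        slopes = []
        for rng_range, s in ((long_range, seeds[r, 1]), (short_range, seeds[r, 2])):
            durs = tuple(rng.uniform(*rng_range, 5))
            spec = SyntheticSpec(
                n_syllables=5, syllable_durations=durs, lam=lam, order=3,
                noise_sd=noise_sd, seed=int(s),
            )
            track, _ = generate_track(spec)
            slopes.append(pipeline_vpd_slope(track, fit_intercept=True))
        if None in slopes:
            continue
        total += 1
        higher += slopes[1] > slopes[0]
    if total == 0:
        raise RuntimeError("no usable replicates")
    return higher / total
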