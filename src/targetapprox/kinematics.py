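"""Per-movement kinematic measurement and the d2-sweep analyses.

Measurements are taken from visible landmarks only (turning points of the
displacement trajectory), never from the underlying target intervals, which
is how kinematic measurements must be taken from real speech where target
intervals are unobservable.  The module also provides the three-movement
sweep protocol that maps out peak velocity as a function of movement
displacement, the plateau ("critical duration") detector, and the capped
vp/d regressions that demonstrate truncation-induced slope bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BoundaryState, ModelConfig, TargetSpec, Trajectory, simulate_sequence

__all__ = [
    "MovementMeasure",
    "VpdRegression",
    "SweepResult",
    "SweepProtocol",
    "CriticalPoint",
    "NoPlateauError",
    "find_turning_points",
    "measure_movement",
    "vpd_regression",
    "run_d2_sweep",
    "critical_point",
    "movement_specific_vpd_curve",
]

#: Movements smaller than this are treated as "no movement": their vp/d ratio
#: is undefined rather than blowing up.
DISPLACEMENT_FLOOR = 1e-9


@dataclass(frozen=True)
class MovementMeasure:
    """Kinematics of one unidirectional movement between two turning points.

    ``displacement`` and ``peak_velocity`` are signed; ``vpd`` is the
    absolute ratio |peak velocity| / |displacement| (1/s), or None when the
    displacement is below the floor.
    """

    displacement: float
    duration: float
    peak_velocity: float
    vpd: float | None

    @property
    def defined(self) -> bool:
        return self.vpd is not None


@dataclass(frozen=True)
class VpdRegression:
    """OLS fit of |peak velocity| on |displacement| across movements."""

    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class SweepResult:
    """(d2, measured duration, displacement, peak velocity) per sweep point."""

    points: np.ndarray  # columns: d2_intended, duration, displacement, peak_velocity
    skipped: list = field(default_factory=list)

    @property
    def d2(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def duration(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def displacement(self) -> np.ndarray:
        return self.points[:, 2]

    @property
    def peak_velocity(self) -> np.ndarray:
        return self.points[:, 3]


@dataclass(frozen=True)
class SweepProtocol:
    """Fixed part of the three-movement simulation protocol.

    Defaults are the standard simulation conditions: start at rest at
    y0 = 85; static targets at heights 80, 100, 80; first and third interval
    durations 0.2 s and 0.3 s; the middle interval duration d2 is the swept
    variable.
    """

    y0: float = 85.0
    b: tuple[float, float, float] = (80.0, 100.0, 80.0)
    m: float = 0.0
    d1: float = 0.2
    d3: float = 0.3

    def targets(self, d2: float) -> list[TargetSpec]:
        b1, b2, b3 = self.b
        return [
            TargetSpec(self.m, b1, self.d1),
            TargetSpec(self.m, b2, d2),
            TargetSpec(self.m, b3, self.d3),
        ]


@dataclass(frozen=True)
class CriticalPoint:
    """First sweep point past which peak velocity gains < threshold per unit displacement."""

    duration_ms: float
    displacement: float
    peak_velocity: float
    d2: float


class NoPlateauError(RuntimeError):
    """The incremental-slope criterion was never met within the sweep grid."""

    def __init__(self, largest_slope_drop: float):
        self.largest_slope_drop = largest_slope_drop
        super().__init__(
            "no plateau within sweep grid; smallest incremental slope was "
            f"{largest_slope_drop:.3g}"
        )


def find_turning_points(y, t=None) -> list[int]:
    """Indices of strict local extrema of ``y`` (sign changes of the first difference).

    Plateaus count once, at their first sample.  Endpoints are never turning
    points.  ``t`` is accepted for interface symmetry but unused.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples to find turning points")
    diff = np.sign(np.diff(y))
    idx: list[int] = []
    prev_sign = 0
    prev_pos = 0  # index where the previous nonzero-sign run started
    for i, s in enumerate(diff):
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            idx.append(prev_pos)
        prev_sign = s
        prev_pos = i + 1
    # a sign change at position i means samples ..i were moving one way and
    # i.. the other; the extremum is the first sample of the in-between
    # plateau, which is i itself when there is no plateau.
    return _plateau_starts(y, idx)


def _plateau_starts(y: np.ndarray, idx: list[int]) -> list[int]:
    out = []
    for i in idx:
        j = i
        while j > 0 and y[j - 1] == y[j]:
            j -= 1
        out.append(j if j > 0 else i)
    return out


def measure_movement(
    traj: Trajectory, i: int, j: int, allow_start: bool = False
) -> MovementMeasure:
    """Kinematics of the movement bounded by sample indices ``i`` and ``j``.

    ``i`` and ``j`` are normally turning points; with ``allow_start`` the
    trajectory's first sample may serve as the left landmark for the first
    movement of a sequence.  Peak velocity is the signed extremum of the
    velocity over ``(i, j]``.
    """
    if not (0 <= i < j < len(traj.t)):
        raise ValueError(f"invalid movement bounds ({i}, {j})")
    if i == 0 and not allow_start:
        raise ValueError("trajectory start is not a turning point (pass allow_start=True)")
    displacement = traj.y[j] - traj.y[i]
    duration = traj.t[j] - traj.t[i]
    seg = traj.v[i + 1 : j + 1]
    peak = seg[np.argmax(np.abs(seg))]
    if abs(displacement) > DISPLACEMENT_FLOOR:
        vpd = abs(peak) / abs(displacement)
    else:
        vpd = None
    return MovementMeasure(displacement, duration, peak, vpd)


def vpd_regression(
    measures,
    fit_intercept: bool = True,
    displacement_cap: float | None = None,
) -> VpdRegression:
    """OLS of |peak velocity| on |displacement|, optionally capped.

    ``measures`` may be a list of :class:`MovementMeasure` or a pair of
    arrays ``(displacement, peak_velocity)``.  Points with displacement above
    ``displacement_cap`` are excluded before fitting, mirroring the
    range-restriction (truncation) analyses.
    """
    import statsmodels.api as sm

    if isinstance(measures, tuple):
        d = np.abs(np.asarray(measures[0], dtype=float))
        vp = np.abs(np.asarray(measures[1], dtype=float))
    else:
        usable = [mm for mm in measures if mm.defined]
        d = np.array([abs(mm.displacement) for mm in usable])
        vp = np.array([abs(mm.peak_velocity) for mm in usable])
    if displacement_cap is not None:
        keep = d <= displacement_cap
        d, vp = d[keep], vp[keep]
    if d.size < 2:
        raise ValueError(f"need at least 2 points to regress, have {d.size}")
    X = sm.add_constant(d) if fit_intercept else d[:, None]
    res = sm.OLS(vp, X).fit()
    if fit_intercept:
        intercept, slope = res.params
        r2 = res.rsquared
    else:
        slope, intercept = res.params[0], 0.0
        # report centred R^2 so the two fit variants are comparable
        ss_res = float(np.sum(res.resid**2))
        ss_tot = float(np.sum((vp - vp.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return VpdRegression(float(slope), float(intercept), float(np.clip(r2, 0.0, 1.0)), int(d.size))


def run_d2_sweep(
    order: int,
    lam: float,
    d2_grid,
    protocol: SweepProtocol | None = None,
    dt: float = 0.001,
) -> SweepResult:
    """Sweep the middle-target duration and measure the middle movement.

    For each ``d2`` the three-target sequence is simulated, and the movement
    bounded by the first and second turning points (the rise toward the
    middle target, including its carry-over into the third interval) is
    measured.  Sweep points whose trajectory shows fewer than two turning
    points (d2 too short to leave a landmark) are skipped and reported in
    ``SweepResult.skipped``.
    """
    protocol = protocol or SweepProtocol()
    d2_grid = np.asarray(d2_grid, dtype=float)
    if d2_grid.size and not np.all(np.diff(d2_grid) > 0):
        raise ValueError("d2 grid must be strictly increasing")
    if np.any(d2_grid <= 0):
        raise ValueError("d2 values must be positive")
    config = ModelConfig(order=order, lam=lam, dt=dt)
    initial = BoundaryState.at_rest(protocol.y0, order)

    rows, skipped = [], []
    for d2 in d2_grid:
        traj = simulate_sequence(protocol.targets(d2), config, initial)
        tps = find_turning_points(traj.y)
        if len(tps) < 2:
            skipped.append(float(d2))
            continue
        mm = measure_movement(traj, tps[0], tps[1])
        rows.append((d2, mm.duration, abs(mm.displacement), abs(mm.peak_velocity)))
    return SweepResult(points=np.asarray(rows).reshape(-1, 4), skipped=skipped)


def critical_point(sweep: SweepResult, threshold: float = 1.0) -> CriticalPoint:
    """Detect where the vp-over-displacement curve flattens.

    Scans successive sweep points in increasing displacement order and
    returns the first point at which the incremental slope
    delta(peak velocity) / delta(displacement) drops below ``threshold``
    (default 1: peak velocity gains less than one unit per unit of added
    displacement).  The duration reported is the measured turning-point
    to turning-point movement duration, in ms.
    """
    pts = sweep.points
    if len(pts) < 2:
        raise ValueError("sweep must contain at least 2 points")
    if not np.isfinite(threshold):
        p = pts[0]
        return CriticalPoint(p[1] * 1000.0, p[2], p[3], p[0])
    order = np.argsort(pts[:, 2], kind="stable")
    pts = pts[order]
    smallest = np.inf
    for a, b in zip(pts[:-1], pts[1:]):
        dd = b[2] - a[2]
        if dd <= DISPLACEMENT_FLOOR:
            continue
        slope = (b[3] - a[3]) / dd
        smallest = min(smallest, slope)
        if slope < threshold:
            return CriticalPoint(b[1] * 1000.0, b[2], b[3], b[0])
    raise NoPlateauError(smallest)


def movement_specific_vpd_curve(measures) -> np.ndarray:
    """(duration, vpd) pairs for movements with a defined vp/d ratio.

    Flat movements (displacement below the floor) are excluded.  Suitable for
    overlaying groups of movements as vp/d against movement duration.
    """
    pairs = [(mm.duration, mm.vpd) for mm in measures if mm.defined]
    return np.asarray(pairs).reshape(-1, 2)
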