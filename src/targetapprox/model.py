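"""Closed-form generation of target-approximation trajectories.

The target approximation (TA) model treats each phonetic unit as a linear
target ``x(t) = m t + b`` that drives the articulatory/acoustic state through
a critically damped N-th order linear system with rate parameter ``lam``
(related to stiffness).  Within one target interval the solution is

    y(t) = x(t) + exp(-lam * t) * sum_{k=0}^{N-1} c_k t^k

with the polynomial coefficients fixed by the state (displacement and
derivatives up to order N-1) at the interval onset.  At each interval
boundary the full state is transferred to the next interval, which makes the
trajectory and its first N-1 derivatives continuous across boundaries and
carries momentum from one movement into the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TargetSpec",
    "ModelConfig",
    "BoundaryState",
    "CoefficientVector",
    "Trajectory",
    "ConfigurationError",
    "MAX_DERIVATIVE_ORDER",
    "ta_coefficients",
    "ta_evaluate",
    "ta_derivative",
    "simulate_sequence",
]

#: Highest supported model / derivative order.  The coefficient recursion is
#: exact in float64 well beyond the 14th order used in high-order simulations;
#: the cap is a documented guard, not a numerical wall.
MAX_DERIVATIVE_ORDER = 32


class ConfigurationError(ValueError):
    """Raised for invalid model or target configuration."""


@dataclass(frozen=True)
class TargetSpec:
    """One phonetic target: the forcing function ``x(t) = m t + b``.

    Parameters
    ----------
    m : float
        Target slope in displacement units per second.  A static target
        (``m = 0``) is an equilibrium point, as in classic mass-spring models.
    b : float
        Target height in displacement units.
    d : float
        Duration of the target interval in seconds; must be positive.
    """

    m: float
    b: float
    d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.m) or not np.isfinite(self.b):
            raise ConfigurationError("target slope and height must be finite")
        if not (self.d > 0):
            raise ConfigurationError(f"target duration must be > 0, got {self.d}")


@dataclass(frozen=True)
class ModelConfig:
    """Model order, approximation rate and sampling step.

    ``order`` is the order N of the critically damped system (the number of
    polynomial coefficients in the interval solution).  ``lam`` is the rate of
    target approximation in 1/s; larger values mean stiffer, faster
    convergence.  ``dt`` is the output sampling step in seconds.
    """

    order: int
    lam: float
    dt: float = 0.001

    def __post_init__(self) -> None:
        if not (isinstance(self.order, (int, np.integer)) and self.order >= 1):
            raise ConfigurationError(f"order must be an integer >= 1, got {self.order}")
        if self.order > MAX_DERIVATIVE_ORDER:
            raise ConfigurationError(
                f"order {self.order} exceeds supported cap {MAX_DERIVATIVE_ORDER}"
            )
        if not (self.lam > 0):
            raise ConfigurationError(f"lam must be > 0, got {self.lam}")
        if not (self.dt > 0):
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")


@dataclass(frozen=True)
class BoundaryState:
    """Displacement and derivatives 1..N-1 at a movement onset."""

    derivs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.derivs, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ConfigurationError("state must be a 1-d vector of length >= 1")
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError("state entries must be finite")
        object.__setattr__(self, "derivs", arr)

    @classmethod
    def at_rest(cls, y0: float, order: int) -> "BoundaryState":
        """State at displacement ``y0`` with all higher derivatives zero."""
        derivs = np.zeros(order)
        derivs[0] = y0
        return cls(derivs)

    @property
    def order(self) -> int:
        return self.derivs.size


@dataclass(frozen=True)
class CoefficientVector:
    """Polynomial coefficients c_0..c_{N-1} of one target interval."""

    c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))

    @property
    def order(self) -> int:
        return self.c.size


@dataclass
class Trajectory:
    """Uniformly sampled displacement/velocity series with interval boundaries.

    ``boundaries`` holds the end time of every target interval (snapped to the
    sampling grid), so ``boundaries[-1] == t[-1]``.
    """

    t: np.ndarray
    y: np.ndarray
    v: np.ndarray
    boundaries: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.y) == len(self.v)):
            raise ValueError("t, y, v must have equal length")

    def to_frame(self):
        """Return the series as a pandas DataFrame (time, displacement, velocity)."""
        import pandas as pd

        return pd.DataFrame({"time": self.t, "displacement": self.y, "velocity": self.v})

    def to_csv(self, path) -> None:
        """Write tabular text with boundary times in a header comment."""
        bstr = ", ".join(f"{b:.6f}" for b in self.boundaries)
        with open(path, "w") as fh:
            fh.write(f"# boundaries_s: {bstr}\n")
            if self.meta:
                for key, val in sorted(self.meta.items()):
                    fh.write(f"# {key}: {val}\n")
            self.to_frame().to_csv(fh, index=False)


def _exp_poly_chain(c: np.ndarray, lam: float, kmax: int) -> list[np.ndarray]:
    """Polynomial parts q_k of d^k/dt^k [exp(-lam t) p(t)] = exp(-lam t) q_k(t).

    Uses the recurrence q_{k+1} = q_k' - lam * q_k, which is exact.
    """
    qs = [np.asarray(c, dtype=float)]
    for _ in range(kmax):
        q = qs[-1]
        nxt = -lam * q
        if q.size > 1:
            nxt[:-1] += q[1:] * np.arange(1, q.size)
        qs.append(nxt)
    return qs


def _polyval(q: np.ndarray, t: np.ndarray | float):
    return np.polynomial.polynomial.polyval(t, q)


def ta_coefficients(
    state: BoundaryState, target: TargetSpec, lam: float, order: int
) -> CoefficientVector:
    """Coefficients c_0..c_{N-1} matching the interval-onset state.

    Solves, in closed form, for the polynomial such that ``y(t)`` and its
    derivatives up to order N-1 equal the supplied state at local time 0:

        c_k = (y^(k)(0) - x^(k)(0)) / k!  -  sum_{j=1}^{k} (-lam)^j / j! * c_{k-j}

    This is the standard recursion written with running factorial ratios so
    no explicit k! * lam^k products appear (stable to high order).  For
    k = 0, 1 it reduces to the familiar third-order (qTA) forms
    ``c_0 = y(0) - b`` and ``c_1 = y'(0) + c_0 lam - m``.
    """
    if not (lam > 0):
        raise ConfigurationError(f"lam must be > 0, got {lam}")
    if order < 1 or order > MAX_DERIVATIVE_ORDER:
        raise ConfigurationError(f"order must be in 1..{MAX_DERIVATIVE_ORDER}")
    if state.order != order:
        raise ConfigurationError(
            f"state length {state.order} does not match order {order}"
        )

    y0 = state.derivs
    # x(t) = m t + b: derivatives at 0 are (b, m, 0, 0, ...)
    x0 = np.zeros(order)
    x0[0] = target.b
    if order > 1:
        x0[1] = target.m

    # prefactors (-lam)^j / j! by running product
    pref = np.empty(order)
    pref[0] = 1.0
    for j in range(1, order):
        pref[j] = pref[j - 1] * (-lam) / j

    c = np.empty(order)
    inv_fact = 1.0
    for k in range(order):
        if k > 0:
            inv_fact /= k
        acc = (y0[k] - x0[k]) * inv_fact
        for j in range(1, k + 1):
            acc -= pref[j] * c[k - j]
        c[k] = acc
    return CoefficientVector(c)


def ta_evaluate(
    coeffs: CoefficientVector, target: TargetSpec, lam: float, times
) -> np.ndarray:
    """Displacement ``y(t) = x(t) + exp(-lam t) * sum_k c_k t^k`` per sample."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.empty(0)
    return target.m * t + target.b + np.exp(-lam * t) * _polyval(coeffs.c, t)


def ta_derivative(
    coeffs: CoefficientVector, target: TargetSpec, lam: float, times, k: int = 1
) -> np.ndarray:
    """Exact k-th time derivative of the interval solution.

    Differentiates the product ``exp(-lam t) p(t)`` analytically via the
    polynomial recurrence and adds the target derivative (``m`` for k = 1).
    """
    if k < 1:
        raise ConfigurationError("derivative order k must be >= 1")
    if k > MAX_DERIVATIVE_ORDER:
        raise ConfigurationError(
            f"derivative order {k} exceeds supported cap {MAX_DERIVATIVE_ORDER}"
        )
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.empty(0)
    qk = _exp_poly_chain(coeffs.c, lam, k)[k]
    out = np.exp(-lam * t) * _polyval(qk, t)
    if k == 1:
        out = out + target.m
    return out


def _state_at(
    coeffs: CoefficientVector, target: TargetSpec, lam: float, t_end: float, order: int
) -> BoundaryState:
    """Analytic state (y and derivatives 1..N-1) at local time ``t_end``."""
    qs = _exp_poly_chain(coeffs.c, lam, order - 1)
    e = np.exp(-lam * t_end)
    derivs = np.empty(order)
    derivs[0] = target.m * t_end + target.b + e * _polyval(qs[0], t_end)
    if order > 1:
        derivs[1] = target.m + e * _polyval(qs[1], t_end)
    for k in range(2, order):
        derivs[k] = e * _polyval(qs[k], t_end)
    return BoundaryState(derivs)


def simulate_sequence(
    targets: list[TargetSpec],
    config: ModelConfig,
    initial: BoundaryState,
    lams: list[float] | None = None,
) -> Trajectory:
    """Simulate consecutive target approximation movements with state transfer.

    Each target interval is solved in closed form on a local time axis starting
    at 0; at the interval end the full analytic state (displacement plus
    derivatives 1..N-1) becomes the initial state of the next interval.  The
    output grid is strictly uniform: the boundary sample belongs to the
    outgoing interval, and the incoming interval starts one step later.

    Parameters
    ----------
    targets : list of TargetSpec
        At least one target, in temporal order.
    config : ModelConfig
        Order, shared rate ``lam`` and sampling step.
    initial : BoundaryState
        State at t = 0; length must equal the model order.
    lams : list of float, optional
        Per-target approximation rates.  Defaults to ``config.lam`` shared by
        all targets, which is the usual simulation setting.
    """
    if not targets:
        raise ConfigurationError("at least one target is required")
    if initial.order != config.order:
        raise ConfigurationError(
            f"initial state length {initial.order} does not match order {config.order}"
        )
    if lams is None:
        lams = [config.lam] * len(targets)
    if len(lams) != len(targets):
        raise ConfigurationError("lams must have one entry per target")

    order, dt = config.order, config.dt
    state = initial
    ts, ys, vs = [], [], []
    boundaries = []
    snapped = False
    t_offset = 0.0

    for target, lam in zip(targets, lams):
        n = int(round(target.d / dt))
        if n < 1:
            n = 1
        if abs(n * dt - target.d) > 1e-12:
            snapped = True
        local = np.arange(n + 1) * dt  # [0, d] inclusive of the end sample
        coeffs = ta_coefficients(state, target, lam, order)
        y = ta_evaluate(coeffs, target, lam, local)
        v = ta_derivative(coeffs, target, lam, local, k=1)
        sl = slice(None) if not ts else slice(1, None)
        ts.append(t_offset + local[sl])
        ys.append(y[sl])
        vs.append(v[sl])
        state = _state_at(coeffs, target, lam, n * dt, order)
        t_offset += n * dt
        boundaries.append(t_offset)

    meta = {"order": order, "dt": dt}
    if snapped:
        meta["boundaries_snapped_to_grid"] = True
    return Trajectory(
        t=np.concatenate(ts),
        y=np.concatenate(ys),
        v=np.concatenate(vs),
        boundaries=np.asarray(boundaries),
        dt=dt,
        meta=meta,
    )
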