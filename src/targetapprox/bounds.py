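"""Minimum-time movement bounds and fitting of the force parameter U.

For a frictionless movement of distance D under constant acceleration and
deceleration of magnitude U, the shortest possible movement time is
``T_m = 2 * sqrt(D / U)`` (Nelson's minimum-time bound).  All physically
realizable (T, D) points lie on or to the right of the bound curve; fitting
U to an observed cloud of (duration, displacement) points gives an index of
the muscle force exerted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ConfigurationError

__all__ = ["BoundCurve", "FittedForce", "min_time", "fit_force"]


@dataclass(frozen=True)
class BoundCurve:
    """Minimum-time bound for a given peak-acceleration parameter U."""

    U: float

    def __post_init__(self) -> None:
        if not (self.U > 0):
            raise ConfigurationError(f"U must be > 0, got {self.U}")

    def min_time(self, D):
        return min_time(D, self.U)

    def max_distance(self, T):
        """Largest distance coverable in time T: D = U * T^2 / 4."""
        T = np.asarray(T, dtype=float)
        return self.U * T**2 / 4.0


@dataclass(frozen=True)
class FittedForce:
    """Least-squares estimate of U with fit diagnostics."""

    U: float
    rss: float
    n: int


def min_time(D, U: float):
    """Minimum movement time ``T_m = 2 * sqrt(D / U)`` for distance D."""
    if not (U > 0):
        raise ConfigurationError(f"U must be > 0, got {U}")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("distance D must be >= 0")
    out = 2.0 * np.sqrt(D / U)
    return float(out) if out.ndim == 0 else out


def fit_force(T, D, duration_cap: float | None = None) -> FittedForce:
    """Least-squares fit of ``D = U * T^2 / 4`` to (duration, displacement) points.

    The model is linear in U with regressor ``T^2 / 4``, so the optimum is
    closed form: ``U = sum(D * T^2/4) / sum((T^2/4)^2)``.  ``duration_cap``
    optionally excludes long movements first — useful when a slow condition
    shows a ceiling effect and no longer parallels any time bound.
    """
    T = np.asarray(T, dtype=float)
    D = np.asarray(D, dtype=float)
    if T.shape != D.shape:
        raise ValueError("T and D must have the same shape")
    if duration_cap is not None:
        keep = T <= duration_cap
        T, D = T[keep], D[keep]
    if T.size < 1:
        raise ValueError("need at least one (T, D) point")
    if np.any(T <= 0):
        raise ValueError("durations must be > 0")
    if np.any(D < 0):
        raise ValueError("displacements must be >= 0")
    x = T**2 / 4.0
    denom = float(x @ x)
    U = float((x @ D) / denom)
    if np.all(D == 0):
        import warnings

        warnings.warn("all displacements are zero; fitted U = 0", stacklevel=2)
        U = 0.0
    rss = float(np.sum((D - U * x) ** 2))
    return FittedForce(U=U, rss=rss, n=int(T.size))
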