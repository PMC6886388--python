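import numpy as np
import pytest

from targetapprox import SweepResult, run_d2_sweep

# The nine (order, lambda) conditions of the standard critical-duration table.
TABLE5_CONDITIONS = [
    (2, 23.0), (2, 29.0), (2, 37.0),
    (6, 48.0), (6, 64.0), (6, 80.0),
    (10, 65.0), (10, 85.0), (10, 105.0),
]

FINE_D2_GRID = np.arange(0.010, 0.4001, 0.001)


@pytest.fixture(scope="session")
def sweep_cache():
    """Memoized d2 sweeps so slow multi-condition tests share work."""
    cache: dict[tuple, SweepResult] = {}

    def get(order: int, lam: float, step: float = 0.001, dt: float = 0.001) -> SweepResult:
        key = (order, lam, step, dt)
        if key not in cache:
            grid = np.arange(0.010, 0.4001, step)
            cache[key] = run_d2_sweep(order, lam, grid, dt=dt)
        return cache[key]

    return get
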