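"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own quadrature and ranking code:
the AUT oracle is a dense rectangle-rule Riemann sum over the linear
interpolant, and the AUROC oracle is exhaustive pair enumeration.
"""

from __future__ import annotations

import numpy as np


def dense_aut(
    times: np.ndarray,
    values: np.ndarray,
    incision: float,
    end: float,
    threshold: float,
    dt: float = 0.001,
) -> float:
    """Rectangle-rule Riemann sum of max(threshold − S(t), 0) at step ``dt``."""
    grid = np.arange(incision, end, dt)
    s = np.interp(grid, times, values)
    return float(np.maximum(threshold - s, 0.0).sum() * dt)


def dense_differential_aut(
    t_renal: np.ndarray,
    v_renal: np.ndarray,
    t_periph: np.ndarray,
    v_periph: np.ndarray,
    renal_baseline: float,
    periph_baseline: float,
    incision: float,
    end: float,
    dt: float = 0.001,
) -> float:
    """Dense sum of the positive baseline-normalised peripheral−renal excess."""
    grid = np.arange(incision, end, dt)
    rn = np.interp(grid, t_renal, v_renal) * 100.0 / renal_baseline
    pn = np.interp(grid, t_periph, v_periph) * 100.0 / periph_baseline
    return float(np.maximum(pn - rn, 0.0).sum() * dt)


def pair_count_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by exhaustive enumeration of (positive, negative) pairs."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_piecewise_linear_trace(
    rng: np.random.Generator,
    max_duration: float = 40.0,
    max_spacing: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Random irregular trace with spacing below the default gap tolerance.

    Returns (times, values, incision_time, end_time) with a few minutes of
    pre-incision baseline included.
    """
    n = int(rng.integers(30, 120))
    steps = rng.uniform(0.05, max_spacing, size=n)
    times = np.concatenate(([0.0], np.cumsum(steps)))
    times = times[times <= max_duration + 8.0]
    values = np.clip(rng.uniform(55.0, 100.0, size=times.size), 0.0, 100.0)
    incision = float(times[-1] * 0.15)
    end = float(times[-1])
    return times, values, incision, end
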