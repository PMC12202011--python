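"""Independent oracles used by the test suite.

These deliberately avoid the package's solver/statistics code paths:
a fixed-step explicit Euler integrator, a textbook Spearman formula, and
dense-grid searches for the scenario inversions.
"""

from __future__ import annotations

import numpy as np


def euler_end_state(
    p0_mmhg: float,
    dose: float,
    dose_rate: float,
    params,
    n_steps: int = 100_000,
) -> tuple[float, float]:
    """Explicit Euler at dt = duration/n_steps; returns (end_pO2, end_radical).

    Only valid where dt * (k_decay + k_capture*[O2]) < 2 (stability); the
    calling tests choose their grid accordingly.
    """
    duration = dose / dose_rate
    dt = duration / n_steps
    g = params.g_consumption
    kc = params.k_capture
    kd = params.k_decay
    kr = params.recovery_rate
    m = params.metabolic_rate
    c = c_amb = p0_mmhg * params.solubility
    r = 0.0
    source = g * dose_rate
    for _ in range(n_steps):
        capture = kc * r * c
        dr = source - capture - kd * r
        dc = -capture + kr * (c_amb - c) - m
        r += dt * dr
        c += dt * dc
        if c < 0.0:
            c = 0.0
        if r < 0.0:
            r = 0.0
    return c / params.solubility, r


def spearman_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via the tie-corrected covariance-of-ranks formula."""

    def midranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    rx = midranks(np.asarray(x, dtype=float))
    ry = midranks(np.asarray(y, dtype=float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def grid_search_min_argument(evaluate, values) -> float:
    """Smallest grid value whose evaluation meets its threshold.

    ``evaluate(v)`` must return True when the target is met; assumes a
    monotone feasibility boundary. Returns the first feasible grid value.
    """
    for v in values:
        if evaluate(v):
            return float(v)
    raise AssertionError("no feasible grid value (oracle setup error)")
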