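"""Restricted cubic spline basis on log time.

The basis is the natural-spline parameterization used by flexible parametric
survival models: for knots k_min < k_1 < ... < k_m < k_max on log time u,

    s(u) = g0 + g1 u + sum_j g_{j+1} v_j(u)
    v_j(u) = (u - k_j)_+^3 - l_j (u - k_min)_+^3 - (1 - l_j)(u - k_max)_+^3
    l_j = (k_max - k_j) / (k_max - k_min)

which is cubic between the boundary knots and exactly linear outside them, so
evaluating beyond the last knot extrapolates linearly in log time.
"""

from __future__ import annotations

import numpy as np


def rcs_basis(u: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design columns [1, u, v_1(u), ..., v_m(u)] for internal knots m.

    Parameters
    ----------
    u : array of log times.
    knots : full increasing knot vector (boundary + internal), length m + 2.
    """
    u = np.asarray(u, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing with length >= 2")
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(u), u]
    for kj in knots[1:-1]:
        lj = (kmax - kj) / (kmax - kmin)
        v = (np.maximum(u - kj, 0.0) ** 3
             - lj * np.maximum(u - kmin, 0.0) ** 3
             - (1.0 - lj) * np.maximum(u - kmax, 0.0) ** 3)
        cols.append(v)
    return np.column_stack(cols)


def rcs_basis_deriv(u: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Derivative d/du of each basis column."""
    u = np.asarray(u, dtype=float)
    knots = np.asarray(knots, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.zeros_like(u), np.ones_like(u)]
    for kj in knots[1:-1]:
        lj = (kmax - kj) / (kmax - kmin)
        v = 3.0 * (np.maximum(u - kj, 0.0) ** 2
                   - lj * np.maximum(u - kmin, 0.0) ** 2
                   - (1.0 - lj) * np.maximum(u - kmax, 0.0) ** 2)
        cols.append(v)
    return np.column_stack(cols)


def default_knots(log_event_times: np.ndarray, n_internal: int = 3) -> np.ndarray:
    """Boundary knots at the extremes of uncensored log times; internal knots
    at evenly spaced percentiles (10/50/90 for the default of three)."""
    t = np.asarray(log_event_times, dtype=float)
    if t.size < n_internal + 2:
        raise ValueError("need at least n_internal + 2 distinct event times")
    if n_internal == 0:
        qs = np.array([0.0, 100.0])
    else:
        inner = np.linspace(10.0, 90.0, n_internal)
        qs = np.concatenate([[0.0], inner, [100.0]])
    knots = np.percentile(t, qs)
    knots = np.unique(knots)
    if knots.size < 2:
        raise ValueError("degenerate event-time distribution: identical times")
    return knots
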