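"""Inner integration kernel: one delay cycle of the forced Mackey-Glass DDE.

By the method of steps, over one delay interval the delayed term is a known
function (the stored previous cycle), so the cycle reduces to a scalar ODE
integrated with Heun's explicit trapezoidal rule.  The loop is sequential in
time and dominates the run time of every experiment, so a numba-compiled
version is used when numba is importable; a pure-Python twin with identical
arithmetic serves as fallback.  Both share one contract:

    prev    -- previous cycle, grid+1 samples, both cycle endpoints included
    forcing -- piecewise-constant forcing, one value per grid interval
    returns -- (next cycle, grid+1 samples; min |denominator| seen;
                index of first guard trip, or -1)

The Heun predictor reads the delayed value at the left grid endpoint, the
corrector at the right one; the forcing value of the interval is used for
both stages (it is genuinely constant within the interval).
"""

from __future__ import annotations

import numpy as np

from .exceptions import SingularityError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    njit = None
    HAVE_NUMBA = False


def _cycle_core(prev, forcing, h, eta, rho, guard):
    n = forcing.shape[0]
    out = np.empty(n + 1)
    x = prev[n]
    out[0] = x
    min_den = np.inf
    half = 0.5 * h
    for g in range(n):
        j = forcing[g]
        x1 = prev[g] + j
        if rho == 1.0:
            d1 = 1.0 + x1
        else:
            d1 = 1.0 + np.sign(x1) * np.abs(x1) ** rho
        a1 = abs(d1)
        if a1 < min_den:
            min_den = a1
        if a1 < guard or d1 != d1:
            return out, min_den, g
        k1 = -x + eta * x1 / d1
        x2 = prev[g + 1] + j
        if rho == 1.0:
            d2 = 1.0 + x2
        else:
            d2 = 1.0 + np.sign(x2) * np.abs(x2) ** rho
        a2 = abs(d2)
        if a2 < min_den:
            min_den = a2
        if a2 < guard or d2 != d2:
            return out, min_den, g
        k2 = -(x + h * k1) + eta * x2 / d2
        x = x + half * (k1 + k2)
        out[g + 1] = x
    return out, min_den, -1


if HAVE_NUMBA:
    _cycle_jit = njit(cache=True)(_cycle_core)
else:  # pragma: no cover
    _cycle_jit = None


def _cycle_py(prev, forcing, h, eta, rho, guard):
    """Pure-Python twin of ``_cycle_core`` operating on lists for speed."""
    n = len(forcing)
    prev_l = prev.tolist() if isinstance(prev, np.ndarray) else list(prev)
    forc_l = forcing.tolist() if isinstance(forcing, np.ndarray) else list(forcing)
    out = [0.0] * (n + 1)
    x = prev_l[n]
    out[0] = x
    min_den = float("inf")
    half = 0.5 * h
    is_linear = rho == 1.0
    for g in range(n):
        j = forc_l[g]
        x1 = prev_l[g] + j
        if is_linear:
            d1 = 1.0 + x1
        else:
            d1 = 1.0 + (abs(x1) ** rho if x1 >= 0 else -(abs(x1) ** rho))
        a1 = abs(d1)
        if a1 < min_den:
            min_den = a1
        if a1 < guard or d1 != d1:
            return np.asarray(out), min_den, g
        k1 = -x + eta * x1 / d1
        x2 = prev_l[g + 1] + j
        if is_linear:
            d2 = 1.0 + x2
        else:
            d2 = 1.0 + (abs(x2) ** rho if x2 >= 0 else -(abs(x2) ** rho))
        a2 = abs(d2)
        if a2 < min_den:
            min_den = a2
        if a2 < guard or d2 != d2:
            return np.asarray(out), min_den, g
        k2 = -(x + h * k1) + eta * x2 / d2
        x = x + half * (k1 + k2)
        out[g + 1] = x
    return np.asarray(out), min_den, -1


def run_cycle(prev, forcing, h, eta, rho, guard, t0=0.0, use_numba=True):
    """Advance one delay cycle; raise :class:`SingularityError` on guard trip."""
    prev = np.ascontiguousarray(prev, dtype=np.float64)
    forcing = np.ascontiguousarray(forcing, dtype=np.float64)
    if use_numba and _cycle_jit is not None:
        out, min_den, bad = _cycle_jit(prev, forcing, h, eta, rho, guard)
    else:
        out, min_den, bad = _cycle_py(prev, forcing, h, eta, rho, guard)
    if bad >= 0:
        raise SingularityError(t0 + bad * h, min_den)
    return out
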