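"""Shared ODE integration backends.

Two modes are exposed through :class:`SolverSettings`:

``adaptive``
    SciPy's LSODA with tight tolerances.  The Ca2+ system alternates slow
    inter-spike drift with fast relaxation spikes -- mildly stiff -- and the
    stiffness-switching multistep method integrates it an order of magnitude
    faster than explicit embedded Runge-Kutta at the same tolerance.
``rk4``
    A fixed-step classical RK4 loop.  Slower, but bit-reproducible across
    runs and across right-hand sides that are floating-point identical -- the
    property the exact-plugin equivalence contract relies on.

Both backends sample the solution on a uniform output grid and enforce the
finite-state and negative-concentration guards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import NegativeConcentrationError, NonFiniteStateError, SolverError

__all__ = ["SolverSettings", "integrate"]

#: States may dip this far below zero before the run is declared invalid;
#: anything beyond it indicates a genuine escape from the positive orthant,
#: not round-off.
NEGATIVE_GUARD = -1e-9


@dataclass(frozen=True)
class SolverSettings:
    """Integration controls shared by all models.

    method   : "adaptive" (LSODA, tolerance-controlled) or "rk4" (fixed step).
    rtol/atol: adaptive-mode tolerances.
    rk4_step : fixed step size in seconds for rk4 mode; coerced to an exact
               divisor of the output interval so samples land on the grid.
    max_step : optional cap on the adaptive step (np.inf = uncapped).
    """

    method: str = "adaptive"
    rtol: float = 1e-8
    atol: float = 1e-10
    rk4_step: float = 1e-3
    max_step: float = np.inf

    def __post_init__(self):
        if self.method not in ("adaptive", "rk4"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.rtol <= 0 or self.atol <= 0 or self.rk4_step <= 0:
            raise ValueError("solver tolerances and step must be positive")


def output_grid(t_end: float, dt_out: float) -> np.ndarray:
    n = int(round(t_end / dt_out))
    if n < 1 or not np.isclose(n * dt_out, t_end, rtol=1e-9, atol=0):
        raise ValueError(f"t_end={t_end} must be a multiple of dt_out={dt_out}")
    return np.arange(n + 1) * dt_out


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    t_end: float,
    dt_out: float,
    settings: SolverSettings | None = None,
    breakpoints: Sequence[float] | None = None,
    nonneg_guard: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``dy/dt = rhs(t, y)`` from 0 to t_end, sampled every dt_out.

    ``breakpoints`` marks times where the right-hand side is discontinuous
    (held-noise interval edges); in adaptive mode the integration is restarted
    at each so the error control never steps across a jump.

    ``nonneg_guard`` enforces the negative-concentration guard; it is switched
    off for circuit node voltages, which are signed quantities.
    """
    if t_end <= 0 or dt_out <= 0:
        raise ValueError("t_end and dt_out must be positive")
    settings = settings or SolverSettings()
    times = output_grid(t_end, dt_out)
    y0 = np.asarray(y0, dtype=float)

    if settings.method == "rk4":
        out = _rk4(rhs, y0, times, dt_out, settings.rk4_step)
    elif breakpoints is None:
        out = _adaptive(rhs, y0, (0.0, t_end), times, settings)
    else:
        out = _adaptive_piecewise(rhs, y0, times, settings, breakpoints)

    _check_state(out, times, nonneg_guard)
    return times, out


def _adaptive(rhs, y0, span, t_eval, settings) -> np.ndarray:
    sol = solve_ivp(
        rhs,
        span,
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=settings.rtol,
        atol=settings.atol,
        max_step=settings.max_step,
        dense_output=False,
    )
    if not sol.success:
        raise SolverError(f"adaptive solver failed: {sol.message}", t=float(sol.t[-1]) if sol.t.size else span[0])
    return sol.y.T.copy()


def _adaptive_piecewise(rhs, y0, times, settings, breakpoints) -> np.ndarray:
    t_end = times[-1]
    edges = np.unique(np.concatenate([[0.0, t_end], np.asarray(breakpoints, float)]))
    edges = edges[(edges >= 0.0) & (edges <= t_end)]
    out = np.empty((times.size, y0.size))
    out[0] = y0
    y = y0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        # RK45 here: multistep startup overhead makes LSODA fragile on the
        # very short spans between noise-hold boundaries
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method="RK45",
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=settings.max_step,
            dense_output=True,
        )
        if not sol.success:
            raise SolverError(f"adaptive solver failed: {sol.message}", t=t0)
        # sample all output points in (t0, t1]
        mask = (times > t0) & (times <= t1)
        if mask.any():
            out[mask] = sol.sol(times[mask]).T
        y = sol.y[:, -1]
    return out


def _rk4(rhs, y0, times, dt_out, h_target) -> np.ndarray:
    # coerce the step to divide dt_out exactly so samples fall on the grid
    k = max(1, int(round(dt_out / h_target)))
    h = dt_out / k
    out = np.empty((times.size, y0.size))
    out[0] = y0
    y = y0.copy()
    half = h / 2.0
    sixth = h / 6.0
    for i in range(1, times.size):
        t_base = times[i - 1]
        for j in range(k):
            t = t_base + j * h
            k1 = rhs(t, y)
            k2 = rhs(t + half, y + half * k1)
            k3 = rhs(t + half, y + half * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i] = y
    return out


def _check_state(out: np.ndarray, times: np.ndarray, nonneg_guard: bool = True) -> None:
    bad = ~np.isfinite(out)
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise NonFiniteStateError(
            f"non-finite state at t={times[i]:g} s", t=float(times[i])
        )
    if not nonneg_guard:
        return
    neg = out < NEGATIVE_GUARD
    if neg.any():
        i = int(np.argwhere(neg.any(axis=1))[0, 0])
        raise NegativeConcentrationError(
            f"state fell below {NEGATIVE_GUARD:g} at t={times[i]:g} s "
            f"(min component {out[i].min():g})",
            t=float(times[i]),
        )
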