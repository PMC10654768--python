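"""Lavrentovich-Hemkin model of spontaneous astrocytic Ca2+ oscillations.

Three coupled ODEs track cytosolic Ca2+ (X), ER Ca2+ (Y) and cytosolic IP3
(Z), all in uM:

    dX/dt = V_in - k_out*X + V_CICR - V_SERCA + k_f*(Y - X)
    dY/dt = V_SERCA - V_CICR - k_f*(Y - X)
    dZ/dt = V_PLC - k_deg*Z

The nonlinear fluxes are Hill forms: the SERCA pump returns cytosolic Ca2+
to the ER, PLC-delta1 produces IP3 in response to cytosolic Ca2+, and CICR is
the IP3-receptor-mediated release from the ER, activated by low cytosolic
Ca2+ and inhibited at high Ca2+:

    V_SERCA = v_M2 * X^2 / (X^2 + k_2^2)
    V_PLC   = v_p  * X^2 / (X^2 + k_p^2)
    V_CICR  = 4*v_M3 * [k_CaA^n X^n / ((X^n + k_CaA^n)(X^n + k_CaI^n))]
                     * [Z^m / (Z^m + k_ip3^m)] * (Y - X)

With the default parameters the system has an attracting limit cycle:
spontaneous oscillations arise from the constant membrane influx V_in alone,
with no synaptic stimulus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._integrate import SolverSettings, integrate
from .exceptions import DomainError
from .trajectory import DEFAULT_INIT, SystemState, Trajectory

__all__ = [
    "LHParams",
    "hill",
    "v_serca",
    "v_plc",
    "v_cicr",
    "cicr_activation",
    "cicr_inhibition",
    "cicr_ip3_gate",
    "lh_rhs",
    "simulate",
]


@dataclass(frozen=True)
class LHParams:
    """Rate and affinity constants of the oscillation model.

    Defaults are the published reference set.  Fluxes in uM/s, first-order
    rates in 1/s, half-activation constants in uM; n and m are dimensionless
    Hill exponents and are used exactly as printed (2.02 and 2.2), not
    rounded to 2.
    """

    V_in: float = 0.05    # membrane Ca2+ influx, uM/s
    k_out: float = 0.5    # Ca2+ efflux rate to extracellular space, 1/s
    k_f: float = 0.5      # ER leak rate, 1/s
    v_M2: float = 15.0    # max SERCA flux, uM/s
    k_2: float = 0.1      # SERCA half-activation, uM
    v_p: float = 0.05     # max IP3 production rate, uM/s
    k_p: float = 0.3      # PLC half-activation, uM
    k_deg: float = 0.08   # IP3 degradation rate, 1/s
    v_M3: float = 40.0    # max CICR rate, 1/s
    k_CaA: float = 0.15   # IP3R activating Ca2+ affinity, uM
    k_CaI: float = 0.15   # IP3R inhibiting Ca2+ affinity, uM
    k_ip3: float = 0.1    # IP3R IP3 half-activation, uM
    n: float = 2.02       # Ca2+ Hill exponent
    m: float = 2.2        # IP3 Hill exponent

    def __post_init__(self):
        # maximal fluxes/rates may be zero (switching a pathway off entirely,
        # e.g. to recover the linear leak subsystem); rate constants,
        # affinities and exponents must be strictly positive
        nonneg = {"V_in", "v_M2", "v_M3", "v_p"}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lo_ok = v >= 0 if f.name in nonneg else v > 0
            if not np.isfinite(v) or not lo_ok:
                raise DomainError(f"parameter {f.name} out of range: {v!r}")

    def replace(self, **changes) -> "LHParams":
        return dataclasses.replace(self, **changes)


def hill(x: float, k: float, p: float) -> float:
    """Hill saturation x^p / (x^p + k^p): 0 at x=0, exactly 1/2 at x=k."""
    if k <= 0 or p <= 0:
        raise DomainError(f"hill requires k > 0 and p > 0, got k={k}, p={p}")
    if isinstance(x, (float, int)):  # scalar fast path (solver hot loop)
        if x < 0:
            raise DomainError("hill requires x >= 0")
        xp = x**p
        return xp / (xp + k**p)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("hill requires x >= 0")
    xp = x**p
    return xp / (xp + k**p)


def v_serca(X: float, params: LHParams) -> float:
    """SERCA pump flux cytosol -> ER, uM/s; saturates at v_M2."""
    return params.v_M2 * hill(X, params.k_2, 2.0)


def v_plc(X: float, params: LHParams) -> float:
    """PLC-delta1 IP3 production, uM/s; saturates at v_p."""
    return params.v_p * hill(X, params.k_p, 2.0)


def cicr_activation(X: float, params: LHParams):
    """F_X1 = k_CaA^n / (X^n + k_CaA^n): Ca2+ activation, decreasing in X."""
    if isinstance(X, (float, int)):
        if X < 0:
            raise DomainError("cicr_activation requires X >= 0")
        kn = params.k_CaA**params.n
        return kn / (X**params.n + kn)
    if np.any(np.asarray(X) < 0):
        raise DomainError("cicr_activation requires X >= 0")
    kn = params.k_CaA**params.n
    return kn / (np.asarray(X, float) ** params.n + kn)


def cicr_inhibition(X: float, params: LHParams):
    """F_X2 = X^n / (X^n + k_CaI^n): relief of inhibition, increasing in X."""
    return hill(X, params.k_CaI, params.n)


def cicr_ip3_gate(Z: float, params: LHParams):
    """F_Z = Z^m / (Z^m + k_ip3^m): IP3 gating of the IP3R channel."""
    return hill(Z, params.k_ip3, params.m)


def v_cicr(state, params: LHParams) -> float:
    """IP3R-mediated Ca2+ flux ER -> cytosol, uM/s.

    Zero when X = 0 (no activation), Z = 0 (channel closed) or Y = X (no
    gradient); its sign is the sign of Y - X.
    """
    X, Y, Z = _unpack(state)
    return (4.0 * params.v_M3) * (
        cicr_activation(X, params)
        * cicr_inhibition(X, params)
        * cicr_ip3_gate(Z, params)
        * (Y - X)
    )


def lh_rhs(state, params: LHParams) -> np.ndarray:
    """Time derivatives (dX/dt, dY/dt, dZ/dt) in uM/s.

    The CICR, SERCA and leak terms cancel between the X and Y equations, so
    dX/dt + dY/dt == V_in - k_out*X holds identically at every state.
    """
    X, Y, Z = _unpack(state)
    vs = v_serca(X, params)
    vc = v_cicr((X, Y, Z), params)
    leak = params.k_f * (Y - X)
    dX = params.V_in - params.k_out * X + vc - vs + leak
    dY = vs - vc - leak
    dZ = v_plc(X, params) - params.k_deg * Z
    return np.array([dX, dY, dZ])


def simulate(
    params: LHParams | None = None,
    init: SystemState = DEFAULT_INIT,
    t_end: float = 2000.0,
    dt_out: float = 0.5,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the model and sample it on a uniform grid.

    Deterministic for fixed settings; the ``rk4`` solver mode is additionally
    bit-reproducible.  Raises loudly (never clamps) if a state goes non-finite
    or more than 1e-9 uM negative.
    """
    params = params or LHParams()
    settings = settings or SolverSettings()

    def rhs(t, y):
        return lh_rhs(y, params)

    times, data = integrate(rhs, init.as_array(), t_end, dt_out, settings)
    return Trajectory(
        times=times,
        data=data,
        columns=("X", "Y", "Z"),
        meta={
            "model": "lh",
            "params": dataclasses.asdict(params),
            "init": dataclasses.asdict(init),
            "seed": "none",
            "solver": dataclasses.asdict(settings),
            "t_end": t_end,
            "dt_out": dt_out,
        },
    )


def _unpack(state):
    if isinstance(state, SystemState):
        return state.X, state.Y, state.Z
    X, Y, Z = state
    if min(X, Y, Z) < 0 or not all(map(np.isfinite, (X, Y, Z))):
        # tiny negative undershoot from solver round-off is tolerated by the
        # integrator guard, but the flux formulas themselves need X, Z >= 0
        if min(X, Z) < -1e-9 or not all(map(np.isfinite, (X, Y, Z))):
            raise DomainError(f"invalid state {(X, Y, Z)}")
        X, Z = max(X, 0.0), max(Z, 0.0)
    return X, Y, Z
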