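"""Behavioral model of the analog neuromorphic oscillator circuit.

The ODE model maps onto three capacitor nodes by Kirchhoff's current law:
concentrations become node voltages (1 V == 1 uM), fluxes become currents
(1 A == 1 uM/s), the first-order rates k_out, k_f, k_deg become conductances,
and the membrane influx V_in becomes a source current I_in:

    c_X dV_X/dt = I_in - I_X + I_CICR - I_SERCA + I_YX
    c_Y dV_Y/dt = I_SERCA - I_CICR - I_YX
    c_Z dV_Z/dt = I_PLC - I_Z

with I_X = g_out*V_X, I_YX = g_f*(V_Y - V_X), I_Z = g_deg*V_Z and unit
capacitances.  The Hill nonlinearities are realized by transistor
differential pairs, whose large-signal transfer is a tanh; each sigmoidal
factor is replaced by a fitted tanh "module":

    I_SERCA ~ tanh(5 X - 0.065)
    I_PLC   ~ tanh(1.78 X - 0.045)
    F_X1    ~ tanh(0.22 - 5.5 X) + 1.08
    F_X2    ~ 4 tanh(3.9 X - 0.07)
    F_Z     ~ 5 tanh(2.5 Z - 0.03)
    I_CICR  = 4 v_M3 * F_X1 * F_X2 * F_Z * I_YX / k_f

The printed tanh coefficients fix each module's shape but not its absolute
output scale -- in hardware that scale lives in the tail currents and the
output resistor, which are free design quantities.  This module therefore
exposes one multiplicative gain per nonlinear block (A_serca, A_plc, A_cicr):
``calibrate_gains`` fits them to the Hill targets by least squares, and the
strict "as printed" configuration (all gains 1) is kept for fidelity checks.

The modules are pluggable callables, so the exact Hill forms can be wired in
place of the tanh approximations ("exact-plugin" mode), making the circuit
right-hand side agree with the reference model to the last bit -- a
machine-precision oracle for all the KCL wiring.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._integrate import SolverSettings, integrate
from .exceptions import DomainError
from .lh_model import (
    LHParams,
    cicr_activation,
    cicr_inhibition,
    cicr_ip3_gate,
    v_plc,
    v_serca,
)
from .trajectory import DEFAULT_INIT, SystemState, Trajectory

__all__ = [
    "DiffPairParams",
    "TanhModule",
    "CircuitParams",
    "diffpair_current",
    "eval_tanh_module",
    "i_cicr_approx",
    "circuit_rhs",
    "calibrate_gains",
    "simulate_circuit",
]


@dataclass(frozen=True)
class DiffPairParams:
    """Large-signal bipolar differential pair.

    alpha : common-base current gain (0 < alpha <= 1); 0.99 is a typical BJT
            value.
    I_EE  : tail current source.
    V_T   : thermal voltage; 0.02585 V at 300 K.
    """

    alpha: float = 0.99
    I_EE: float = 1.0
    V_T: float = 0.02585

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise DomainError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.V_T <= 0:
            raise DomainError(f"V_T must be > 0, got {self.V_T}")
        if self.I_EE < 0:
            raise DomainError(f"I_EE must be >= 0, got {self.I_EE}")


def diffpair_current(V_b1: float, V_b2: float, p: DiffPairParams) -> float:
    """Differential collector current Ic1 - Ic2 = alpha*I_EE*tanh(dV/2V_T).

    Odd in V_b1 - V_b2 and bounded by alpha*I_EE in magnitude.
    """
    if not (math.isfinite(V_b1) and math.isfinite(V_b2)):
        raise DomainError("diffpair_current requires finite base voltages")
    return p.alpha * p.I_EE * math.tanh((V_b1 - V_b2) / (2.0 * p.V_T))


@dataclass(frozen=True)
class TanhModule:
    """One differential-pair block: gain*tanh(+-slope*u - offset) + gain*additive.

    ``negate_argument`` flips the sign of the slope*u term (the pair's output
    taken with opposite polarity); ``additive`` is a constant current source
    summed at the output, expressed in units of the gain.
    """

    slope: float
    offset: float
    gain: float = 1.0
    additive: float = 0.0
    negate_argument: bool = False

    def __post_init__(self):
        if self.slope == 0:
            raise DomainError("TanhModule slope must be nonzero")

    def __call__(self, u):
        s = -self.slope * u if self.negate_argument else self.slope * u
        if isinstance(s, (float, int)):  # scalar fast path (solver hot loop)
            return self.gain * (math.tanh(s - self.offset) + self.additive)
        return self.gain * (np.tanh(s - self.offset) + self.additive)

    @property
    def bound(self) -> float:
        """Hard bound on |output|: |gain| * (1 + |additive|)."""
        return abs(self.gain) * (1.0 + abs(self.additive))


def eval_tanh_module(m: TanhModule, u: float) -> float:
    """Evaluate a tanh module at input u (uM-equivalent volts)."""
    return m(u)


# printed differential-pair fits, shape coefficients as designed
def _printed_modules() -> dict[str, TanhModule]:
    return {
        "serca": TanhModule(slope=5.0, offset=0.065),
        "plc": TanhModule(slope=1.78, offset=0.045),
        "fx1": TanhModule(slope=5.5, offset=-0.22, additive=1.08, negate_argument=True),
        "fx2": TanhModule(slope=3.9, offset=0.07, gain=4.0),
        "fz": TanhModule(slope=2.5, offset=0.03, gain=5.0),
    }


@dataclass(frozen=True)
class CircuitParams:
    """Full behavioral parameter set of the oscillator circuit.

    The five nonlinear blocks are arbitrary callables; by default they are
    the printed tanh modules.  ``module_gains`` = (A_serca, A_plc, A_cicr)
    are the per-block output scales (all 1 in as-printed mode).
    """

    serca: Callable = field(default_factory=lambda: _printed_modules()["serca"])
    plc: Callable = field(default_factory=lambda: _printed_modules()["plc"])
    fx1: Callable = field(default_factory=lambda: _printed_modules()["fx1"])
    fx2: Callable = field(default_factory=lambda: _printed_modules()["fx2"])
    fz: Callable = field(default_factory=lambda: _printed_modules()["fz"])
    cicr_prefactor: float = 4.0 * 40.0  # 4*v_M3, the CICR output scale
    I_in: float = 0.05   # source current == V_in, uM/s-equivalent
    g_out: float = 0.5   # conductance == k_out
    g_f: float = 0.5     # conductance == k_f
    g_deg: float = 0.08  # conductance == k_deg
    c_X: float = 1.0
    c_Y: float = 1.0
    c_Z: float = 1.0
    module_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if min(self.c_X, self.c_Y, self.c_Z) <= 0:
            raise DomainError("capacitances must be positive")
        if min(self.g_out, self.g_f, self.g_deg) <= 0:
            raise DomainError("conductances must be positive")

    def replace(self, **changes) -> "CircuitParams":
        return dataclasses.replace(self, **changes)

    @classmethod
    def printed(cls, lh: LHParams | None = None) -> "CircuitParams":
        """As-printed tanh modules, linear elements mapped from the ODE set."""
        lh = lh or LHParams()
        return cls(
            cicr_prefactor=4.0 * lh.v_M3,
            I_in=lh.V_in,
            g_out=lh.k_out,
            g_f=lh.k_f,
            g_deg=lh.k_deg,
            **_printed_modules(),
        )

    @classmethod
    def exact_plugin(cls, lh: LHParams | None = None) -> "CircuitParams":
        """Exact Hill nonlinearities wired into the KCL structure.

        With this configuration ``circuit_rhs`` reproduces the reference
        right-hand side bit for bit.
        """
        lh = lh or LHParams()
        return cls(
            serca=lambda X: v_serca(X, lh),
            plc=lambda X: v_plc(X, lh),
            fx1=lambda X: cicr_activation(X, lh),
            fx2=lambda X: cicr_inhibition(X, lh),
            fz=lambda Z: cicr_ip3_gate(Z, lh),
            cicr_prefactor=4.0 * lh.v_M3,
            I_in=lh.V_in,
            g_out=lh.k_out,
            g_f=lh.k_f,
            g_deg=lh.k_deg,
        )

    @classmethod
    def calibrated(
        cls,
        lh: LHParams | None = None,
        X_range: tuple[float, float] = (0.0, 1.5),
        Z_range: tuple[float, float] = (0.0, 1.0),
        n_grid: int = 301,
    ) -> "CircuitParams":
        """Printed modules with least-squares gains against the Hill targets."""
        lh = lh or LHParams()
        cp = cls.printed(lh)
        return cp.replace(module_gains=calibrate_gains(cp, lh, X_range, Z_range, n_grid))


def _ls_gain(target: np.ndarray, model: np.ndarray) -> float:
    """Closed-form least-squares scale: argmin_A sum (target - A*model)^2."""
    denom = float(np.dot(model, model))
    if denom == 0.0:
        return 0.0
    return float(np.dot(target, model) / denom)


def calibrate_gains(
    cp: CircuitParams,
    lh: LHParams | None = None,
    X_range: tuple[float, float] = (0.0, 1.5),
    Z_range: tuple[float, float] = (0.0, 1.0),
    n_grid: int = 301,
) -> tuple[float, float, float]:
    """Fit (A_serca, A_plc, A_cicr) to the Hill targets on uniform grids.

    Each gain minimizes the mean squared difference between the scaled block
    output and its Hill counterpart; for the CICR product the (Y - X) driving
    factor is common to both forms and cancels, so the fit runs over the
    (X, Z) grid of the remaining gate product.  Deterministic.
    """
    lh = lh or LHParams()
    if not (X_range[1] > X_range[0]) or not (Z_range[1] > Z_range[0]):
        raise DomainError(f"degenerate calibration range: X={X_range}, Z={Z_range}")
    Xg = np.linspace(X_range[0], X_range[1], n_grid)
    Zg = np.linspace(Z_range[0], Z_range[1], n_grid)

    a_serca = _ls_gain(v_serca(Xg, lh), cp.serca(Xg))
    a_plc = _ls_gain(v_plc(Xg, lh), cp.plc(Xg))

    XX, ZZ = np.meshgrid(Xg, Zg, indexing="ij")
    target = (4.0 * lh.v_M3) * (
        cicr_activation(XX, lh) * cicr_inhibition(XX, lh) * cicr_ip3_gate(ZZ, lh)
    )
    model = cp.cicr_prefactor * (cp.fx1(XX) * cp.fx2(XX) * cp.fz(ZZ))
    a_cicr = _ls_gain(target.ravel(), model.ravel())
    return (a_serca, a_plc, a_cicr)


def _as_voltages(state):
    """Unpack a state as signed node voltages (finiteness is the only domain).

    Unlike concentrations, circuit voltages may legitimately dip slightly
    negative: the printed tanh fits are signed near the origin (e.g. the PLC
    module output is negative for X < 0.045/1.78 uM), which is a real feature
    of the approximation, not an error.
    """
    if isinstance(state, SystemState):
        return state.X, state.Y, state.Z
    X, Y, Z = state
    if not (math.isfinite(X) and math.isfinite(Y) and math.isfinite(Z)):
        raise DomainError(f"non-finite node voltages {(X, Y, Z)}")
    return X, Y, Z


def i_cicr_approx(state, cp: CircuitParams) -> float:
    """CICR output current A_cicr * 4v_M3 * F_X1 F_X2 F_Z * (V_Y - V_X).

    The driving term I_YX/k_f reduces to the voltage difference V_Y - V_X,
    which is how it is evaluated here.
    """
    X, Y, Z = _as_voltages(state)
    return (cp.module_gains[2] * cp.cicr_prefactor) * (
        cp.fx1(X) * cp.fx2(X) * cp.fz(Z) * (Y - X)
    )


def circuit_rhs(state, cp: CircuitParams) -> np.ndarray:
    """Node-voltage derivatives (dV_X/dt, dV_Y/dt, dV_Z/dt).

    The SERCA, CICR and leak currents cancel between the V_X and V_Y nodes,
    so c_X dV_X/dt + c_Y dV_Y/dt == I_in - g_out*V_X identically (KCL).
    """
    X, Y, Z = _as_voltages(state)
    a_serca, a_plc, _ = cp.module_gains
    i_serca = a_serca * cp.serca(X)
    i_cicr = i_cicr_approx((X, Y, Z), cp)
    i_yx = cp.g_f * (Y - X)
    dX = (cp.I_in - cp.g_out * X + i_cicr - i_serca + i_yx) / cp.c_X
    dY = (i_serca - i_cicr - i_yx) / cp.c_Y
    dZ = (a_plc * cp.plc(X) - cp.g_deg * Z) / cp.c_Z
    return np.array([dX, dY, dZ])


def simulate_circuit(
    cp: CircuitParams | None = None,
    init: SystemState = DEFAULT_INIT,
    t_end: float = 2000.0,
    dt_out: float = 0.5,
    settings: SolverSettings | None = None,
    noise_spec=None,
) -> Trajectory:
    """Integrate the circuit model; optionally with held input noise.

    With a noise spec (fraction > 0) a clean run is performed first to learn
    the running maxima of the module input signals; seeded piecewise-constant
    perturbations bounded by fraction * max are then injected at the module
    inputs and the noisy run is integrated restarting at each hold boundary.
    Fully reproducible for a fixed seed; a spec with fraction 0 (or none)
    takes the clean path and reproduces the clean run bit for bit.
    """
    cp = cp or CircuitParams.calibrated()
    settings = settings or SolverSettings()

    meta = {
        "model": "circuit",
        "params": _params_meta(cp),
        "init": dataclasses.asdict(init),
        "seed": "none",
        "solver": dataclasses.asdict(settings),
        "t_end": t_end,
        "dt_out": dt_out,
    }

    def clean_rhs(t, y):
        return circuit_rhs(y, cp)

    if noise_spec is None or noise_spec.fraction == 0.0:
        times, data = integrate(
            clean_rhs, init.as_array(), t_end, dt_out, settings, nonneg_guard=False
        )
        return Trajectory(times, data, ("X", "Y", "Z"), meta)

    from .noise import build_module_noise  # local import: noise depends on analysis types

    clean_times, clean_data = integrate(
        clean_rhs, init.as_array(), t_end, dt_out, settings, nonneg_guard=False
    )
    eta = build_module_noise(noise_spec, t_end, clean_times, clean_data, i_in=cp.I_in)
    rhs = _noisy_rhs(cp, eta)
    breaks = np.arange(0.0, t_end, noise_spec.hold_interval)[1:]
    times, data = integrate(
        rhs, init.as_array(), t_end, dt_out, settings, breakpoints=breaks, nonneg_guard=False
    )
    meta = dict(meta)
    meta["noise"] = dataclasses.asdict(noise_spec)
    meta["seed"] = noise_spec.seed
    return Trajectory(times, data, ("X", "Y", "Z"), meta)


def _noisy_rhs(cp: CircuitParams, eta: dict):
    """Right-hand side with held perturbations added at the module inputs."""
    zero = lambda t: 0.0
    e_iin = eta.get("iin", zero)
    e_serca = eta.get("serca", zero)
    e_plc = eta.get("plc", zero)
    e_cicr_x = eta.get("cicr_x", zero)
    e_cicr_z = eta.get("cicr_z", zero)
    a_serca, a_plc, a_cicr = cp.module_gains

    def rhs(t, y):
        X, Y, Z = _as_voltages(y)
        i_serca = a_serca * cp.serca(X + e_serca(t))
        xc = X + e_cicr_x(t)
        i_cicr = (a_cicr * cp.cicr_prefactor) * (
            cp.fx1(xc) * cp.fx2(xc) * cp.fz(Z + e_cicr_z(t)) * (Y - X)
        )
        i_yx = cp.g_f * (Y - X)
        dX = (cp.I_in + e_iin(t) - cp.g_out * X + i_cicr - i_serca + i_yx) / cp.c_X
        dY = (i_serca - i_cicr - i_yx) / cp.c_Y
        dZ = (a_plc * cp.plc(X + e_plc(t)) - cp.g_deg * Z) / cp.c_Z
        return np.array([dX, dY, dZ])

    return rhs


def _params_meta(cp: CircuitParams) -> dict:
    out = {}
    for f in dataclasses.fields(cp):
        v = getattr(cp, f.name)
        if isinstance(v, TanhModule):
            out[f.name] = dataclasses.asdict(v)
        elif callable(v):
            out[f.name] = getattr(v, "__name__", "callable")
        else:
            out[f.name] = v
    return out
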