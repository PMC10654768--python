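"""Gliotransmitter release driven by the Ca2+ oscillation.

Astrocytic Ca2+ spikes trigger the release of glutamate (depolarizing the
postsynaptic neuron) and ATP (hyperpolarizing it via adenosine) into the
tripartite synapse.  Release is modeled by two first-order gating variables
G_m (glutamate) and G_a (ATP), each driven by cytosolic Ca2+ X(t) through a
steep tanh activation (Postnov form):

    tau dG/dt = [1 + tanh(S (X - h))] * (1 - G) - G / d

With the default steepness S = 100 /uM the activation is effectively a step
at the threshold h = 0.5 uM: each Ca2+ spike crossing h produces one release
pulse.  The sign structure makes [0, 1] forward-invariant for G, and under
sustained suprathreshold drive G relaxes to the fixed point 2d/(2d+1).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._integrate import SolverSettings
from .exceptions import DomainError, SolverError
from .trajectory import Trajectory

__all__ = ["GlioParams", "GlioState", "glio_rhs", "activation", "simulate_glio"]


@dataclass(frozen=True)
class GlioParams:
    """Release-model constants (published reference set).

    tau_* scale time (the equations are used literally, dG/dt = RHS/tau),
    S_* are activation steepnesses in 1/uM, h_* activation thresholds in uM,
    d_* control the deactivation rate (dimensionless).
    """

    tau_Gm: float = 5.0
    S_Gm: float = 100.0
    h_Gm: float = 0.5
    d_Gm: float = 3.0
    tau_Ga: float = 3.0
    S_Ga: float = 100.0
    h_Ga: float = 0.5
    d_Ga: float = 3.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"parameter {f.name} must be finite and > 0, got {v!r}")

    def fixed_point(self, which: str = "Gm") -> float:
        """Saturated-drive fixed point 2d/(2d+1) of the release variable."""
        d = self.d_Gm if which == "Gm" else self.d_Ga
        return 2.0 * d / (2.0 * d + 1.0)


@dataclass(frozen=True)
class GlioState:
    """Release variables, dimensionless fractions in [0, 1]."""

    G_m: float = 0.0
    G_a: float = 0.0

    def __post_init__(self):
        for name in ("G_m", "G_a"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must start in [0, 1], got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.G_m, self.G_a], dtype=float)


def activation(X: float, S: float, h: float):
    """Gating drive 1 + tanh(S*(X - h)), in [0, 2], equal to 1 at X = h."""
    return 1.0 + np.tanh(S * (np.asarray(X, float) - h))


def glio_rhs(g, X: float, p: GlioParams) -> np.ndarray:
    """(dG_m/dt, dG_a/dt) at cytosolic Ca2+ level X (uM)."""
    if isinstance(g, GlioState):
        gm, ga = g.G_m, g.G_a
    else:
        gm, ga = g
    if not all(map(math.isfinite, (gm, ga, X))):
        raise DomainError(f"non-finite gliotransmitter input: G=({gm}, {ga}), X={X}")
    dgm = (activation(X, p.S_Gm, p.h_Gm) * (1.0 - gm) - gm / p.d_Gm) / p.tau_Gm
    dga = (activation(X, p.S_Ga, p.h_Ga) * (1.0 - ga) - ga / p.d_Ga) / p.tau_Ga
    return np.array([dgm, dga])


def simulate_glio(
    ca_trace: Trajectory,
    p: GlioParams | None = None,
    init: GlioState = GlioState(0.0, 0.0),
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the release equations along a given Ca2+ trajectory.

    X(t) is held piecewise-linear between the trace's samples.  Returns the
    input trajectory extended with ``Gm`` and ``Ga`` columns on the same
    time grid.
    """
    if len(ca_trace) == 0:
        raise DomainError("empty Ca2+ trace")
    p = p or GlioParams()
    settings = settings or SolverSettings()
    t = ca_trace.times
    X = ca_trace.column("X")

    def rhs(s, g):
        return glio_rhs(g, float(np.interp(s, t, X)), p)

    if len(ca_trace) == 1:
        out = init.as_array()[None, :]
    else:
        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            init.as_array(),
            method="RK45",
            t_eval=t,
            rtol=settings.rtol,
            atol=settings.atol,
        )
        if not sol.success:
            raise SolverError(f"gliotransmitter integration failed: {sol.message}")
        out = sol.y.T

    traj = ca_trace.with_columns(("Gm", "Ga"), out)
    traj.meta["glio_params"] = dataclasses.asdict(p)
    traj.meta["glio_init"] = dataclasses.asdict(init)
    return traj
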