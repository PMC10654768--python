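"""Experiment layer: period estimation, input sweeps, trajectory comparison.

All summary statistics discard an initial transient (30% of the run by
default) so they describe the attracting limit cycle, not the approach to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from ._integrate import SolverSettings
from .circuit import CircuitParams, simulate_circuit
from .exceptions import NonOscillatoryError, SweepError, TooFewPeaksError
from .lh_model import LHParams, simulate
from .noise import NoiseSpec, add_noise  # re-exported: part of the experiment surface
from .trajectory import DEFAULT_INIT, SystemState, Trajectory

__all__ = [
    "OscillationSummary",
    "NoiseSpec",
    "add_noise",
    "estimate_period",
    "sweep_vin",
    "compare_trajectories",
    "TrajectoryComparison",
    "TRANSIENT_FRACTION",
]

#: fraction of every run discarded before any summary statistic
TRANSIENT_FRACTION = 0.3

#: peaks must exceed mid-range + this fraction of the half-range
PEAK_PROMINENCE_FRACTION = 0.25


@dataclass(frozen=True)
class OscillationSummary:
    """Post-transient limit-cycle statistics of one variable."""

    period: float          # mean inter-peak interval, s
    period_sd: float       # SD of inter-peak intervals, s
    n_peaks: int
    peak_mean: float       # mean peak level, uM
    trough_mean: float     # mean trough level, uM
    transient_discarded: float  # leading time discarded, s

    def __post_init__(self):
        if self.n_peaks < 3 or self.period <= 0 or self.period_sd < 0:
            raise ValueError("summary requires >= 3 peaks and a positive period")


def _post_transient(traj: Trajectory, variable: str, transient_fraction: float):
    t, x = traj.times, traj.column(variable)
    t_cut = t[0] + transient_fraction * (t[-1] - t[0])
    keep = t >= t_cut
    return t[keep], x[keep], t_cut - t[0]


def estimate_period(
    traj: Trajectory,
    variable: str = "X",
    transient_fraction: float = TRANSIENT_FRACTION,
) -> OscillationSummary:
    """Estimate the oscillation period of one trajectory variable.

    After discarding the transient, local maxima above
    mid-range + 0.25 * half-range qualify as peaks (plateau ties resolved to
    the earliest sample); the period is the mean inter-peak interval.

    Raises TooFewPeaksError when fewer than three peaks qualify -- either the
    signal is not oscillatory or the run is too short to tell.
    """
    t, x, discarded = _post_transient(traj, variable, transient_fraction)
    if t.size < 3:
        raise TooFewPeaksError("trajectory too short after transient discard")
    lo, hi = float(np.min(x)), float(np.max(x))
    half_range = (hi - lo) / 2.0
    height = (lo + hi) / 2.0 + PEAK_PROMINENCE_FRACTION * half_range
    # find_peaks reports the left edge of plateaus -> earliest-sample ties
    peaks, _ = find_peaks(x, height=height) if hi > lo else (np.array([], int), None)
    if peaks.size < 3:
        raise TooFewPeaksError(
            f"only {peaks.size} qualifying peaks in {variable!r}; need >= 3"
        )
    intervals = np.diff(t[peaks])
    troughs, _ = find_peaks(-x, height=-((lo + hi) / 2.0 - PEAK_PROMINENCE_FRACTION * half_range))
    trough_mean = float(np.mean(x[troughs])) if troughs.size else lo
    return OscillationSummary(
        period=float(np.mean(intervals)),
        period_sd=float(np.std(intervals)),
        n_peaks=int(peaks.size),
        peak_mean=float(np.mean(x[peaks])),
        trough_mean=trough_mean,
        transient_discarded=float(discarded),
    )


def sweep_vin(
    values,
    model: str = "lh",
    lh_params: LHParams | None = None,
    init: SystemState = DEFAULT_INIT,
    t_end: float = 2000.0,
    dt_out: float = 0.5,
    settings: SolverSettings | None = None,
    variable: str = "X",
) -> list[tuple[float, OscillationSummary]]:
    """Oscillation summary for each membrane-influx value, in input order.

    ``model`` selects the reference ODE system ("lh") or the calibrated
    circuit analogue ("circuit"); all runs share the same solver settings.
    Per-run failures are re-raised as SweepError tagged with the offending
    influx value.
    """
    values = list(values)
    if not values:
        raise SweepError("empty V_in sweep", value=float("nan"))
    if model not in ("lh", "circuit"):
        raise ValueError(f"unknown model {model!r}")
    lh_params = lh_params or LHParams()
    out = []
    for v in values:
        try:
            p = lh_params.replace(V_in=v)
            if model == "lh":
                traj = simulate(p, init=init, t_end=t_end, dt_out=dt_out, settings=settings)
            else:
                cp = CircuitParams.calibrated(p)
                traj = simulate_circuit(cp, init=init, t_end=t_end, dt_out=dt_out, settings=settings)
            out.append((v, estimate_period(traj, variable)))
        except Exception as e:  # tag the failing sweep member
            raise SweepError(f"V_in={v}: {e}", value=v) from e
    return out


def module_noise_response(
    cp: CircuitParams,
    traj: Trajectory,
    spec: NoiseSpec,
) -> dict:
    """Open-loop module robustness: clean vs noisy module outputs.

    Drives each nonlinear block with the trajectory's clean input waveform
    plus held bounded noise (no feedback), and reports the RMS output
    deviation relative to the clean output range, per module.
    """
    from .noise import build_module_noise

    t = traj.times
    data = traj.data
    eta = build_module_noise(
        spec.__class__(
            fraction=spec.fraction,
            hold_interval=spec.hold_interval,
            seed=spec.seed,
            targets=("serca", "plc", "cicr"),
        ),
        float(t[-1]),
        t,
        data,
        i_in=cp.I_in,
    )
    X, Y, Z = data[:, 0], data[:, 1], data[:, 2]
    e = {k: np.array([v(ti) for ti in t]) for k, v in eta.items()}
    a_serca, a_plc, a_cicr = cp.module_gains

    def rel_rms(clean, noisy):
        span = float(clean.max() - clean.min()) or 1.0
        return float(np.sqrt(np.mean((noisy - clean) ** 2)) / span)

    serca_c = a_serca * cp.serca(X)
    plc_c = a_plc * cp.plc(X)
    cicr_c = (a_cicr * cp.cicr_prefactor) * (cp.fx1(X) * cp.fx2(X) * cp.fz(Z) * (Y - X))
    xc = X + e["cicr_x"]
    cicr_n = (a_cicr * cp.cicr_prefactor) * (
        cp.fx1(xc) * cp.fx2(xc) * cp.fz(Z + e["cicr_z"]) * (Y - X)
    )
    return {
        "serca": rel_rms(serca_c, a_serca * cp.serca(X + e["serca"])),
        "plc": rel_rms(plc_c, a_plc * cp.plc(X + e["plc"])),
        "cicr": rel_rms(cicr_c, cicr_n),
    }


@dataclass(frozen=True)
class TrajectoryComparison:
    """Summary of how closely two oscillatory trajectories agree."""

    period_ratio: float              # period(a) / period(b)
    amplitude_ratios: dict           # per-variable peak level a / b
    portrait_distance: float         # normalized nearest-neighbor orbit distance
    summary_a: OscillationSummary
    summary_b: OscillationSummary


def portrait_distance(
    orbit_a: np.ndarray, orbit_b: np.ndarray
) -> float:
    """Mean nearest-neighbor distance between two orbits, symmetrized.

    Each coordinate is normalized by the combined range of the two orbits,
    so the distance is dimensionless and comparable across variables.
    Time-parametrization-free: a time-shifted copy of a closed orbit is at
    distance ~0 from the original.
    """
    lo = np.minimum(orbit_a.min(axis=0), orbit_b.min(axis=0))
    hi = np.maximum(orbit_a.max(axis=0), orbit_b.max(axis=0))
    scale = np.where(hi > lo, hi - lo, 1.0)
    a = (orbit_a - lo) / scale
    b = (orbit_b - lo) / scale
    d_ab = cKDTree(b).query(a)[0].mean()
    d_ba = cKDTree(a).query(b)[0].mean()
    return float(0.5 * (d_ab + d_ba))


def compare_trajectories(
    a: Trajectory,
    b: Trajectory,
    variables: tuple[str, ...] = ("X", "Y", "Z"),
    transient_fraction: float = TRANSIENT_FRACTION,
) -> TrajectoryComparison:
    """Compare two oscillatory trajectories on period, amplitude and orbit.

    Both inputs must oscillate (>= 3 peaks post-transient in the first
    variable); otherwise NonOscillatoryError is raised.
    """
    try:
        sa = estimate_period(a, variables[0], transient_fraction)
        sb = estimate_period(b, variables[0], transient_fraction)
    except TooFewPeaksError as e:
        raise NonOscillatoryError(f"both trajectories must oscillate: {e}") from e

    amp = {}
    orbits = []
    for traj in (a, b):
        cols = []
        for v in variables:
            tv, xv, _ = _post_transient(traj, v, transient_fraction)
            cols.append(xv)
        orbits.append(np.column_stack(cols))
    for j, v in enumerate(variables):
        amp[v] = float(orbits[0][:, j].max() / orbits[1][:, j].max())

    return TrajectoryComparison(
        period_ratio=sa.period / sb.period,
        amplitude_ratios=amp,
        portrait_distance=portrait_distance(orbits[0], orbits[1]),
        summary_a=sa,
        summary_b=sb,
    )
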