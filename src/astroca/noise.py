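"""Seeded bounded input noise for robustness experiments.

The perturbation is piecewise constant: a fresh uniform draw is held over
each ``hold_interval`` so the perturbed right-hand side stays well defined
for the ODE solver.  Each draw is uniform on [-f*M(t), +f*M(t)], where f is
the noise fraction and M(t) is the running maximum magnitude of the *clean*
target signal up to time t -- so the bound |noise| <= f * max|signal| holds
over every horizon by construction.  Everything is driven by a single seed
through independent child streams, one per injection target, so runs are
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = ["NoiseSpec", "HeldUniformNoise", "add_noise", "build_module_noise"]

#: valid injection points: "iin" perturbs the source current (the closed
#: loop's input signal); "serca"/"plc"/"cicr" perturb the nonlinear module
#: inputs ("cicr" covers both the X input of the activation/inhibition blocks
#: and the Z input of the IP3 gate).  Module-input injection is meant for
#: open-loop module characterization: inside the closed loop it can push the
#: state past the F_X2 sign change, where the rail-free behavioral model has
#: no saturation to stop the escape.
VALID_TARGETS = ("iin", "serca", "plc", "cicr")


@dataclass(frozen=True)
class NoiseSpec:
    """Bounded-noise experiment description.

    fraction      : bound as a fraction of the clean signal's running max
                    (0 <= fraction < 1); 0 disables noise entirely.
    hold_interval : seconds each draw is held for.
    seed          : integer seed; same seed -> identical sample paths.
    targets       : which inputs are perturbed (see VALID_TARGETS); the
                    default perturbs the oscillator's input signal.
    """

    fraction: float = 0.1
    hold_interval: float = 0.1
    seed: int = 0
    targets: tuple[str, ...] = ("iin",)

    def __post_init__(self):
        if not (0 <= self.fraction < 1):
            raise DomainError(f"noise fraction must be in [0, 1), got {self.fraction}")
        if self.hold_interval <= 0:
            raise DomainError(f"hold_interval must be > 0, got {self.hold_interval}")
        bad = set(self.targets) - set(VALID_TARGETS)
        if bad:
            raise DomainError(f"unknown noise targets {sorted(bad)}; valid: {VALID_TARGETS}")


class HeldUniformNoise:
    """Piecewise-constant bounded noise, callable as eta(t)."""

    def __init__(
        self,
        spec: NoiseSpec,
        t_end: float,
        ref_times: np.ndarray,
        ref_signal: np.ndarray,
        rng: np.random.Generator | None = None,
    ):
        self.spec = spec
        self.hold = spec.hold_interval
        n = int(np.ceil(t_end / self.hold)) + 1
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        self._draws = rng.uniform(-1.0, 1.0, size=n)
        # running max of |clean signal| evaluated at each interval start
        starts = np.arange(n) * self.hold
        runmax = np.maximum.accumulate(np.abs(np.asarray(ref_signal, float)))
        idx = np.searchsorted(np.asarray(ref_times, float), starts, side="right")
        idx = np.clip(idx, 1, len(runmax)) - 1
        self._bounds = spec.fraction * runmax[idx]

    def __call__(self, t: float) -> float:
        i = min(int(t / self.hold), self._draws.size - 1)
        return self._draws[i] * self._bounds[i]

    @property
    def max_magnitude(self) -> float:
        return float(np.max(np.abs(self._draws * self._bounds)))


class _ZeroNoise:
    def __call__(self, t: float) -> float:
        return 0.0

    max_magnitude = 0.0


def add_noise(
    spec: NoiseSpec,
    t_end: float = 600.0,
    ref_times: np.ndarray | None = None,
    ref_signal: np.ndarray | None = None,
):
    """Build a single noise process from a spec.

    With fraction 0 the process is identically zero and needs no reference;
    otherwise the clean reference signal sets the running-max bound.
    """
    if spec.fraction == 0.0:
        return _ZeroNoise()
    if ref_times is None or ref_signal is None:
        raise DomainError("a clean reference signal is required when fraction > 0")
    return HeldUniformNoise(spec, t_end, ref_times, ref_signal)


def build_module_noise(
    spec: NoiseSpec,
    t_end: float,
    clean_times: np.ndarray,
    clean_data: np.ndarray,
    i_in: float = 0.0,
) -> dict:
    """One independent noise process per perturbed injection point.

    Child RNG streams are spawned deterministically from the NoiseSpec seed, so
    the set of processes is reproducible as a whole.  For the constant source
    current the reference "signal" is |I_in| itself.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rngs = {
        "iin": np.random.default_rng(streams[0]),
        "serca": np.random.default_rng(streams[1]),
        "plc": np.random.default_rng(streams[2]),
        "cicr_x": np.random.default_rng(streams[3]),
        "cicr_z": np.random.default_rng(streams[4]),
    }
    X, Z = clean_data[:, 0], clean_data[:, 2]
    refs = {
        "iin": np.full(2, abs(i_in)),
        "serca": X,
        "plc": X,
        "cicr_x": X,
        "cicr_z": Z,
    }
    ref_t = {"iin": clean_times[:2] if clean_times.size >= 2 else clean_times}
    wanted = []
    if "iin" in spec.targets:
        wanted.append("iin")
    if "serca" in spec.targets:
        wanted.append("serca")
    if "plc" in spec.targets:
        wanted.append("plc")
    if "cicr" in spec.targets:
        wanted.extend(["cicr_x", "cicr_z"])
    return {
        k: HeldUniformNoise(
            spec, t_end, ref_t.get(k, clean_times), refs[k][: refs[k].size], rng=rngs[k]
        )
        for k in wanted
    }
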