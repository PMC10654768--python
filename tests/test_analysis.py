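"""Experiment layer: period estimation, sweeps, noise process, comparison."""

import numpy as np
import pytest

from astroca import (
    NoiseSpec,
    Trajectory,
    compare_trajectories,
    estimate_period,
    simulate,
    sweep_vin,
)
from astroca.analysis import portrait_distance
from astroca.exceptions import (
    DomainError,
    NonOscillatoryError,
    SweepError,
    TooFewPeaksError,
)
from astroca.noise import HeldUniformNoise, add_noise


def synthetic_trace(signal: np.ndarray, t: np.ndarray) -> Trajectory:
    data = np.column_stack([signal, np.ones_like(t), np.ones_like(t)])
    return Trajectory(t, data)


class TestEstimatePeriod:
    def test_known_sinusoid(self):
        t = np.arange(0.0, 300.0, 0.01)
        traj = synthetic_trace(np.sin(2 * np.pi * t / 30.0), t)
        s = estimate_period(traj)
        assert s.period == pytest.approx(30.0, abs=0.01)
        assert s.period_sd < 0.02

    def test_constant_signal_raises(self):
        t = np.arange(0.0, 100.0, 0.1)
        with pytest.raises(TooFewPeaksError):
            estimate_period(synthetic_trace(np.ones_like(t), t))

    def test_agrees_with_mean_crossing_oracle(self, lh_traj):
        # independent estimate: mean interval between upward crossings of the
        # post-transient mean level
        s = estimate_period(lh_traj)
        t, x = lh_traj.times, lh_traj.column("X")
        keep = t >= 600.0
        t, x = t[keep], x[keep]
        mean = x.mean()
        up = np.where((x[:-1] < mean) & (x[1:] >= mean))[0]
        oracle = float(np.mean(np.diff(t[up])))
        assert s.period == pytest.approx(oracle, rel=0.01)

    def test_invariant_to_scaling_and_time_shift(self, lh_traj):
        s0 = estimate_period(lh_traj)
        scaled = Trajectory(
            lh_traj.times + 137.0, lh_traj.data * 3.7, lh_traj.columns
        )
        s1 = estimate_period(scaled)
        assert s1.period == s0.period
        assert s1.n_peaks == s0.n_peaks


class TestSweep:
    def test_single_value_matches_direct_composition(self, lh_params):
        [(v, s)] = sweep_vin([0.05], lh_params=lh_params, t_end=1500.0)
        direct = estimate_period(simulate(lh_params, t_end=1500.0, dt_out=0.5))
        assert v == 0.05
        assert s.period == direct.period

    def test_preserves_input_order(self, lh_params):
        res = sweep_vin([0.05, 0.04], lh_params=lh_params, t_end=1500.0)
        assert [v for v, _ in res] == [0.05, 0.04]

    def test_period_decreases_with_influx_in_oscillatory_window(self, lh_params):
        # the qualitative influx dependence, inside the window where the
        # model actually has a limit cycle
        res = sweep_vin([0.04, 0.05, 0.06], lh_params=lh_params, t_end=2000.0)
        periods = [s.period for _, s in res]
        assert periods[0] > periods[1] > periods[2]

    def test_empty_sweep_rejected(self):
        with pytest.raises(SweepError):
            sweep_vin([])

    def test_failures_tagged_with_offending_value(self, lh_params):
        # V_in = 0.2 is far above the oscillatory window: stable equilibrium
        with pytest.raises(SweepError) as err:
            sweep_vin([0.2], lh_params=lh_params, t_end=400.0)
        assert err.value.value == 0.2


class TestNoiseProcess:
    def test_zero_fraction_is_identically_zero(self):
        eta = add_noise(NoiseSpec(fraction=0.0))
        assert all(eta(t) == 0.0 for t in np.linspace(0, 100, 57))

    def test_bound_holds_everywhere(self):
        t_ref = np.arange(0.0, 50.0, 0.1)
        sig = 0.3 * np.sin(t_ref) + 0.2
        spec = NoiseSpec(fraction=0.1, hold_interval=0.25, seed=3)
        eta = add_noise(spec, 50.0, t_ref, sig)
        bound = 0.1 * np.max(np.abs(sig))
        samples = np.array([eta(t) for t in np.linspace(0, 50, 2000)])
        assert np.all(np.abs(samples) <= bound + 1e-15)

    def test_running_maximum_bound_is_causal(self):
        # early noise is bounded by the signal seen so far, not the global max
        t_ref = np.arange(0.0, 50.0, 0.1)
        sig = np.where(t_ref < 25.0, 0.1, 1.0)
        eta = add_noise(NoiseSpec(fraction=0.1, seed=5), 50.0, t_ref, sig)
        early = np.array([eta(t) for t in np.linspace(0, 24.9, 500)])
        assert np.all(np.abs(early) <= 0.01 + 1e-15)

    def test_seed_reproducibility(self):
        t_ref = np.arange(0.0, 20.0, 0.1)
        sig = np.ones_like(t_ref)
        a = add_noise(NoiseSpec(fraction=0.2, seed=9), 20.0, t_ref, sig)
        b = add_noise(NoiseSpec(fraction=0.2, seed=9), 20.0, t_ref, sig)
        ts = np.linspace(0, 20, 333)
        assert [a(t) for t in ts] == [b(t) for t in ts]

    def test_piecewise_constant_over_hold_interval(self):
        t_ref = np.arange(0.0, 10.0, 0.1)
        eta = add_noise(NoiseSpec(fraction=0.5, hold_interval=1.0, seed=2),
                        10.0, t_ref, np.ones_like(t_ref))
        assert eta(3.01) == eta(3.5) == eta(3.99)
        assert isinstance(eta, HeldUniformNoise)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(DomainError):
            NoiseSpec(fraction=1.2)
        with pytest.raises(DomainError):
            NoiseSpec(fraction=-0.1)
        with pytest.raises(DomainError):
            NoiseSpec(targets=("nonsense",))


class TestCompareTrajectories:
    def test_identity(self, lh_traj):
        rec = compare_trajectories(lh_traj, lh_traj)
        assert rec.period_ratio == 1.0
        assert rec.portrait_distance == pytest.approx(0.0, abs=1e-12)
        assert all(r == 1.0 for r in rec.amplitude_ratios.values())

    def test_time_shifted_copy_has_same_orbit(self, lh_traj):
        # drop one full cycle from the front: same closed curve in phase space
        s = estimate_period(lh_traj)
        k = int(round(s.period / 0.5))
        shifted = Trajectory(
            lh_traj.times[: len(lh_traj) - k],
            lh_traj.data[k:],
            lh_traj.columns,
        )
        rec = compare_trajectories(lh_traj, shifted)
        assert rec.portrait_distance < 0.01

    def test_non_oscillatory_input_rejected(self):
        t = np.arange(0.0, 100.0, 0.1)
        flat = Trajectory(t, np.ones((t.size, 3)))
        with pytest.raises(NonOscillatoryError):
            compare_trajectories(flat, flat)

    def test_distance_matches_all_pairs_oracle(self, lh_traj, circuit_traj):
        # brute-force all-pairs nearest neighbor on decimated orbits
        a = lh_traj.data[lh_traj.times >= 600.0][::20]
        b = circuit_traj.data[circuit_traj.times >= 600.0][::20]
        fast = portrait_distance(a, b)
        lo = np.minimum(a.min(axis=0), b.min(axis=0))
        hi = np.maximum(a.max(axis=0), b.max(axis=0))
        an = (a - lo) / (hi - lo)
        bn = (b - lo) / (hi - lo)
        d = np.linalg.norm(an[:, None, :] - bn[None, :, :], axis=2)
        brute = 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())
        assert fast == pytest.approx(brute, rel=1e-12)
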