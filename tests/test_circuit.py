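"""Circuit behavioral model: differential pair, tanh modules, KCL wiring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astroca import (
    CircuitParams,
    DiffPairParams,
    LHParams,
    SolverSettings,
    TanhModule,
    calibrate_gains,
    circuit_rhs,
    diffpair_current,
    eval_tanh_module,
    i_cicr_approx,
    simulate,
    simulate_circuit,
)
from astroca.circuit import _ls_gain, _printed_modules
from astroca.exceptions import DomainError
from astroca.lh_model import lh_rhs


class TestDiffPair:
    P = DiffPairParams(alpha=0.99, I_EE=2.0, V_T=0.02585)

    def test_zero_at_balance(self):
        assert diffpair_current(0.7, 0.7, self.P) == 0.0

    def test_saturates_at_tail_current(self):
        assert diffpair_current(10.0, -10.0, self.P) == pytest.approx(
            self.P.alpha * self.P.I_EE, rel=1e-12
        )

    def test_transfer_at_two_thermal_voltages(self):
        got = diffpair_current(2 * self.P.V_T, 0.0, self.P)
        assert got == pytest.approx(self.P.alpha * self.P.I_EE * math.tanh(1.0), rel=1e-14)

    @given(dv=st.floats(-1.0, 1.0))
    def test_odd_and_bounded(self, dv):
        up = diffpair_current(dv, 0.0, self.P)
        dn = diffpair_current(0.0, dv, self.P)
        assert up == pytest.approx(-dn, abs=1e-15)
        assert abs(up) <= self.P.alpha * self.P.I_EE

    def test_parameter_validation(self):
        with pytest.raises(DomainError):
            DiffPairParams(alpha=1.5)
        with pytest.raises(DomainError):
            DiffPairParams(V_T=0.0)


class TestTanhModules:
    def test_serca_zero_crossing(self):
        m = _printed_modules()["serca"]
        # argument 5*0.013 - 0.065 = 0
        assert eval_tanh_module(m, 0.013) == pytest.approx(0.0, abs=1e-15)

    def test_fx1_additive_constant_at_zero_argument(self):
        m = _printed_modules()["fx1"]
        # argument 0.22 - 5.5*0.04 = 0, leaving only the constant source
        assert eval_tanh_module(m, 0.04) == pytest.approx(1.08, abs=1e-15)

    def test_fz_saturation(self):
        m = _printed_modules()["fz"]
        assert eval_tanh_module(m, 1e6) == pytest.approx(5.0, rel=1e-12)

    @settings(max_examples=200)
    @given(u=st.floats(-50.0, 50.0))
    @pytest.mark.parametrize("name", ["serca", "plc", "fx1", "fx2", "fz"])
    def test_output_bound(self, name, u):
        m = _printed_modules()[name]
        assert abs(m(u)) <= m.bound + 1e-12

    def test_zero_slope_rejected(self):
        with pytest.raises(DomainError):
            TanhModule(slope=0.0, offset=0.1)


class TestCicrApprox:
    def test_zero_when_no_gradient(self):
        cp = CircuitParams.printed()
        assert i_cicr_approx((0.3, 0.3, 0.1), cp) == 0.0

    def test_zero_at_ip3_gate_crossing(self):
        # fz argument 2.5*0.012 - 0.03 = 0 annihilates the product
        cp = CircuitParams.printed()
        assert i_cicr_approx((0.04, 1.0, 0.012), cp) == pytest.approx(0.0, abs=1e-15)

    def test_matches_straight_line_transcription(self):
        # independent term-by-term evaluation of the printed approximation
        cp = CircuitParams.printed()
        X, Y, Z = 0.04, 1.0, 0.1
        fx1 = math.tanh(0.22 - 5.5 * X) + 1.08
        fx2 = 4.0 * math.tanh(3.9 * X - 0.07)
        fz = 5.0 * math.tanh(2.5 * Z - 0.03)
        expected = 4.0 * 40.0 * fx1 * fx2 * fz * (Y - X)
        assert i_cicr_approx((X, Y, Z), cp) == pytest.approx(expected, rel=1e-14)


_CPS = {"printed": CircuitParams.printed(), "calibrated": CircuitParams.calibrated()}


@settings(max_examples=200)
@given(
    x=st.floats(0.0, 3.0),
    y=st.floats(0.0, 5.0),
    z=st.floats(0.0, 1.0),
)
@pytest.mark.parametrize("mode", ["printed", "calibrated"])
def test_kcl_conservation(mode, x, y, z):
    cp = _CPS[mode]
    d = circuit_rhs((x, y, z), cp)
    assert cp.c_X * d[0] + cp.c_Y * d[1] == pytest.approx(
        cp.I_in - cp.g_out * x, abs=1e-10
    )


class TestExactPlugin:
    def test_pointwise_equivalence(self):
        lh = LHParams()
        cp = CircuitParams.exact_plugin(lh)
        rng = np.random.default_rng(1)
        for state in rng.uniform(0.0, 2.0, size=(500, 3)):
            a = lh_rhs(state, lh)
            b = circuit_rhs(state, cp)
            assert np.array_equal(a, b), f"mismatch at {state}"

    def test_fixed_step_trajectories_bit_identical(self):
        lh = LHParams()
        cp = CircuitParams.exact_plugin(lh)
        st_ = SolverSettings(method="rk4", rk4_step=1e-3)
        a = simulate(lh, t_end=10.0, dt_out=0.1, settings=st_)
        b = simulate_circuit(cp, t_end=10.0, dt_out=0.1, settings=st_)
        assert np.array_equal(a.data, b.data)


class TestCalibration:
    def test_self_match_gives_unit_gains(self):
        # when the "approximations" are the Hill forms themselves, the
        # least-squares scale must be exactly 1
        lh = LHParams()
        cp = CircuitParams.exact_plugin(lh)
        gains = calibrate_gains(cp, lh)
        assert gains == pytest.approx((1.0, 1.0, 1.0), rel=1e-12)

    def test_zero_target_gives_zero_gain(self):
        model = np.linspace(0.1, 1.0, 50)
        assert _ls_gain(np.zeros(50), model) == 0.0

    def test_serca_gain_scales_like_pump_maximum(self):
        # the unit-amplitude tanh must be scaled up to the uM/s flux range
        lh = LHParams()
        gains = calibrate_gains(CircuitParams.printed(lh), lh, X_range=(0.0, 1.5))
        assert 0.5 * lh.v_M2 < gains[0] < 1.5 * lh.v_M2
        assert 0.5 * lh.v_p < gains[1] < 1.5 * lh.v_p

    def test_degenerate_range_rejected(self):
        lh = LHParams()
        with pytest.raises(DomainError):
            calibrate_gains(CircuitParams.printed(lh), lh, X_range=(1.0, 1.0))

    def test_closed_form_least_squares_oracle(self):
        # gain = <f*g> / <g*g> on the grid, checked against the implementation
        lh = LHParams()
        cp = CircuitParams.printed(lh)
        from astroca.lh_model import v_serca

        Xg = np.linspace(0.0, 1.5, 301)
        f = v_serca(Xg, lh)
        g = cp.serca(Xg)
        expected = float(f @ g / (g @ g))
        assert calibrate_gains(cp, lh)[0] == pytest.approx(expected, rel=1e-12)


def test_circuit_oscillates_with_calibrated_gains(circuit_traj):
    from astroca.analysis import estimate_period

    s = estimate_period(circuit_traj)
    assert s.n_peaks >= 5
    # closed orbit: post-transient range is stable (no decay to equilibrium)
    x = circuit_traj.column("X")[circuit_traj.times >= 1000.0]
    assert x.max() - x.min() > 0.1


def test_circuit_simulation_deterministic(circuit_cp):
    a = simulate_circuit(circuit_cp, t_end=100.0, dt_out=0.5)
    b = simulate_circuit(circuit_cp, t_end=100.0, dt_out=0.5)
    assert np.array_equal(a.data, b.data)
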