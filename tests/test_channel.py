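"""Closed-form Ih component model: activation, kinetics, step response."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ihfit.channel import (ChannelConstants, ComponentParams, StepSpec,
                           activation, deactivation_current, step_current,
                           time_constant, total_current)

SLOW = ComponentParams(Vh=-100, k=-6, M=-80, S=80, A=1000, B=60, G=3)
FAST = ComponentParams(Vh=-130, k=-9, M=-80, S=40, A=250, B=40, G=4)


params_st = st.builds(
    ComponentParams,
    Vh=st.floats(-160, -60),
    k=st.floats(-15, -1),
    M=st.floats(-140, -40),
    S=st.floats(5, 150),
    A=st.floats(10, 2000),
    B=st.floats(1, 200),
    G=st.floats(0, 20),
)


class TestActivation:
    @pytest.mark.parametrize("V, expected", [
        (-100.0, 0.5),            # Boltzmann midpoint
        (-130.0, 0.99331),
        (-70.0, 0.00669),
    ])
    def test_boltzmann_values(self, V, expected):
        assert activation(V, SLOW) == pytest.approx(expected, abs=1e-5)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            ComponentParams(Vh=-100, k=0, M=-80, S=80, A=1000, B=60, G=3)

    @given(params_st, st.floats(-200, 20))
    def test_bounded_open_interval(self, p, V):
        r = activation(V, p)
        assert 0.0 < r < 1.0

    @given(params_st, st.floats(-200, 20), st.floats(0.5, 30))
    def test_monotone_decreasing_for_negative_k(self, p, V, dV):
        assert activation(V + dV, p) < activation(V, p)


class TestTimeConstant:
    def test_peak_at_M(self):
        assert time_constant(SLOW.M, SLOW) == pytest.approx(1060.0)

    def test_one_width_from_peak(self):
        for sign in (-1, 1):
            tau = time_constant(SLOW.M + sign * SLOW.S, SLOW)
            assert tau == pytest.approx(SLOW.B + SLOW.A / np.e)

    def test_derived_value(self):
        assert time_constant(-160.0, SLOW) == pytest.approx(427.879, abs=1e-2)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            ComponentParams(Vh=-100, k=-6, M=-80, S=0, A=1000, B=60, G=3)

    @given(params_st, st.floats(-200, 20))
    def test_range(self, p, V):
        # infimum B (reached only in floating-point underflow far from M),
        # maximum A + B at V = M
        tau = time_constant(V, p)
        assert p.B <= tau <= p.A + p.B + 1e-9


class TestStepCurrent:
    STEP = StepSpec(Vps=-60, Vs=-150, t_step=4000)

    def test_steady_state_amplitude(self):
        # 3 nS * 0.99976 * (-150 + 36) = -341.9 pA
        assert step_current(1e9, self.STEP, SLOW) == pytest.approx(-341.92, abs=0.05)

    def test_initial_value_is_prestep_steady_state(self):
        i0 = step_current(0.0, self.STEP, SLOW)
        r0 = activation(-60.0, SLOW)
        assert i0 == pytest.approx(SLOW.G * r0 * (-150 + 36))
        assert abs(i0) < 1.0  # essentially zero for Ih held at -60 mV

    def test_no_relaxation_when_step_equals_prestep(self):
        step = StepSpec(Vps=-100, Vs=-100, t_step=1000)
        t = np.linspace(0, 1000, 50)
        i = step_current(t, step, SLOW)
        assert np.allclose(i, i[0])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            step_current(-1.0, self.STEP, SLOW)

    def test_monotone_relaxation_between_endpoints(self):
        t = np.linspace(0, 20000, 2000)
        i = step_current(t, self.STEP, SLOW)
        # relaxes toward the more negative limit; flat only once converged
        # to machine precision at the tail
        assert np.all(np.diff(i) <= 0)
        assert np.all(np.diff(i[:500]) < 0)
        lo = SLOW.G * activation(-150.0, SLOW) * (-150 + 36)
        assert i[0] > lo and i[-1] == pytest.approx(lo, rel=1e-6)

    def test_relaxation_time_constant_is_tau_at_step_voltage(self):
        tau = time_constant(-150.0, SLOW)
        i_inf = step_current(1e9, self.STEP, SLOW)
        i0 = step_current(0.0, self.STEP, SLOW)
        i_tau = step_current(tau, self.STEP, SLOW)
        assert (i_tau - i_inf) / (i0 - i_inf) == pytest.approx(np.exp(-1))


class TestDeactivation:
    def test_zero_duration_step_is_holding_current(self):
        step = StepSpec(Vps=-60, Vs=-150, t_step=1e-12)
        t = np.linspace(0, 500, 20)
        i = deactivation_current(t, step, SLOW)
        hold = SLOW.G * activation(-60.0, SLOW) * (-60 + 36)
        assert np.allclose(i, hold, atol=1e-6)

    def test_long_time_returns_to_prestep_steady_state(self):
        step = StepSpec(Vps=-60, Vs=-150, t_step=50000)
        i = deactivation_current(1e9, step, SLOW)
        assert i == pytest.approx(SLOW.G * activation(-60.0, SLOW) * (-60 + 36))

    def test_tail_matches_ode_oracle(self):
        from conftest import euler_gate_current

        step = StepSpec(Vps=-60, Vs=-150, t_step=1500, t_post=800)
        oracle = euler_gate_current(step, FAST, dt=0.01,
                                    n_act=150000, n_post=80000, sample_every=1000)
        t_act = np.arange(150) * 10.0
        t_post = np.arange(80) * 10.0
        closed = np.concatenate([
            step_current(t_act, step, FAST),
            deactivation_current(t_post, step, FAST),
        ])
        assert np.max(np.abs(closed - oracle)) < 0.05


class TestTotalCurrent:
    STEP = StepSpec(Vps=-60, Vs=-150, t_step=4000)

    def test_zero_fast_conductance_leaves_slow_only(self):
        t = np.linspace(0, 4000, 100)
        gone = FAST.replace(G=0.0)
        assert np.allclose(total_current(t, self.STEP, SLOW, gone),
                           step_current(t, self.STEP, SLOW))

    def test_identical_components_double(self):
        t = np.linspace(0, 4000, 100)
        assert np.allclose(total_current(t, self.STEP, SLOW, SLOW),
                           2 * step_current(t, self.STEP, SLOW))

    def test_steady_state_is_sum_of_closed_forms(self):
        i = total_current(1e9, self.STEP, SLOW, FAST)
        expect = sum(p.G * activation(-150.0, p) * (-150 + 36) for p in (SLOW, FAST))
        assert i == pytest.approx(expect)

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    def test_linear_in_each_conductance(self, gs, gf):
        t = np.array([0.0, 500.0, 4000.0])
        a = total_current(t, self.STEP, SLOW.replace(G=gs), FAST.replace(G=gf))
        b = gs / 3 * step_current(t, self.STEP, SLOW) \
            + gf / 4 * step_current(t, self.STEP, FAST)
        assert np.allclose(a, b)


def test_reversal_potential_constant():
    c = ChannelConstants()
    assert c.Eh == -36.0
    # current vanishes when stepping to the reversal potential
    step = StepSpec(Vps=-60, Vs=-36.0, t_step=100)
    assert step_current(50.0, step, SLOW, c) == 0.0
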