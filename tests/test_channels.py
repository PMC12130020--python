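"""Channel current laws, gating updates and synaptic windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from caadex.channels import (
    ReceptorSpec,
    ca_hva_current,
    double_exp_normalization,
    double_exp_peak_time,
    gating_step,
    kca_current,
    kca_m_inf,
    nmda_block,
    receptor_conductance,
    sigmoid_inf,
    update_calcium,
    adex_exponential_current,
    EXP_ARG_CLAMP,
)
from caadex.model import CaHotzoneMechanism, ConfigurationError


def _hz(**kw):
    base = dict(g_Ca=10.0, E_Ca=50.0, m_slope=-0.4, m_half=-25.0, tau_m_Ca=4.0,
                h_slope=0.25, h_half=-35.0, tau_h_Ca=80.0, g_K=15.0, E_K=-85.0,
                tau_m_KCa=10.0, Ca_th=4e-4, const_KCa=4.0, phi_Ca=1e-7,
                Ca_0=1e-4, tau_Ca=80.0)
    base.update(kw)
    return CaHotzoneMechanism(**base)


class TestSteadyStates:
    def test_half_activation_at_m_half(self):
        spec = _hz()
        assert sigmoid_inf(spec.m_half, spec.m_slope, spec.m_half) == pytest.approx(0.5)

    def test_kca_half_activation_at_threshold(self):
        assert kca_m_inf(4e-4, _hz()) == pytest.approx(0.5)

    def test_kca_saturates(self):
        assert kca_m_inf(1.0, _hz()) == pytest.approx(1.0, abs=1e-9)

    def test_kca_at_half_threshold_with_square_exponent(self):
        # 1 / (1 + (Ca_th / (Ca_th/2))**2) = 1/5
        assert kca_m_inf(2e-4, _hz(const_KCa=2.0)) == pytest.approx(0.2)

    def test_kca_zero_calcium_limit(self):
        assert kca_m_inf(0.0, _hz()) == 0.0


class TestCurrents:
    def test_closed_gates_carry_no_current(self):
        spec = _hz()
        assert ca_hva_current(0.0, 1.0, -30.0, spec) == 0.0
        assert ca_hva_current(1.0, 0.0, -30.0, spec) == 0.0

    def test_driving_force_form(self):
        # g=2 nS fully open, 10 mV below reversal -> 20 pA inward
        spec = _hz(g_Ca=2.0)
        assert ca_hva_current(1.0, 1.0, spec.E_Ca - 10.0, spec) == pytest.approx(20.0)

    def test_kca_is_outward_above_EK(self):
        spec = _hz()
        assert kca_current(0.5, -30.0, spec) < 0

    def test_exponential_term_at_threshold(self):
        # exp(0) = 1 -> current equals g_L * Delta_T
        assert adex_exponential_current(-50.0, 10.0, 2.0, -50.0) == pytest.approx(20.0)

    def test_exponential_clamp_is_finite(self):
        v = adex_exponential_current(1000.0, 10.0, 2.0, -50.0)
        assert v == pytest.approx(10.0 * 2.0 * math.exp(EXP_ARG_CLAMP))


class TestCalciumPool:
    def test_baseline_is_fixed_point(self):
        spec = _hz()
        assert update_calcium(spec.Ca_0, 0.0, 0.1, spec) == pytest.approx(spec.Ca_0)

    def test_relaxation_toward_baseline(self):
        spec = _hz()
        ca0 = 5e-4
        ca1 = update_calcium(ca0, 0.0, spec.tau_Ca, spec)
        expected = spec.Ca_0 + (ca0 - spec.Ca_0) * math.exp(-1.0)
        assert ca1 == pytest.approx(expected, rel=1e-12)

    def test_steady_state_under_constant_current(self):
        spec = _hz()
        ca = spec.Ca_0
        for _ in range(400):
            ca = update_calcium(ca, 100.0, 5.0, spec)
        assert ca == pytest.approx(spec.Ca_0 + spec.phi_Ca * 100.0 * spec.tau_Ca,
                                   rel=1e-6)


class TestGatingStep:
    def test_zero_step_is_identity(self):
        assert gating_step(0.3, 0.9, 5.0, 0.0) == pytest.approx(0.3)

    def test_long_step_saturates(self):
        assert gating_step(0.3, 0.9, 5.0, 1e4) == pytest.approx(0.9)

    def test_against_fine_step_reference(self):
        """Propagator trajectory under sinusoidal V vs RK45 at tiny steps."""
        spec = _hz()
        h = 0.1

        def V(t):
            return -45.0 + 20.0 * np.sin(2 * np.pi * t / 40.0)

        def rhs(t, y):
            return (sigmoid_inf(V(t), spec.m_slope, spec.m_half) - y) / spec.tau_m_Ca

        T = 80.0
        sol = solve_ivp(rhs, (0, T), [0.1], rtol=1e-10, atol=1e-12, dense_output=True)
        y = 0.1
        errs = []
        for k in range(int(T / h)):
            # the propagator holds V at the end-of-step value, as in the solver
            y = gating_step(y, sigmoid_inf(V((k + 1) * h), spec.m_slope, spec.m_half),
                            spec.tau_m_Ca, h)
            errs.append(abs(y - sol.sol((k + 1) * h)[0]))
        assert max(errs) < 5e-3

    @given(st.floats(-120, 40), st.floats(0.0, 10.0), st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_stays_in_unit_interval(self, V, h, y0):
        spec = _hz()
        y = gating_step(y0, sigmoid_inf(V, spec.m_slope, spec.m_half),
                        spec.tau_m_Ca, h)
        assert 0.0 <= y <= 1.0


class TestReceptorWindow:
    def test_peak_equals_weight(self):
        spec = ReceptorSpec("AMPA", tau_r=0.2, tau_d=3.0, w=2.5)
        t_peak = double_exp_peak_time(0.2, 3.0)
        assert receptor_conductance(spec, [0.0], t_peak) == pytest.approx(2.5, abs=1e-9)

    def test_ampa_normalization_constant(self):
        assert double_exp_normalization(0.2, 3.0) == pytest.approx(1.300, abs=2e-3)

    def test_causality(self):
        spec = ReceptorSpec("AMPA", tau_r=0.2, tau_d=3.0, w=1.0)
        assert receptor_conductance(spec, [5.0], 4.9) == 0.0
        assert receptor_conductance(spec, [5.0], 5.0) == 0.0

    def test_single_interior_maximum(self):
        spec = ReceptorSpec("GABA", tau_r=0.2, tau_d=10.0, w=1.0)
        t = np.linspace(0, 60, 6001)
        g = receptor_conductance(spec, [0.0], t)
        assert g.max() == pytest.approx(1.0, abs=1e-4)
        peaks = np.flatnonzero((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:]))
        assert len(peaks) == 1

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ConfigurationError):
            ReceptorSpec("AMPA", tau_r=3.0, tau_d=3.0)


class TestNmdaBlock:
    @pytest.mark.parametrize("V, expected", [
        (0.0, 1.0 / 1.3),
        (-10.0, 1.0 / (1.0 + 0.3 * math.exp(1.0))),
        (500.0, 1.0),
    ])
    def test_values(self, V, expected):
        assert nmda_block(V) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, v1, v2):
        s1, s2 = nmda_block(v1), nmda_block(v2)
        assert 0.0 < s1 < 1.0
        if v2 - v1 > 1e-9:      # below float resolution sigma can tie
            assert s1 < s2
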