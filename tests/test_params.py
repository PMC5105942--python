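"""Membrane-model unit tests: gating curves, right-hand side, rest."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from padsim.params import (
    InvalidParameterError,
    NeuronParams,
    StateVector,
    cable_membrane_params,
    default_params,
    gating_steady,
    gating_tau,
    membrane_rhs,
    resting_state,
    revised_s1_params,
)


class TestGatingSteady:
    @pytest.mark.parametrize(
        "V, beta, gamma, expected",
        [
            (-1.2, -1.2, 18.0, 0.5),                       # midpoint
            (16.8, -1.2, 18.0, 0.5 * (1 + math.tanh(1))),  # one slope up
            (-70.0, -1.2, 18.0, 0.5 * (1 + math.tanh((-70 + 1.2) / 18))),
        ],
    )
    def test_closed_form(self, V, beta, gamma, expected):
        assert gating_steady(V, beta, gamma) == pytest.approx(
            expected, rel=1e-12
        )

    def test_deep_hyperpolarization_value(self):
        # sodium activation is essentially shut at rest
        assert gating_steady(-70.0, -1.2, 18.0) == pytest.approx(
            4.8e-4, rel=0.02
        )

    @given(
        v1=st.floats(-60, 30),
        dv=st.floats(1e-3, 20),
        gamma=st.floats(5.0, 30),
    )
    def test_monotone_and_bounded(self, v1, dv, gamma):
        # domain kept clear of float64 tanh saturation (|x| < ~19)
        lo, hi = gating_steady(v1, -10.0, gamma), gating_steady(
            v1 + dv, -10.0, gamma
        )
        assert 0 < lo < hi < 1
        # negative slope reverses the direction (h-type gate)
        assert gating_steady(v1, -10.0, -gamma) > gating_steady(
            v1 + dv, -10.0, -gamma
        )

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            gating_steady(0.0, -1.2, 0.0)


class TestGatingTau:
    def test_maximum_at_midpoint(self):
        assert gating_tau(-20.0, -20.0, 10.0) == 1.0

    def test_closed_form(self):
        assert gating_tau(0.0, -20.0, 10.0) == pytest.approx(
            1.0 / math.cosh(1.0), rel=1e-12
        )

    @given(x=st.floats(0, 80), gamma=st.floats(0.5, 30))
    def test_even_about_midpoint(self, x, gamma):
        beta = -20.0
        assert gating_tau(beta + x, beta, gamma) == pytest.approx(
            gating_tau(beta - x, beta, gamma), rel=1e-12
        )

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            gating_tau(0.0, -20.0, 0.0)


class TestMembraneRhs:
    def test_bare_capacitor(self):
        p = NeuronParams(g_Na_bar=0.0, g_K_bar=0.0, g_leak=0.0)
        dv = membrane_rhs(np.array([-60.0, 0.1, 0.9]), 0.0, p, i_stim=5.0)[0]
        assert dv == pytest.approx(5.0 / p.C)

    def test_leak_equilibrium(self):
        p = NeuronParams(g_Na_bar=0.0, g_K_bar=0.0)
        dv = membrane_rhs(np.array([p.E_leak, 0.0, 1.0]), 0.0, p)[0]
        assert dv == 0.0

    def test_full_h_neutralizes_inactivation(self):
        s = np.array([-30.0, 0.2, 1.0])
        d0 = membrane_rhs(s, 0.0, default_params())
        d5 = membrane_rhs(s, 0.0, default_params().replace(p=0.5))
        assert d0[0] == pytest.approx(d5[0], rel=1e-14)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(FloatingPointError):
            membrane_rhs(np.array([np.nan, 0.1, 1.0]), 0.0, default_params())


class TestRestingState:
    def test_leak_only_rests_at_e_leak(self):
        p = NeuronParams(g_Na_bar=0.0, g_K_bar=0.0)
        assert resting_state(p).V == pytest.approx(-70.0, abs=1e-9)

    def test_default_rest_matches_independent_root(self, default_params):
        # independent oracle: scalar root of the steady-state current
        p = default_params

        def f(V):
            m = 0.5 * (1 + math.tanh((V - p.beta_m) / p.gamma_m))
            w = 0.5 * (1 + math.tanh((V - p.beta_w) / p.gamma_w))
            return -(
                p.g_Na_bar * m * (V - p.E_Na)
                + p.g_K_bar * w * (V - p.E_K)
                + p.g_leak * (V - p.E_leak)
            )

        v_oracle = brentq(f, -100.0, -40.0, xtol=1e-12)
        rest = resting_state(p)
        assert rest.V == pytest.approx(v_oracle, abs=1e-9)
        assert rest.V == pytest.approx(-69.4, abs=0.3)

    def test_rhs_vanishes_at_rest(self, default_params):
        rest = resting_state(default_params)
        rhs = membrane_rhs(rest.as_array(), 0.0, default_params)
        assert np.max(np.abs(rhs)) < 1e-9

    def test_virtual_na_shifts_rest_depolarized(self, default_params):
        p = default_params.replace(
            g_Na_virtual=0.5, beta_m_virtual=-55.0, gamma_m_virtual=10.0
        )
        assert resting_state(p).V > resting_state(default_params).V


class TestPresetsAndValidation:
    def test_default_preset_values(self):
        p = default_params()
        assert (p.C, p.g_Na_bar, p.E_Na) == (2.0, 20.0, 50.0)
        assert (p.beta_m, p.gamma_m) == (-1.2, 18.0)
        assert (p.g_K_bar, p.E_K, p.phi_w, p.gamma_w) == (20.0, -100.0, 0.15, 10.0)
        assert (p.g_leak, p.E_leak, p.beta_w) == (2.0, -70.0, -20.0)
        assert (p.beta_h, p.gamma_h, p.phi_h) == (-28.0, -14.0, 0.005)
        assert p.p == 0.0

    def test_variant_presets(self):
        s1 = revised_s1_params()
        assert (s1.g_leak, s1.g_K_bar) == (0.7, 30.0)
        cab = cable_membrane_params()
        assert (cab.g_Na_bar, cab.g_K_bar) == (30.0, 30.0)

    @pytest.mark.parametrize(
        "bad",
        [
            {"C": 0.0},
            {"g_leak": -1.0},
            {"p": 1.5},
            {"gamma_m": -1.0},
            {"gamma_h": 14.0},
        ],
    )
    def test_invariants_enforced(self, bad):
        with pytest.raises(InvalidParameterError):
            NeuronParams(**bad)

    def test_toml_round_trip(self, tmp_path):
        p = revised_s1_params(beta_w=-12.5, p=0.3)
        path = tmp_path / "params.toml"
        p.to_toml(str(path))
        assert NeuronParams.from_toml(str(path)) == p

    def test_unknown_key_rejected(self):
        with pytest.raises(InvalidParameterError, match="g_mystery"):
            NeuronParams.from_dict({"g_mystery": 1.0})

    def test_nspf_conversion(self):
        # 1 nS/pF == 1 mS/uF, so 2 nS/pF at C = 2 uF/cm^2 is 4 mS/cm^2
        p = default_params()
        assert p.density_from_nspf(2.0) == pytest.approx(4.0)
        assert p.current_from_papf(10.0) == pytest.approx(20.0)
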