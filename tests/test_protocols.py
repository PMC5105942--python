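"""Protocol tests: titration, kinetics comparison, virtual sodium,
rheobase, inhibition assays."""

import numpy as np
import pytest

from padsim.engine import classify_response, detect_spikes, simulate
from padsim.params import default_params as dp, resting_state
from padsim.protocols import (
    add_virtual_sodium,
    compare_kinetics,
    find_min_ggaba,
    inhibition_assay,
    rheobase,
)
from padsim.waveforms import (
    fast_synaptic,
    gaba_step,
    slow_synaptic,
    stimulus_window,
)


class TestTitration:
    def test_hyperpolarizing_input_never_spikes(self):
        # E_GABA below the trajectory: pure shunt, no excitation
        res = find_min_ggaba(dp(), fast_synaptic(1.0, E_rev=-70.0),
                             bounds=(0.0, 10.0))
        assert not res.found

    def test_excitable_cell_fast_threshold_below_2(self):
        # a transient-regime cell reachable by the 2 nS/pF fast waveform
        res = find_min_ggaba(
            dp().replace(beta_w=-10.0), fast_synaptic(1.0, E_rev=-15.0)
        )
        assert res.found
        assert res.min_g_bar <= 2.0

    def test_bracketing_invariant(self):
        params = dp().replace(beta_w=-10.0)
        stim = fast_synaptic(1.0, E_rev=-15.0)
        res = find_min_ggaba(params, stim, resolution=0.02)
        window = stimulus_window(stim)

        def spikes(g):
            tr = simulate(params, [stim.replace(g_bar=g)],
                          t_end=window[1] + 50.0)
            return detect_spikes(tr).in_window(window).n_spikes > 0

        assert spikes(res.min_g_bar)
        assert not spikes(res.min_g_bar - res.resolution)

    def test_4ap_analog_lowers_threshold(self):
        # shifting beta_w toward 0 (Kv1 block analog) always helps
        base = dp().replace(beta_w=-16.0)
        stim = fast_synaptic(1.0, E_rev=-15.0)
        r0 = find_min_ggaba(base, stim)
        r1 = find_min_ggaba(base.replace(beta_w=-6.0), stim)
        assert r0.found and r1.found
        assert r1.min_g_bar < r0.min_g_bar

    def test_depolarizing_e_shift_lowers_threshold(self):
        base = dp().replace(beta_w=-10.0)
        r35 = find_min_ggaba(base, fast_synaptic(1.0, E_rev=-20.0))
        r20 = find_min_ggaba(base, fast_synaptic(1.0, E_rev=-15.0))
        assert r35.found and r20.found
        assert r20.min_g_bar < r35.min_g_bar

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            find_min_ggaba(dp(), fast_synaptic(1.0), bounds=(5.0, 1.0))
        with pytest.raises(ValueError):
            find_min_ggaba(dp(), fast_synaptic(1.0), resolution=0.0)


class TestCompareKinetics:
    def test_transient_regime_is_rate_sensitive(self):
        ck = compare_kinetics(dp().replace(beta_w=-10.0), E_rev=-20.0)
        assert ck.rate_sensitive
        assert ck.min_slow > ck.min_fast
        # a ramp 2.5x stronger than the minimal step still fails
        assert ck.ramp_spikes is False

    def test_repetitive_regime_is_amplitude_sensitive(self):
        ck = compare_kinetics(dp().replace(beta_w=0.0), E_rev=-20.0)
        assert ck.regime == "repetitive"
        assert ck.rate_sensitive is False
        # slow and fast thresholds agree closely (slow never needs more)
        assert ck.min_slow <= ck.min_fast + ck.resolution
        assert abs(ck.min_slow - ck.min_fast) < 0.1 * ck.min_fast


class TestVirtualSodium:
    def test_zero_density_is_identity(self):
        p = dp()
        pv = add_virtual_sodium(p, 0.0)
        stim = gaba_step(2.0, E_rev=-20.0, t_on=20.0, duration=300.0)
        a = simulate(p, [stim], t_end=350.0)
        b = simulate(pv, [stim], t_end=350.0)
        np.testing.assert_array_equal(a.V, b.V)

    def test_spontaneous_spiking_develops(self):
        # switching the conductance on in a resting hyperexcitable cell
        p4 = dp().replace(beta_w=-10.0)
        rest = resting_state(p4)
        pv = add_virtual_sodium(p4, 0.5, beta_m=-55.0, gamma_m=10.0)
        tr = simulate(pv, [], t_end=1000.0, y0=rest)
        assert detect_spikes(tr).n_spikes > 10

    def test_hyperexcitable_cell_fires_repetitively_to_gaba(self):
        p4 = dp().replace(beta_w=-10.0)
        rest = resting_state(p4)
        pv = add_virtual_sodium(p4, 0.5, beta_m=-55.0, gamma_m=10.0)
        for stim, t_end in (
            (gaba_step(2.0, E_rev=-20.0, t_on=50.0), 1100.0),
            (slow_synaptic(2.0, E_rev=-20.0, t_on=50.0), 850.0),
        ):
            tr = simulate(pv, [stim], t_end=t_end, y0=rest)
            label = classify_response(
                detect_spikes(tr), stimulus_window(stim)
            ).label
            assert label == "repetitive"

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            add_virtual_sodium(dp(), -0.1)


class TestRheobase:
    def test_baseline_exists(self):
        rb = rheobase(dp(), g_bar=0.0)
        assert rb is not None
        assert rb > 0

    def test_shunt_raises_rheobase(self):
        p = dp().replace(p=1.0)
        r1 = rheobase(p, g_bar=1.0, E_rev=-35.0)
        r2 = rheobase(p, g_bar=2.0, E_rev=-35.0)
        assert r1 is not None and r2 is not None
        assert r2 > r1 > rheobase(p, g_bar=0.0)

    def test_unreachable_returns_none(self):
        # an overwhelming shunt: no spike up to the current bound
        p = dp().replace(p=1.0)
        assert rheobase(p, g_bar=20.0, E_rev=-35.0, bounds=(0.0, 30.0)) is None


@pytest.fixture(scope="module")
def params():
    return dp().replace(beta_w=0.0, p=1.0)


class TestInhibitionAssay:
    BASE = dict(i_amplitude=30.0)

    def test_without_gaba_firing_is_uniform(self, params):
        r = inhibition_assay(params, g_bar=0.0, E_rev=-35.0, **self.BASE)
        assert r.baseline_repetitive
        assert r.spikes_during > 0
        assert not r.inhibited_stopped
        # no shunt, no attenuation
        assert abs(r.mean_height_during - r.mean_height_outside) < 3.0

    def test_strong_gaba_silences_then_firing_resumes(self, params):
        r = inhibition_assay(params, g_bar=2.0, E_rev=-35.0, **self.BASE)
        assert r.inhibited_stopped
        assert r.spikes_during == 0
        assert r.spikes_after > 0  # firing resumes once the step ends

    def test_weak_gaba_attenuates_spike_height(self, params):
        r = inhibition_assay(params, g_bar=0.5, E_rev=-35.0, **self.BASE)
        assert r.spikes_during > 0
        assert r.mean_height_during < r.mean_height_outside - 3.0

    def test_coexistence_of_excitation_and_inhibition(self, params):
        # the same step fires its own spike(s) yet silences I-driven firing
        r = inhibition_assay(params, g_bar=2.0, E_rev=-20.0, **self.BASE)
        assert r.pad_spiking
        assert r.inhibited_stopped

    def test_g_before_i_ordering(self, params):
        r = inhibition_assay(
            params, g_bar=2.0, E_rev=-20.0, ordering="g-before-I",
            **self.BASE,
        )
        assert r.pad_spiking
        assert r.spikes_after > 0  # repetitive firing starts after g ends

    def test_unknown_ordering_rejected(self, params):
        with pytest.raises(ValueError):
            inhibition_assay(params, g_bar=1.0, E_rev=-35.0,
                             ordering="interleaved", **self.BASE)
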