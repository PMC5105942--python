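"""Engine tests: integration accuracy, spike detection, classification."""

import numpy as np
import pytest

from padsim.engine import (
    IntegrationError,
    SolverOptions,
    SpikeTrain,
    Trace,
    classify_response,
    detect_spikes,
    measure_depolarization,
    simulate,
)
from padsim.params import default_params as dp, resting_state
from padsim.waveforms import (
    fast_synaptic,
    gaba_step,
    slow_synaptic,
    stimulus_window,
)


def _synthetic_trace(t, V):
    z = np.zeros_like(t)
    return Trace(t=t, V=V, w=z, h=z, g_gaba=z, i_stim=z,
                 params=dp(), v_rest=-69.4)


class TestSimulate:
    def test_rest_is_stationary(self, default_params):
        tr = simulate(default_params, [], t_end=500.0)
        assert np.max(np.abs(tr.V - tr.v_rest)) < 0.5

    def test_point_b_depolarizes_without_spiking(self, default_params):
        stim = gaba_step(2.0, E_rev=-35.0, t_on=50.0)
        tr = simulate(default_params, [stim], t_end=1100.0)
        assert np.max(tr.V) > tr.v_rest + 10.0
        assert detect_spikes(tr).n_spikes == 0

    def test_strong_shunt_clamps_near_e_gaba(self, default_params):
        stim = gaba_step(20.0, E_rev=-35.0, t_on=50.0, duration=500.0)
        tr = simulate(default_params, [stim], t_end=600.0)
        sel = (tr.t > 300) & (tr.t < 550)
        assert np.max(np.abs(tr.V[sel] - (-35.0))) < 2.0

    def test_refinement_invariance(self, default_params):
        # a repetitively spiking trace: halving dt moves no sample by
        # 0.5 mV and changes no spike count
        p = default_params.replace(beta_w=-5.0)
        stim = gaba_step(2.0, E_rev=-10.0, t_on=50.0)
        a = simulate(p, [stim], t_end=1100.0)
        b = simulate(p, [stim], t_end=1100.0,
                     solver=SolverOptions(dt=0.005))
        assert np.max(np.abs(a.V - b.V)) < 0.5
        assert detect_spikes(a).n_spikes == detect_spikes(b).n_spikes

    def test_rk4_matches_lsoda(self, default_params):
        # independent integrator cross-check on a spiking trace
        p = default_params.replace(beta_w=-5.0)
        stim = gaba_step(2.0, E_rev=-10.0, t_on=50.0, duration=400.0)
        a = simulate(p, [stim], t_end=500.0)
        b = simulate(
            p, [stim], t_end=500.0,
            solver=SolverOptions(method="lsoda", rtol=1e-10, atol=1e-10),
        )
        assert detect_spikes(a).n_spikes == detect_spikes(b).n_spikes
        assert np.max(np.abs(a.V - b.V)) < 1.0

    def test_gating_stays_in_unit_box(self, default_params):
        p = default_params.replace(p=0.7)
        stim = gaba_step(4.0, E_rev=-10.0, t_on=20.0, duration=800.0)
        tr = simulate(p, [stim], t_end=900.0)
        for arr in (tr.w, tr.h):
            assert np.all(arr >= -1e-12)
            assert np.all(arr <= 1 + 1e-12)

    def test_inactivation_free_limit(self, default_params):
        # with p = 0 the h gate must not influence the trajectory at all
        stim = gaba_step(2.0, E_rev=-15.0, t_on=50.0, duration=400.0)
        a = simulate(default_params, [stim], t_end=500.0)
        b = simulate(
            default_params.replace(beta_h=-50.0, phi_h=0.1),
            [stim], t_end=500.0,
        )
        np.testing.assert_array_equal(a.V, b.V)

    def test_divergence_reports_time(self, default_params):
        p = default_params.replace(beta_w=-5.0)
        stim = gaba_step(2.0, E_rev=-10.0, t_on=10.0)
        with pytest.raises(IntegrationError, match="t ="):
            simulate(p, [stim], t_end=500.0,
                     solver=SolverOptions(dt=5.0, output_dt=5.0))

    def test_invalid_t_end(self, default_params):
        with pytest.raises(ValueError):
            simulate(default_params, [], t_end=-1.0)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        t = np.arange(0, 100, 0.05)
        tr = _synthetic_trace(t, np.full_like(t, -60.0))
        assert detect_spikes(tr).n_spikes == 0

    def test_three_separated_crossings(self):
        t = np.arange(0, 200, 0.05)
        V = np.full_like(t, -60.0)
        for t0 in (50.0, 100.0, 150.0):
            V += 90.0 * np.exp(-0.5 * ((t - t0) / 0.5) ** 2)
        tr = _synthetic_trace(t, V)
        spikes = detect_spikes(tr, refractory=2.0)
        assert spikes.n_spikes == 3
        assert np.all(np.diff(spikes.times) > 2.0)

    def test_refractory_merges_close_crossings(self):
        t = np.arange(0, 50, 0.05)
        V = np.full_like(t, -60.0)
        for t0 in (20.0, 21.0):  # 1 ms apart
            V += 90.0 * np.exp(-0.5 * ((t - t0) / 0.2) ** 2)
        tr = _synthetic_trace(t, V)
        assert detect_spikes(tr, refractory=2.0).n_spikes == 1

    def test_prominence_rejects_plateau(self):
        # slow drift across threshold without a spike-like upstroke
        t = np.arange(0, 300, 0.05)
        V = -60.0 + 65.0 * (1 - np.exp(-t / 50.0))
        tr = _synthetic_trace(t, V)
        assert detect_spikes(tr).n_spikes == 0


class TestClassifyResponse:
    def _train(self, times):
        times = np.asarray(times, dtype=float)
        return SpikeTrain(times=times, peaks=np.full_like(times, 20.0))

    def test_no_spikes_is_none(self):
        assert classify_response(self._train([]), (0, 1000)).label == "none"

    def test_single_onset_spike_is_transient(self):
        r = classify_response(self._train([10.0]), (0, 1000))
        assert r.label == "transient"
        assert r.n_spikes == 1

    def test_sustained_train_is_repetitive(self):
        r = classify_response(self._train(np.arange(20, 1000, 40)),
                              (0, 1000))
        assert r.label == "repetitive"

    def test_onset_burst_is_not_repetitive(self):
        # many spikes, all confined to the first 10% of the window
        r = classify_response(self._train([5, 15, 25, 35, 45]), (0, 1000))
        assert r.label == "transient"

    def test_spikes_outside_window_ignored(self):
        r = classify_response(self._train([1500.0]), (0, 1000))
        assert r.label == "none"


class TestMeasureDepolarization:
    def test_no_stimulus_near_zero(self, default_params):
        tr = simulate(default_params, [], t_end=300.0)
        d = measure_depolarization(tr, (100.0, 250.0))
        assert abs(d.value) < 0.2
        assert not d.contains_spikes

    def test_shunt_clamp_limit(self, default_params):
        # large conductance pulls depolarization toward E_GABA - V_rest
        stim = gaba_step(50.0, E_rev=-35.0, t_on=20.0, duration=400.0)
        tr = simulate(default_params, [stim], t_end=450.0)
        d = measure_depolarization(tr, (200.0, 400.0))
        ceiling = -35.0 - tr.v_rest
        assert d.value < ceiling
        assert d.value > ceiling - 1.0

    def test_monotone_in_g_bar_subthreshold(self, default_params):
        vals = []
        for g in (0.25, 0.5, 1.0, 2.0):
            stim = gaba_step(g, E_rev=-35.0, t_on=20.0, duration=400.0)
            tr = simulate(default_params, [stim], t_end=450.0)
            d = measure_depolarization(tr, (20.0, 420.0))
            assert not d.contains_spikes
            vals.append(d.value)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_spiking_window_flagged(self, default_params):
        p = default_params.replace(beta_w=-5.0)
        stim = gaba_step(2.0, E_rev=-10.0, t_on=20.0, duration=400.0)
        tr = simulate(p, [stim], t_end=450.0)
        assert measure_depolarization(tr, (20.0, 420.0)).contains_spikes


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path, default_params):
        import pandas as pd

        tr = simulate(default_params, [], t_end=10.0)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "V", "w", "h", "g_gaba", "i_stim"]
        np.testing.assert_allclose(df["V"].to_numpy(), tr.V)

    def test_grid_validation(self):
        t = np.array([0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            _synthetic_trace(t, np.zeros(3))
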