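"""In-silico analogs of the dynamic-clamp protocols.

These mirror what was done at the rig: titrate the minimum GABA conductance
density needed to make a cell fire, compare fast/slow/step/ramp onset
kinetics, add a virtual sodium conductance, measure rheobase while a GABA
shunt is active, and interleave g_GABA and I_stim steps to ask whether PAD
inhibits firing it did not itself cause.

The 4-AP analog — blocking Kv1-type channels to raise excitability — is a
shift of ``beta_w`` toward 0 mV (default +10 mV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .params import NeuronParams
from .waveforms import (
    ConductanceInput,
    CurrentInput,
    fast_synaptic,
    gaba_ramp,
    gaba_step,
    slow_synaptic,
    stimulus_window,
)
from .engine import (
    SolverOptions,
    classify_response,
    detect_spikes,
    simulate,
)

__all__ = [
    "TitrationResult",
    "find_min_ggaba",
    "KineticsComparison",
    "compare_kinetics",
    "add_virtual_sodium",
    "rheobase",
    "InhibitionAssayResult",
    "inhibition_assay",
    "DEFAULT_DELTA_BETA_W_4AP",
]

DEFAULT_DELTA_BETA_W_4AP = 10.0  # mV shift of beta_w toward 0


@dataclass
class TitrationResult:
    """Outcome of a minimum-g_GABA titration."""

    min_g_bar: Optional[float]       # nS/pF; None if upper bound fails
    resolution: float                # nS/pF
    tested: List[Tuple[float, str]]  # (g_bar, response label) pairs
    target: str
    monotone: bool                   # spiking set was an up-set where probed
    g_input: ConductanceInput
    params: NeuronParams

    @property
    def found(self) -> bool:
        return self.min_g_bar is not None


def _matches(label: str, target: str) -> bool:
    if target == "any":
        return label in ("transient", "repetitive")
    return label == target


def find_min_ggaba(
    params: NeuronParams,
    g_input: ConductanceInput,
    bounds: Tuple[float, float] = (0.0, 10.0),
    resolution: float = 0.01,
    target: str = "any",
    solver: Optional[SolverOptions] = None,
    pre_scan: int = 0,
    detect_kwargs: Optional[dict] = None,
) -> TitrationResult:
    """Bisect the peak conductance to the minimum eliciting the target
    response (``any`` spiking, ``transient``, or ``repetitive``).

    An optional coarse ``pre_scan`` (number of intermediate amplitudes)
    guards against non-monotone spiking versus g_bar — the region maps show
    spiking need not be monotone in g_bar — by bracketing the *first* onset;
    any non-up-set pattern seen is reported through ``monotone=False``.
    """
    lo, hi = bounds
    if not (hi > lo >= 0):
        raise ValueError("bounds must satisfy hi > lo >= 0")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    detect_kwargs = detect_kwargs or {}
    tested: List[Tuple[float, str]] = []
    window = stimulus_window(g_input)
    t_end = window[1] + 50.0

    def response(g_bar: float) -> str:
        stim = g_input.replace(g_bar=g_bar)
        trace = simulate(params, [stim], t_end=t_end, solver=solver)
        label = classify_response(
            detect_spikes(trace, **detect_kwargs), window
        ).label
        tested.append((g_bar, label))
        return label

    monotone = True
    if _matches(response(lo), target):
        return TitrationResult(lo, resolution, tested, target, monotone,
                               g_input, params)
    if not _matches(response(hi), target):
        # check interior once in case the target occurs only mid-range
        mid_label = response(0.5 * (lo + hi))
        if not _matches(mid_label, target):
            return TitrationResult(None, resolution, tested, target,
                                   monotone, g_input, params)
        monotone = False
        hi = 0.5 * (lo + hi)
    if pre_scan > 0:
        grid = np.linspace(lo, hi, pre_scan + 2)[1:-1]
        hits = [_matches(response(g), target) for g in grid]
        first = next((k for k, hit in enumerate(hits) if hit), None)
        if first is not None:
            if not all(hits[first:]):
                monotone = False
            hi = grid[first]
            if first > 0:
                lo = grid[first - 1]
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _matches(response(mid), target):
            hi = mid
        else:
            lo = mid
    return TitrationResult(hi, resolution, tested, target, monotone,
                           g_input, params)


@dataclass
class KineticsComparison:
    """Minimum g_GABA by onset kinetics, plus the step-vs-ramp challenge."""

    min_fast: Optional[float]
    min_slow: Optional[float]
    min_step: Optional[float]
    ramp_amplitude: Optional[float]      # 2.5x the step minimum
    ramp_spikes: Optional[bool]          # does that ramp elicit spiking?
    regime: str                          # response class of the step at min
    rate_sensitive: Optional[bool]       # slow needs more than fast?
    resolution: float
    E_rev: float


def compare_kinetics(
    params: NeuronParams,
    E_rev: float,
    bounds: Tuple[float, float] = (0.0, 10.0),
    resolution: float = 0.01,
    ramp_factor: float = 2.5,
    solver: Optional[SolverOptions] = None,
) -> KineticsComparison:
    """Titrate fast/slow synaptic waveforms and a step; then test whether a
    slow ramp at ``ramp_factor`` times the step minimum still fails.

    Transient-regime cells are rate-sensitive (slow > fast minimum);
    repetitive-regime cells care only about amplitude (slow == fast within
    one resolution step).
    """
    r_fast = find_min_ggaba(
        params, fast_synaptic(1.0, E_rev=E_rev), bounds, resolution,
        solver=solver,
    )
    r_slow = find_min_ggaba(
        params, slow_synaptic(1.0, E_rev=E_rev), bounds, resolution,
        solver=solver,
    )
    r_step = find_min_ggaba(
        params, gaba_step(1.0, E_rev=E_rev), bounds, resolution,
        solver=solver,
    )
    regime = "none"
    ramp_amplitude = None
    ramp_spikes = None
    if r_step.found:
        step = gaba_step(r_step.min_g_bar, E_rev=E_rev)
        win = stimulus_window(step)
        tr = simulate(params, [step], t_end=win[1] + 50.0, solver=solver)
        regime = classify_response(detect_spikes(tr), win).label
        ramp_amplitude = ramp_factor * r_step.min_g_bar
        ramp = gaba_ramp(ramp_amplitude, E_rev=E_rev)
        rwin = stimulus_window(ramp)
        tr = simulate(params, [ramp], t_end=rwin[1] + 50.0, solver=solver)
        ramp_spikes = detect_spikes(tr).in_window(rwin).n_spikes > 0
    rate_sensitive = None
    if r_fast.found and r_slow.found:
        rate_sensitive = (r_slow.min_g_bar - r_fast.min_g_bar) > resolution
    elif r_fast.found and not r_slow.found:
        rate_sensitive = True
    return KineticsComparison(
        min_fast=r_fast.min_g_bar,
        min_slow=r_slow.min_g_bar,
        min_step=r_step.min_g_bar,
        ramp_amplitude=ramp_amplitude,
        ramp_spikes=ramp_spikes,
        regime=regime,
        rate_sensitive=rate_sensitive,
        resolution=resolution,
        E_rev=E_rev,
    )


def add_virtual_sodium(
    params: NeuronParams,
    g_na_virtual: float,
    beta_m: Optional[float] = None,
    gamma_m: Optional[float] = None,
) -> NeuronParams:
    """Add a non-inactivating virtual sodium conductance (nS/pF).

    By default the virtual channel reuses the model's own instantaneous
    activation curve (beta_m, gamma_m) — a declared stand-in for the
    dynamic-clamp sodium conductance, whose published formulation is
    external to this package.  Its activation midpoint/slope can be
    overridden: a midpoint well below the intrinsic one (around -30 mV) is
    what lets a sub-nS/pF density destabilize rest into spontaneous firing,
    as the experimental manipulation did.  ``g_na_virtual = 0`` leaves the
    dynamics bit-identical.
    """
    if g_na_virtual < 0:
        raise ValueError("g_na_virtual must be nonnegative")
    changes = {"g_Na_virtual": params.g_Na_virtual + g_na_virtual}
    if beta_m is not None:
        changes["beta_m_virtual"] = beta_m
    if gamma_m is not None:
        changes["gamma_m_virtual"] = gamma_m
    return params.replace(**changes)


def rheobase(
    params: NeuronParams,
    g_bar: float = 0.0,
    E_rev: float = -35.0,
    bounds: Tuple[float, float] = (0.0, 60.0),
    resolution: float = 0.1,
    g_t_on: float = 100.0,
    g_duration: float = 600.0,
    i_t_on: float = 300.0,
    i_duration: float = 300.0,
    solver: Optional[SolverOptions] = None,
    detect_kwargs: Optional[dict] = None,
) -> Optional[float]:
    """Minimum I_stim step amplitude (pA/pF) evoking >= 1 spike while a
    g_GABA step is active.  Returns None when the upper bound stays
    subthreshold.  With ``g_bar = 0`` this is the baseline rheobase."""
    detect_kwargs = detect_kwargs or {}
    stims_g = (
        [gaba_step(g_bar, E_rev=E_rev, t_on=g_t_on, duration=g_duration)]
        if g_bar > 0 else []
    )
    i_win = (i_t_on, i_t_on + i_duration)
    t_end = max(i_win[1], g_t_on + g_duration) + 50.0

    def spikes_at(amp: float) -> bool:
        i_in = CurrentInput(amplitude=amp, t_on=i_t_on, duration=i_duration)
        tr = simulate(params, stims_g + [i_in], t_end=t_end, solver=solver)
        return detect_spikes(tr, **detect_kwargs).in_window(i_win).n_spikes > 0

    lo, hi = bounds
    if spikes_at(lo):
        return lo
    if not spikes_at(hi):
        return None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class InhibitionAssayResult:
    """Spike counts and heights around a g_GABA step riding on (or before)
    an I_stim step."""

    spikes_before: int
    spikes_during: int
    spikes_after: int
    mean_height_during: Optional[float]   # mV, spike peaks in the g window
    mean_height_outside: Optional[float]
    inhibited_stopped: bool               # no spikes in late overlap
    inhibited_reduced: bool               # >= 50% rate drop vs I alone
    baseline_repetitive: bool
    pad_spiking: bool                     # g step alone elicits spikes
    ordering: str
    g_input: ConductanceInput
    i_input: CurrentInput


def inhibition_assay(
    params: NeuronParams,
    g_bar: float,
    E_rev: float,
    i_amplitude: float,
    ordering: str = "g-within-I",
    solver: Optional[SolverOptions] = None,
    detect_kwargs: Optional[dict] = None,
    stop_tail_fraction: float = 0.5,
    reduce_factor: float = 0.5,
) -> InhibitionAssayResult:
    """Combined g_GABA / I_stim protocol.

    ``g-within-I``: a 1000 ms I_stim step with a 400 ms g_GABA step
    interposed 300 ms after current onset.  ``g-before-I``: the g step leads
    and overlaps the first 100 ms of the I step, so the same PAD that may
    fire a spike of its own is then asked to hold back the I-driven firing.
    """
    if ordering == "g-within-I":
        i_input = CurrentInput(amplitude=i_amplitude, t_on=100.0,
                               duration=1000.0)
        g_input = gaba_step(g_bar, E_rev=E_rev, t_on=400.0, duration=400.0)
    elif ordering == "g-before-I":
        g_input = gaba_step(g_bar, E_rev=E_rev, t_on=100.0, duration=400.0)
        i_input = CurrentInput(amplitude=i_amplitude, t_on=400.0,
                               duration=1000.0)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    detect_kwargs = detect_kwargs or {}
    g_win = stimulus_window(g_input)
    i_win = (i_input.t_on, i_input.t_on + i_input.duration)
    overlap = (max(g_win[0], i_win[0]), min(g_win[1], i_win[1]))
    t_end = max(g_win[1], i_win[1]) + 50.0

    tr_base = simulate(params, [i_input], t_end=t_end, solver=solver)
    spk_base = detect_spikes(tr_base, **detect_kwargs)
    baseline = classify_response(spk_base, i_win)

    tr_g = simulate(params, [g_input], t_end=t_end, solver=solver)
    pad_spiking = (
        detect_spikes(tr_g, **detect_kwargs).in_window(g_win).n_spikes > 0
    )

    tr = simulate(params, [g_input, i_input], t_end=t_end, solver=solver)
    spk = detect_spikes(tr, **detect_kwargs)
    in_g = (spk.times >= g_win[0]) & (spk.times <= g_win[1])
    before = int(np.sum(spk.times < g_win[0]))
    during = int(np.sum(in_g))
    after = int(np.sum(spk.times > g_win[1]))
    mh_in = float(np.mean(spk.peaks[in_g])) if during else None
    outside = ~in_g
    mh_out = float(np.mean(spk.peaks[outside])) if outside.any() else None
    late = (
        overlap[0] + (1 - stop_tail_fraction) * (overlap[1] - overlap[0]),
        overlap[1],
    )
    stopped = spk.in_window(late).n_spikes == 0
    n_overlap = spk.in_window(overlap).n_spikes
    n_base = spk_base.in_window(overlap).n_spikes
    reduced = n_overlap <= reduce_factor * n_base
    return InhibitionAssayResult(
        spikes_before=before,
        spikes_during=during,
        spikes_after=after,
        mean_height_during=mh_in,
        mean_height_outside=mh_out,
        inhibited_stopped=stopped and baseline.label == "repetitive",
        inhibited_reduced=reduced and baseline.label == "repetitive",
        baseline_repetitive=baseline.label == "repetitive",
        pad_spiking=pad_spiking,
        ordering=ordering,
        g_input=g_input,
        i_input=i_input,
    )
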