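"""Stimulus time courses: GABA_A conductance inputs and current steps.

Conductance inputs come in three kinds:

* ``step`` — instantaneous rise to ``g_bar``, held for ``duration``;
* ``ramp`` — linear rise 0 -> ``g_bar`` over ``ramp_rise_time`` then held for
  ``duration`` (the slow-onset challenge: ramps recruit the rate-sensitive
  spike-initiation mechanism far less effectively than steps);
* ``synaptic`` — normalized double exponential
  ``g(t) = g_bar * x * (exp(-t/tau_decay) - exp(-t/tau_rise))``, with ``x``
  chosen so the peak equals ``g_bar``.  The *fast* kinetics (2/20 ms) emulate
  phasic intrasynaptic GABA_A receptors, the *slow* kinetics (20/200 ms)
  emulate asynchronous activation of extrasynaptic receptors by spilled-over
  GABA.

Amplitudes are per-capacitance densities (nS/pF for conductance, pA/pF for
current), matching how dynamic-clamp experiments report them; the engine
converts to areal densities with the cell capacitance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace as _dc_replace
from typing import Optional

import numpy as np

__all__ = [
    "ConductanceInput",
    "CurrentInput",
    "normalization_factor",
    "peak_time",
    "conductance_at",
    "current_at",
    "gaba_step",
    "gaba_ramp",
    "fast_synaptic",
    "slow_synaptic",
    "current_step",
    "stimulus_window",
]

FAST_KINETICS = (2.0, 20.0)   # ms (tau_rise, tau_decay)
SLOW_KINETICS = (20.0, 200.0)  # ms


class InvalidKineticsError(ValueError):
    """Synaptic time constants must satisfy tau_decay > tau_rise > 0."""


def peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the double-exponential peak after onset.

    t* = ln(tau_decay/tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    """
    _check_kinetics(tau_rise, tau_decay)
    return (
        math.log(tau_decay / tau_rise)
        * tau_rise
        * tau_decay
        / (tau_decay - tau_rise)
    )


def normalization_factor(tau_rise: float, tau_decay: float) -> float:
    """Factor x that scales the double exponential to unit peak."""
    t_star = peak_time(tau_rise, tau_decay)
    peak = math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise)
    return 1.0 / peak


def _check_kinetics(tau_rise: float, tau_decay: float) -> None:
    if not (tau_decay > tau_rise > 0):
        raise InvalidKineticsError(
            f"need tau_decay > tau_rise > 0, got ({tau_rise}, {tau_decay})"
        )


@dataclass(frozen=True)
class ConductanceInput:
    """A GABA_A conductance stimulus."""

    kind: str                      # "step" | "ramp" | "synaptic"
    g_bar: float                   # peak density, nS/pF
    E_rev: float = -35.0           # E_GABA, mV
    tau_rise: float = 2.0          # ms, synaptic only
    tau_decay: float = 20.0        # ms, synaptic only
    t_on: float = 0.0              # ms
    duration: float = 1000.0       # ms hold (step/ramp)
    ramp_rise_time: float = 500.0  # ms, ramp only

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "synaptic"):
            raise ValueError(f"unknown conductance kind {self.kind!r}")
        if self.g_bar < 0:
            raise ValueError("g_bar must be nonnegative")
        if self.kind == "synaptic":
            _check_kinetics(self.tau_rise, self.tau_decay)
        if self.kind in ("step", "ramp") and self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "ramp" and self.ramp_rise_time <= 0:
            raise ValueError("ramp_rise_time must be positive")

    def replace(self, **changes) -> "ConductanceInput":
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def t_off(self) -> float:
        """End of the active window (synaptic: end of the 5%-of-peak tail)."""
        return stimulus_window(self)[1]


@dataclass(frozen=True)
class CurrentInput:
    """A rectangular injected-current step."""

    amplitude: float          # pA/pF
    t_on: float = 0.0         # ms
    duration: float = 1000.0  # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def replace(self, **changes) -> "CurrentInput":
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration


def conductance_at(t, inp: ConductanceInput):
    """Evaluate the conductance (nS/pF) at time(s) ``t`` (ms).  Total
    function: 0 outside the active window."""
    t = np.asarray(t, dtype=float)
    s = t - inp.t_on
    g = np.zeros_like(s)
    if inp.kind == "step":
        g = np.where((s >= 0) & (s <= inp.duration), inp.g_bar, 0.0)
    elif inp.kind == "ramp":
        rising = (s >= 0) & (s < inp.ramp_rise_time)
        holding = (s >= inp.ramp_rise_time) & (
            s <= inp.ramp_rise_time + inp.duration
        )
        g = np.where(rising, inp.g_bar * s / inp.ramp_rise_time, 0.0)
        g = np.where(holding, inp.g_bar, g)
    else:  # synaptic
        x = normalization_factor(inp.tau_rise, inp.tau_decay)
        active = s >= 0
        sa = np.where(active, s, 0.0)
        g = np.where(
            active,
            inp.g_bar * x * (np.exp(-sa / inp.tau_decay) - np.exp(-sa / inp.tau_rise)),
            0.0,
        )
        g = np.maximum(g, 0.0)
    return g if g.shape else float(g)


def current_at(t, inp: CurrentInput):
    """Evaluate the injected current (pA/pF) at time(s) ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    s = t - inp.t_on
    i = np.where((s >= 0) & (s <= inp.duration), inp.amplitude, 0.0)
    return i if i.shape else float(i)


def stimulus_window(inp, decay_fraction: float = 0.05) -> tuple:
    """(start, end) of the window used to classify the response.

    For steps and ramps this is the active window; for synaptic waveforms it
    runs from onset until the waveform has decayed below ``decay_fraction``
    of its peak.
    """
    if isinstance(inp, CurrentInput):
        return (inp.t_on, inp.t_on + inp.duration)
    if inp.kind == "step":
        return (inp.t_on, inp.t_on + inp.duration)
    if inp.kind == "ramp":
        return (inp.t_on, inp.t_on + inp.ramp_rise_time + inp.duration)
    # synaptic: solve x*(e^{-t/td} - e^{-t/tr}) = decay_fraction past the peak
    x = normalization_factor(inp.tau_rise, inp.tau_decay)
    t_star = peak_time(inp.tau_rise, inp.tau_decay)
    from scipy.optimize import brentq

    def f(s):
        return (
            x * (math.exp(-s / inp.tau_decay) - math.exp(-s / inp.tau_rise))
            - decay_fraction
        )

    hi = t_star
    while f(hi) > 0:
        hi *= 2.0
    s_end = brentq(f, t_star, hi, xtol=1e-9)
    return (inp.t_on, inp.t_on + s_end)


# -- convenience constructors -------------------------------------------------


def gaba_step(
    g_bar: float, E_rev: float = -35.0, t_on: float = 50.0,
    duration: float = 1000.0,
) -> ConductanceInput:
    return ConductanceInput(
        kind="step", g_bar=g_bar, E_rev=E_rev, t_on=t_on, duration=duration
    )


def gaba_ramp(
    g_bar: float, E_rev: float = -35.0, t_on: float = 50.0,
    ramp_rise_time: float = 500.0, duration: float = 500.0,
) -> ConductanceInput:
    return ConductanceInput(
        kind="ramp", g_bar=g_bar, E_rev=E_rev, t_on=t_on,
        duration=duration, ramp_rise_time=ramp_rise_time,
    )


def fast_synaptic(
    g_bar: float, E_rev: float = -35.0, t_on: float = 50.0
) -> ConductanceInput:
    tr, td = FAST_KINETICS
    return ConductanceInput(
        kind="synaptic", g_bar=g_bar, E_rev=E_rev,
        tau_rise=tr, tau_decay=td, t_on=t_on,
    )


def slow_synaptic(
    g_bar: float, E_rev: float = -35.0, t_on: float = 50.0
) -> ConductanceInput:
    tr, td = SLOW_KINETICS
    return ConductanceInput(
        kind="synaptic", g_bar=g_bar, E_rev=E_rev,
        tau_rise=tr, tau_decay=td, t_on=t_on,
    )


def current_step(
    amplitude: float, t_on: float = 50.0, duration: float = 1000.0
) -> CurrentInput:
    return CurrentInput(amplitude=amplitude, t_on=t_on, duration=duration)
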