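"""Simulation engine: integrate the membrane model under arbitrary stimuli,
detect spikes, and classify the response.

Responses are classified into three patterns:

* ``none`` — no spikes during the stimulus window;
* ``transient`` — spiking confined to stimulus onset (the rate-sensitive
  initiation mode typical of afferent somata);
* ``repetitive`` — sustained firing: at least ``min_spikes`` spikes with the
  last one falling in the final quarter of the stimulus window.

The default integrator is a fixed-step RK4 (numba kernel) on a 0.01 ms grid
with output subsampled to 0.05 ms for detection; an LSODA path through
scipy.integrate.solve_ivp is available as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .params import NeuronParams, StateVector, membrane_rhs, resting_state
from .waveforms import (
    ConductanceInput,
    CurrentInput,
    conductance_at,
    current_at,
    stimulus_window,
)
from ._integrators import rk4_single

__all__ = [
    "SolverOptions",
    "Trace",
    "SpikeTrain",
    "ResponseClass",
    "simulate",
    "detect_spikes",
    "classify_response",
    "classify_trace",
    "measure_depolarization",
    "IntegrationError",
]

StimulusLike = Union[ConductanceInput, CurrentInput]


class IntegrationError(RuntimeError):
    """The solver produced a non-finite state."""


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the fixed-grid integrator.

    ``dt`` is the internal RK4 step, ``output_dt`` the sampling period of the
    returned trace (must be an integer multiple of ``dt``).
    """

    dt: float = 0.01          # ms
    output_dt: float = 0.05   # ms
    method: str = "rk4"       # "rk4" | "lsoda"
    rtol: float = 1e-8        # lsoda only
    atol: float = 1e-8        # lsoda only

    def refined(self, factor: int = 2) -> "SolverOptions":
        return SolverOptions(
            dt=self.dt / factor,
            output_dt=self.output_dt,
            method=self.method,
            rtol=self.rtol / 10.0,
            atol=self.atol / 10.0,
        )


DEFAULT_SOLVER = SolverOptions()


@dataclass
class Trace:
    """A simulated time series on a uniform grid."""

    t: np.ndarray        # ms
    V: np.ndarray        # mV
    w: np.ndarray
    h: np.ndarray
    g_gaba: np.ndarray   # total applied conductance, nS/pF
    i_stim: np.ndarray   # applied current, pA/pF
    params: NeuronParams
    v_rest: float

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("V", "w", "h", "g_gaba", "i_stim"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name} length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "V": self.V,
                "w": self.w,
                "h": self.h,
                "g_gaba": self.g_gaba,
                "i_stim": self.i_stim,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spikes: threshold-crossing times and peak voltages."""

    times: np.ndarray   # ms, strictly increasing
    peaks: np.ndarray   # mV

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def in_window(self, window: tuple) -> "SpikeTrain":
        lo, hi = window
        sel = (self.times >= lo) & (self.times <= hi)
        return SpikeTrain(times=self.times[sel], peaks=self.peaks[sel])


@dataclass(frozen=True)
class ResponseClass:
    """none / transient / repetitive, with supporting counts."""

    label: str
    n_spikes: int
    spikes_in_onset_window: int

    def __str__(self) -> str:
        return self.label


# ---------------------------------------------------------------------------


def _sample_stimuli(
    stimuli: Sequence[StimulusLike],
    params: NeuronParams,
    t_half: np.ndarray,
):
    """Total conductance G(t) (mS/cm^2), conductance-weighted reversal sum
    sum_i g_i*E_i, and current I(t) (uA/cm^2) on the half-step grid."""
    g = np.zeros_like(t_half)
    ge = np.zeros_like(t_half)
    i = np.zeros_like(t_half)
    for stim in stimuli:
        if isinstance(stim, ConductanceInput):
            gi = conductance_at(t_half, stim) * params.C
            g += gi
            ge += gi * stim.E_rev
        elif isinstance(stim, CurrentInput):
            i += current_at(t_half, stim) * params.C
        else:
            raise TypeError(f"unknown stimulus type {type(stim)!r}")
    return g, ge, i


def simulate(
    params: NeuronParams,
    stimuli: Sequence[StimulusLike] = (),
    t_end: float = 1000.0,
    solver: Optional[SolverOptions] = None,
    y0: Optional[StateVector] = None,
) -> Trace:
    """Integrate the model from its resting state (or ``y0``) to ``t_end``.

    Raises :class:`IntegrationError` naming the failing time if the state
    goes non-finite.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    solver = solver or DEFAULT_SOLVER
    rest = resting_state(params)
    if y0 is None:
        y0 = rest
    if solver.method == "lsoda":
        return _simulate_lsoda(params, stimuli, t_end, solver, y0, rest.V)
    if solver.method != "rk4":
        raise ValueError(f"unknown solver method {solver.method!r}")

    stride = max(1, int(round(solver.output_dt / solver.dt)))
    dt = solver.output_dt / stride
    n_steps = int(np.ceil(t_end / solver.output_dt)) * stride
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    g_half, ge_half, i_half = _sample_stimuli(stimuli, params, t_half)
    V, w, h, status = rk4_single(
        params.to_array(), g_half, ge_half, i_half,
        dt, n_steps, y0.V, y0.w, y0.h, stride,
    )
    if status != 0:
        raise IntegrationError(
            f"non-finite state at t = {status * dt:.4f} ms"
        )
    t_out = np.arange(len(V)) * (dt * stride)
    g_out = g_half[:: 2 * stride] / params.C
    i_out = i_half[:: 2 * stride] / params.C
    return Trace(
        t=t_out, V=V, w=w, h=h, g_gaba=g_out, i_stim=i_out,
        params=params, v_rest=rest.V,
    )


def _simulate_lsoda(params, stimuli, t_end, solver, y0, v_rest) -> Trace:
    from scipy.integrate import solve_ivp

    cond = [s for s in stimuli if isinstance(s, ConductanceInput)]
    curr = [s for s in stimuli if isinstance(s, CurrentInput)]

    def rhs(t, y):
        g = 0.0
        ge = 0.0
        for c in cond:
            gi = conductance_at(t, c) * params.C
            g += gi
            ge += gi * c.E_rev
        i = sum(current_at(t, c) * params.C for c in curr)
        # fold sum g_i (V - E_i) into a single effective reversal
        e_eff = ge / g if g > 0 else 0.0
        return membrane_rhs(y, t, params, g_gaba=g, e_gaba=e_eff, i_stim=i)

    t_eval = np.arange(0.0, t_end + solver.output_dt / 2, solver.output_dt)
    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), y0.as_array(), method="LSODA",
        t_eval=t_eval, rtol=solver.rtol, atol=solver.atol, max_step=1.0,
    )
    if not sol.success:
        raise IntegrationError(f"LSODA failed: {sol.message}")
    g_out = np.zeros_like(sol.t)
    for c in cond:
        g_out = g_out + conductance_at(sol.t, c)
    i_out = np.zeros_like(sol.t)
    for c in curr:
        i_out = i_out + current_at(sol.t, c)
    return Trace(
        t=sol.t, V=sol.y[0], w=sol.y[1], h=sol.y[2],
        g_gaba=g_out, i_stim=i_out, params=params, v_rest=v_rest,
    )


# ---------------------------------------------------------------------------
# spike detection and response classification


def detect_spikes(
    trace: Trace,
    threshold: float = 0.0,
    refractory: float = 2.0,
    prominence: float = 20.0,
    baseline_window: float = 10.0,
) -> SpikeTrain:
    """One spike per upward threshold crossing, separated by >= refractory.

    A prominence criterion (peak at least ``prominence`` mV above the mean
    voltage over the ``baseline_window`` ms preceding the crossing) rejects
    slow plateau depolarizations that drift across threshold under strong
    shunting, where spike height is attenuated.
    """
    V = trace.V
    t = trace.t
    above = V >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    peaks = []
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    nb = max(1, int(round(baseline_window / dt)))
    last = -np.inf
    for idx in crossings:
        tc = t[idx]
        if tc - last < refractory:
            continue
        # peak: max V until it falls back below threshold (or trace end)
        j = idx
        while j + 1 < len(V) and V[j + 1] >= threshold:
            j += 1
        peak = float(np.max(V[idx : j + 1]))
        base = float(np.mean(V[max(0, idx - nb) : idx]))
        if peak - base < prominence:
            continue
        times.append(tc)
        peaks.append(peak)
        last = tc
    return SpikeTrain(times=np.asarray(times), peaks=np.asarray(peaks))


def classify_response(
    spikes: SpikeTrain,
    stim_window: tuple,
    min_spikes_repetitive: int = 3,
    tail_fraction: float = 0.25,
    onset_fraction: float = 0.25,
) -> ResponseClass:
    """Classify spiking within a stimulus window.

    ``none``: zero spikes in the window.  ``repetitive``: at least
    ``min_spikes_repetitive`` spikes and the last spike falls within the
    final ``tail_fraction`` of the window (firing sustained to stimulus
    end).  ``transient`` otherwise (spiking confined to onset).
    """
    lo, hi = stim_window
    if hi <= lo:
        raise ValueError("stimulus window must have positive length")
    inside = spikes.in_window(stim_window)
    n = inside.n_spikes
    onset_hi = lo + onset_fraction * (hi - lo)
    n_onset = int(np.sum(inside.times <= onset_hi))
    if n == 0:
        return ResponseClass("none", 0, 0)
    tail_lo = hi - tail_fraction * (hi - lo)
    if n >= min_spikes_repetitive and inside.times[-1] >= tail_lo:
        return ResponseClass("repetitive", n, n_onset)
    return ResponseClass("transient", n, n_onset)


def classify_trace(
    params: NeuronParams,
    stimulus: ConductanceInput,
    t_end: Optional[float] = None,
    solver: Optional[SolverOptions] = None,
    extra_stimuli: Sequence[StimulusLike] = (),
    **detect_kwargs,
) -> ResponseClass:
    """Simulate a single conductance input from rest and classify it."""
    window = stimulus_window(stimulus)
    if t_end is None:
        t_end = window[1] + 50.0
    trace = simulate(
        params, [stimulus, *extra_stimuli], t_end=t_end, solver=solver
    )
    spikes = detect_spikes(trace, **detect_kwargs)
    return classify_response(spikes, window)


@dataclass(frozen=True)
class Depolarization:
    """Peak depolarization over a window; flagged if spikes intrude."""

    value: float          # mV above rest
    contains_spikes: bool


def measure_depolarization(
    trace: Trace,
    window: tuple,
    **detect_kwargs,
) -> Depolarization:
    """max(V in window) - V_rest; flagged when the window contains spikes
    (depolarization of a spiking trace is ill-defined)."""
    lo, hi = window
    if lo < trace.t[0] or hi > trace.t[-1]:
        raise ValueError("window must lie inside the trace")
    sel = (trace.t >= lo) & (trace.t <= hi)
    value = float(np.max(trace.V[sel]) - trace.v_rest)
    spikes = detect_spikes(trace, **detect_kwargs).in_window(window)
    return Depolarization(value=value, contains_spikes=spikes.n_spikes > 0)
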