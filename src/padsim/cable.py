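"""Three-compartment unmyelinated-axon model of conduction block.

The axon is three 1 mm compartments of 1 um diameter in series, each
subdivided into equipotential segments by the d_lambda rule (segment length
at most ``d_lambda`` times the membrane space constant at 100 Hz).  Every
segment obeys the single-compartment membrane equations with gNa = gK =
30 mS/cm^2; neighbouring segments couple through the axial resistivity
R_a = 150 Ohm*cm.  Spikes are evoked by current pulses at the left end; the
GABA conductance is distributed uniformly over the middle compartment, so a
depolarized middle stretch can shunt and inactivate its way into blocking
the passing spike — or, with depolarized E_GABA, launch a spike of its own
in both directions.

Voltage is recorded at the midpoint of each compartment.  Integration is
Rush-Larsen gating plus a linearly implicit voltage step with a tridiagonal
(Thomas) solve, unconditionally stable in the axial-diffusion part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .params import NeuronParams, cable_membrane_params, resting_state
from .waveforms import ConductanceInput, CurrentInput, conductance_at
from .engine import SolverOptions, SpikeTrain, Trace, detect_spikes, IntegrationError
from ._integrators import cable_integrate

__all__ = [
    "CableParams",
    "Cable",
    "CableTrace",
    "ConductionResult",
    "build_cable",
    "simulate_cable",
    "threshold_current",
    "conduction_assay",
    "space_constant_um",
]


@dataclass(frozen=True)
class CableParams:
    """Geometry and membrane of the three-compartment axon."""

    n_compartments: int = 3
    compartment_length: float = 1.0   # mm
    diameter: float = 1.0             # um
    R_a: float = 150.0                # Ohm*cm
    membrane: NeuronParams = field(default_factory=cable_membrane_params)
    d_lambda: float = 0.01

    def __post_init__(self) -> None:
        if self.n_compartments < 1:
            raise ValueError("need at least one compartment")
        if min(self.compartment_length, self.diameter, self.R_a) <= 0:
            raise ValueError("geometry must be positive")
        if not 0 < self.d_lambda <= 1:
            raise ValueError("d_lambda must lie in (0, 1]")

    def replace(self, **changes) -> "CableParams":
        import dataclasses

        return dataclasses.replace(self, **changes)


def space_constant_um(params: CableParams, freq_hz: float = 100.0) -> float:
    """AC space constant at ``freq_hz`` (um), the d_lambda reference length:
    lambda_f = 1e5 * sqrt(diam / (4*pi*f*R_a*C_m))."""
    return 1e5 * math.sqrt(
        params.diameter
        / (4.0 * math.pi * freq_hz * params.R_a * params.membrane.C)
    )


@dataclass
class Cable:
    """Discretized cable: uniform chain of segments with midpoint markers."""

    params: CableParams
    nseg_per_compartment: int
    dx_um: float
    axial_coeff: float               # uA/cm^2 per mV between neighbours
    midpoint_segments: np.ndarray    # recording sites (one per compartment)
    gaba_mask: np.ndarray            # 1.0 on middle-compartment segments

    @property
    def n_segments(self) -> int:
        return self.nseg_per_compartment * self.params.n_compartments


def build_cable(params: CableParams) -> Cable:
    """Apply the d_lambda rule and precompute axial coupling.

    Segments per compartment: ``int((L/(d_lambda*lambda_100) + 0.9)/2)*2 + 1``
    (odd, so a midpoint segment exists), with a floor of 3.  Doubling R_a
    halves the axial coupling coefficient.
    """
    lam = space_constant_um(params)
    L_um = params.compartment_length * 1000.0
    nseg = int((L_um / (params.d_lambda * lam) + 0.9) / 2) * 2 + 1
    nseg = max(nseg, 3)
    dx_um = L_um / nseg
    dx_cm = dx_um * 1e-4
    d_cm = params.diameter * 1e-4
    # C dV/dt = (d/(4*R_a)) * d2V/dx2 + ...; factor 1e3 converts
    # mV/(Ohm*cm^2) to uA/cm^2
    axial = 1e3 * d_cm / (4.0 * params.R_a * dx_cm * dx_cm)
    n = nseg * params.n_compartments
    mids = np.array(
        [c * nseg + nseg // 2 for c in range(params.n_compartments)],
        dtype=np.int64,
    )
    mask = np.zeros(n)
    mid_comp = params.n_compartments // 2
    mask[mid_comp * nseg : (mid_comp + 1) * nseg] = 1.0
    return Cable(
        params=params,
        nseg_per_compartment=nseg,
        dx_um=dx_um,
        axial_coeff=axial,
        midpoint_segments=mids,
        gaba_mask=mask,
    )


@dataclass
class CableTrace:
    """Voltage at the three compartment midpoints (left, middle, right)."""

    t: np.ndarray
    V_mid: np.ndarray            # shape (n_compartments, n_t)
    cable: Cable
    v_rest: float

    def midpoint_trace(self, which: int) -> Trace:
        """View one midpoint as an engine Trace (for spike detection)."""
        n = len(self.t)
        z = np.zeros(n)
        return Trace(
            t=self.t, V=self.V_mid[which], w=z, h=z, g_gaba=z, i_stim=z,
            params=self.cable.params.membrane, v_rest=self.v_rest,
        )

    def to_dataframe(self):
        import pandas as pd

        frames = []
        for c in range(self.V_mid.shape[0]):
            seg = self.cable.midpoint_segments[c]
            frames.append(
                pd.DataFrame(
                    {
                        "t": self.t,
                        "compartment": c,
                        "position_mm": (seg + 0.5)
                        * self.cable.dx_um
                        / 1000.0,
                        "V": self.V_mid[c],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


DEFAULT_CABLE_SOLVER = SolverOptions(dt=0.005, output_dt=0.025)


def simulate_cable(
    cable: Cable,
    g_input: Optional[ConductanceInput] = None,
    pulses: Sequence[CurrentInput] = (),
    t_end: float = 100.0,
    solver: Optional[SolverOptions] = None,
    axial_scale: float = 1.0,
    inject_length_um: float = 100.0,
    theta: float = 0.5,
) -> CableTrace:
    """Integrate the cable.

    ``g_input`` (if any) is spread uniformly over the middle compartment at
    its per-capacitance density; current ``pulses`` inject uniformly over
    the leftmost ``inject_length_um`` of axon (a point electrode would be
    diluted into a ~1.6 um segment at the default discretization).
    ``axial_scale = 0`` decouples the segments (single-compartment limit
    used by the validation suite).
    """
    solver = solver or DEFAULT_CABLE_SOLVER
    pr = cable.params.membrane
    stride = max(1, int(round(solver.output_dt / solver.dt)))
    dt = solver.output_dt / stride
    n_steps = int(np.ceil(t_end / solver.output_dt)) * stride
    t_full = np.arange(n_steps + 1) * dt

    if g_input is not None:
        g_shape = conductance_at(t_full, g_input) * pr.C  # mS/cm^2
        e_gaba = g_input.E_rev
    else:
        g_shape = np.zeros_like(t_full)
        e_gaba = 0.0
    i_shape = np.zeros_like(t_full)
    for p in pulses:
        s = t_full - p.t_on
        i_shape += np.where(
            (s >= 0) & (s <= p.duration), p.amplitude * pr.C, 0.0
        )

    rest = resting_state(pr)
    n = cable.n_segments
    n_inj = max(1, int(round(inject_length_um / cable.dx_um)))
    i_mask = np.zeros(n)
    i_mask[:n_inj] = 1.0
    V0 = np.full(n, rest.V)
    w0 = np.full(n, rest.w)
    h0 = np.full(n, rest.h)
    V_rec, _, _, _, status = cable_integrate(
        pr.to_array(),
        cable.axial_coeff * axial_scale,
        cable.gaba_mask,
        e_gaba,
        g_shape,
        i_shape,
        i_mask,
        dt,
        n_steps,
        V0, w0, h0,
        stride,
        cable.midpoint_segments,
        theta,
    )
    if status != 0:
        raise IntegrationError(
            f"cable state non-finite at t = {status * dt:.4f} ms"
        )
    t_out = np.arange(V_rec.shape[1]) * (dt * stride)
    return CableTrace(t=t_out, V_mid=V_rec, cable=cable, v_rest=rest.V)


def threshold_current(
    cable: Cable,
    pulse_width: float = 1.0,
    bounds: Tuple[float, float] = (0.0, 400.0),
    resolution: float = 1.0,
    t_end: float = 20.0,
    solver: Optional[SolverOptions] = None,
) -> float:
    """Minimum 1 ms pulse amplitude (pA/pF) that fires the left midpoint."""

    def fires(amp: float) -> bool:
        tr = simulate_cable(
            cable,
            pulses=[CurrentInput(amplitude=amp, t_on=1.0,
                                 duration=pulse_width)],
            t_end=t_end, solver=solver,
        )
        return detect_spikes(tr.midpoint_trace(0)).n_spikes > 0

    lo, hi = bounds
    if not fires(hi):
        raise RuntimeError("upper bound does not fire the axon")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class PulseOutcome:
    """Fate of one evoked pulse."""

    t_pulse: float
    launched: bool                 # spike seen at left midpoint
    reached_middle: bool
    reached_right: bool
    latency_left: Optional[float]
    latency_right: Optional[float]


@dataclass
class ConductionResult:
    """Per-pulse propagation outcomes plus PAD-evoked spike bookkeeping."""

    pulses: List[PulseOutcome]
    pad_spike_times_mid: np.ndarray     # PAD-evoked spikes, middle midpoint
    pad_reaches_left: bool
    pad_reaches_right: bool
    ambiguous: bool                     # possible collision in attribution
    trace: CableTrace

    @property
    def n_propagated(self) -> int:
        return sum(p.reached_right for p in self.pulses)


def _match_times(candidates: np.ndarray, reference: np.ndarray,
                 tol: float) -> np.ndarray:
    """Mask of ``candidates`` lying within ``tol`` of any reference time."""
    if len(reference) == 0:
        return np.zeros(len(candidates), dtype=bool)
    d = np.min(np.abs(candidates[:, None] - reference[None, :]), axis=1)
    return d <= tol


def conduction_assay(
    cable: Cable,
    g_input: Optional[ConductanceInput],
    pulse_amplitude: float,
    pulse_times: Sequence[float],
    pulse_width: float = 1.0,
    t_end: Optional[float] = None,
    solver: Optional[SolverOptions] = None,
    window: float = 30.0,
    match_tol: float = 1.5,
) -> ConductionResult:
    """Evoke pulses at the left end under a PAD conductance and score
    propagation.

    Attribution is by a paired simulation: a GABA-only run identifies
    PAD-evoked spikes, and any midpoint spike in the combined run that
    matches a GABA-only spike time (within ``match_tol`` ms) is credited to
    PAD rather than to an evoked pulse.  Near-coincidences are flagged
    ``ambiguous`` rather than silently classified.
    """
    pulse_times = np.asarray(sorted(pulse_times), dtype=float)
    if t_end is None:
        t_end = float(pulse_times[-1]) + window + 10.0 if len(pulse_times) \
            else 100.0
        if g_input is not None:
            t_end = max(t_end, g_input.t_on + 60.0)
    pulses = [
        CurrentInput(amplitude=pulse_amplitude, t_on=tp,
                     duration=pulse_width)
        for tp in pulse_times
    ]
    # GABA-only reference run
    if g_input is not None:
        tr_g = simulate_cable(cable, g_input=g_input, t_end=t_end,
                              solver=solver)
        pad_left = detect_spikes(tr_g.midpoint_trace(0)).times
        pad_mid = detect_spikes(tr_g.midpoint_trace(1)).times
        pad_right = detect_spikes(tr_g.midpoint_trace(2)).times
    else:
        pad_left = pad_mid = pad_right = np.array([])

    tr = simulate_cable(cable, g_input=g_input, pulses=pulses, t_end=t_end,
                        solver=solver)
    spk_left = detect_spikes(tr.midpoint_trace(0)).times
    spk_mid = detect_spikes(tr.midpoint_trace(1)).times
    spk_right = detect_spikes(tr.midpoint_trace(2)).times

    is_pad_left = _match_times(spk_left, pad_left, match_tol)
    is_pad_mid = _match_times(spk_mid, pad_mid, match_tol)
    is_pad_right = _match_times(spk_right, pad_right, match_tol)

    ambiguous = False
    outcomes = []
    # greedy assignment: each non-PAD spike credits at most one pulse, in
    # pulse order, so overlapping windows (ISI shorter than the end-to-end
    # latency) do not double-count wavefronts
    used_left = is_pad_left.copy()
    used_mid = is_pad_mid.copy()
    used_right = is_pad_right.copy()

    def _claim(times: np.ndarray, used: np.ndarray, tp: float):
        sel = np.flatnonzero(
            (times >= tp) & (times <= tp + window) & ~used
        )
        if len(sel) == 0:
            return None
        used[sel[0]] = True
        return float(times[sel[0]])

    for tp in pulse_times:
        t_l = _claim(spk_left, used_left, tp)
        t_m = _claim(spk_mid, used_mid, tp)
        t_r = _claim(spk_right, used_right, tp)
        launched = t_l is not None
        # collision risk: a PAD spike close to (but outside match_tol of)
        # the evoked wavefront inside this window
        near_pad = _match_times(
            spk_mid[(spk_mid >= tp) & (spk_mid <= tp + window)],
            pad_mid, 3.0 * match_tol,
        )
        if near_pad.any() and t_m is not None:
            ambiguous = True
        outcomes.append(
            PulseOutcome(
                t_pulse=float(tp), launched=launched,
                reached_middle=t_m is not None,
                reached_right=t_r is not None,
                latency_left=(t_l - tp) if launched else None,
                latency_right=(t_r - tp) if t_r is not None else None,
            )
        )
    pad_times_obs = spk_mid[is_pad_mid]
    return ConductionResult(
        pulses=outcomes,
        pad_spike_times_mid=pad_times_obs,
        pad_reaches_left=bool(is_pad_left.any()),
        pad_reaches_right=bool(is_pad_right.any()),
        ambiguous=ambiguous,
        trace=tr,
    )
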