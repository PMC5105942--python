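"""Single-compartment membrane model of a primary afferent neuron.

The model is a Morris-Lecar-type conductance-based neuron with an
instantaneous sodium activation ``m``, a slow recovery variable ``w``
(aggregate low-threshold potassium / spike-repolarising current), an optional
sodium-inactivation variable ``h`` applied to a fraction ``p`` of the sodium
conductance, and a time-varying GABA_A chloride conductance whose reversal
potential ``E_GABA`` sits well above rest in primary afferents (chloride is
actively loaded by NKCC1, so GABA depolarises these cells).

State equations (voltage in mV, time in ms, densities in mS/cm^2, uA/cm^2,
uF/cm^2)::

    C dV/dt = I_stim - gNa*m_inf(V)*[(1-p) + p*h]*(V - E_Na)
                     - gK*w*(V - E_K) - g_leak*(V - E_leak)
                     - g_GABA(t)*(V - E_GABA) - gNa_virtual*m_inf(V)*(V - E_Na)
    dx/dt   = phi_x * (x_inf(V) - x) / tau_x(V)         for x in {w, h}
    x_inf(V) = 0.5*(1 + tanh((V - beta_x)/gamma_x))
    tau_x(V) = 1 / cosh((V - beta_x)/(2*gamma_x))

``beta_w`` is the excitability dial: shifting it toward 0 mV mimics the
hyperexcitability produced by Kv1 block (4-AP) or nerve injury.

Conductances quoted per-capacitance (nS/pF), as in dynamic-clamp work, are
converted to areal densities via ``g[mS/cm^2] = g[nS/pF] * C[uF/cm^2]``
(1 nS/pF == 1 mS/uF).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import IO, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NeuronParams",
    "StateVector",
    "gating_steady",
    "gating_tau",
    "membrane_rhs",
    "resting_state",
    "default_params",
    "revised_s1_params",
    "cable_membrane_params",
    "PRESETS",
]


class InvalidParameterError(ValueError):
    """A parameter violates a model invariant."""


class ConvergenceError(RuntimeError):
    """A root/fixed-point search failed to converge."""


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical parameters of the membrane model.

    Conductance densities are in mS/cm^2 except ``g_Na_virtual`` which is a
    dynamic-clamp-style per-capacitance density in nS/pF (converted
    internally).  ``p`` is the fraction of sodium channels subject to
    inactivation through ``h``; ``p = 0`` recovers the inactivation-free
    model exactly.
    """

    C: float = 2.0            # uF/cm^2
    g_Na_bar: float = 20.0    # mS/cm^2
    E_Na: float = 50.0        # mV
    beta_m: float = -1.2      # mV
    gamma_m: float = 18.0     # mV
    g_K_bar: float = 20.0     # mS/cm^2
    E_K: float = -100.0       # mV
    phi_w: float = 0.15
    beta_w: float = -20.0     # mV
    gamma_w: float = 10.0     # mV
    g_leak: float = 2.0       # mS/cm^2
    E_leak: float = -70.0     # mV
    p: float = 0.0            # fraction of Na channels that inactivate
    beta_h: float = -28.0     # mV
    gamma_h: float = -14.0    # mV (negative: h closes with depolarization)
    phi_h: float = 0.005
    g_Na_virtual: float = 0.0  # nS/pF (dynamic-clamp add-on, non-inactivating)
    # optional activation kinetics of the virtual channel; None inherits
    # (beta_m, gamma_m).  The dynamic-clamp conductance used experimentally
    # activated at more hyperpolarized voltages than the intrinsic current,
    # which is what lets it destabilize rest at sub-nS/pF densities.
    beta_m_virtual: float | None = None
    gamma_m_virtual: float | None = None

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise InvalidParameterError(f"C must be positive, got {self.C}")
        for name in ("g_Na_bar", "g_K_bar", "g_leak", "g_Na_virtual"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"{name} must be nonnegative, got {getattr(self, name)}"
                )
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError(f"p must lie in [0, 1], got {self.p}")
        if not self.gamma_m > 0:
            raise InvalidParameterError("gamma_m must be positive")
        if not self.gamma_w > 0:
            raise InvalidParameterError("gamma_w must be positive")
        if not self.gamma_h < 0:
            raise InvalidParameterError(
                "gamma_h must be negative so h closes with depolarization"
            )
        if self.gamma_m_virtual is not None and not self.gamma_m_virtual > 0:
            raise InvalidParameterError("gamma_m_virtual must be positive")

    def replace(self, **changes) -> "NeuronParams":
        return dataclasses.replace(self, **changes)

    # -- unit helpers -----------------------------------------------------
    def density_from_nspf(self, g_nspf: float) -> float:
        """Convert a per-capacitance density (nS/pF) to mS/cm^2."""
        return g_nspf * self.C

    def current_from_papf(self, i_papf: float) -> float:
        """Convert a per-capacitance current (pA/pF) to uA/cm^2."""
        return i_papf * self.C

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter key(s): {sorted(unknown)}"
            )
        return cls(**d)

    def to_toml(self, fp: Union[str, IO[str], None] = None) -> str:
        lines = [
            f"{k} = {v!r}"
            for k, v in self.to_dict().items()
            if v is not None
        ]
        text = "\n".join(lines) + "\n"
        if fp is not None:
            if isinstance(fp, str):
                with open(fp, "w") as fh:
                    fh.write(text)
            else:
                fp.write(text)
        return text

    @classmethod
    def from_toml(cls, src: Union[str, bytes]) -> "NeuronParams":
        import tomllib

        if isinstance(src, bytes):
            data = tomllib.loads(src.decode())
        elif "\n" in src or "=" in src:
            data = tomllib.loads(src)
        else:  # a path
            with open(src, "rb") as fh:
                data = tomllib.load(fh)
        return cls.from_dict(data)

    # packed layout used by the numba kernels; g_Na_virtual converted to
    # mS/cm^2 here so the kernels live entirely in areal units
    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.C,
                self.g_Na_bar,
                self.E_Na,
                self.beta_m,
                self.gamma_m,
                self.g_K_bar,
                self.E_K,
                self.phi_w,
                self.beta_w,
                self.gamma_w,
                self.g_leak,
                self.E_leak,
                self.p,
                self.beta_h,
                self.gamma_h,
                self.phi_h,
                self.density_from_nspf(self.g_Na_virtual),
                self.beta_m if self.beta_m_virtual is None
                else self.beta_m_virtual,
                self.gamma_m if self.gamma_m_virtual is None
                else self.gamma_m_virtual,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class StateVector:
    """Membrane state: voltage plus the two slow gating variables."""

    V: float  # mV
    w: float  # recovery gating, in [0, 1]
    h: float  # Na inactivation gating, in [0, 1]

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.w, self.h], dtype=np.float64)


# ---------------------------------------------------------------------------
# gating curves


def gating_steady(V, beta: float, gamma: float):
    """Steady-state activation 0.5*(1 + tanh((V - beta)/gamma)).

    Strictly monotone in V (increasing for gamma > 0, decreasing for
    gamma < 0), with open range (0, 1).
    """
    if gamma == 0:
        raise InvalidParameterError("gating slope gamma must be nonzero")
    return 0.5 * (1.0 + np.tanh((np.asarray(V, dtype=float) - beta) / gamma))


def gating_tau(V, beta: float, gamma: float):
    """Voltage-dependent time-constant factor 1/cosh((V - beta)/(2*gamma)).

    Even about ``V = beta`` where it attains its maximum of 1.  The rate of
    relaxation of gate x is ``phi_x / tau_x(V)``.
    """
    if gamma == 0:
        raise InvalidParameterError("gating slope gamma must be nonzero")
    return 1.0 / np.cosh((np.asarray(V, dtype=float) - beta) / (2.0 * gamma))


# ---------------------------------------------------------------------------
# right-hand side


def membrane_rhs(
    state,
    t: float,
    params: NeuronParams,
    g_gaba: float = 0.0,
    e_gaba: float = -35.0,
    i_stim: float = 0.0,
) -> np.ndarray:
    """Time derivative of (V, w, h).

    ``g_gaba`` is the instantaneous GABA_A conductance density in mS/cm^2
    (already converted from nS/pF), ``i_stim`` the injected current density
    in uA/cm^2.  With ``p = 0`` the inactivation gate ``h`` has no effect on
    dV/dt (it still relaxes toward h_inf so trajectories stay comparable).
    """
    V, w, h = float(state[0]), float(state[1]), float(state[2])
    if not (math.isfinite(V) and math.isfinite(w) and math.isfinite(h)):
        raise FloatingPointError(f"non-finite membrane state {state!r}")
    if not (math.isfinite(g_gaba) and math.isfinite(i_stim)):
        raise InvalidParameterError("stimulus values must be finite")
    pr = params
    m_inf = gating_steady(V, pr.beta_m, pr.gamma_m)
    na_open = (1.0 - pr.p) + pr.p * h
    g_nav = pr.density_from_nspf(pr.g_Na_virtual)
    bmv = pr.beta_m if pr.beta_m_virtual is None else pr.beta_m_virtual
    gmv = pr.gamma_m if pr.gamma_m_virtual is None else pr.gamma_m_virtual
    m_inf_v = gating_steady(V, bmv, gmv)
    i_na = (
        pr.g_Na_bar * na_open * m_inf + g_nav * m_inf_v
    ) * (V - pr.E_Na)
    i_k = pr.g_K_bar * w * (V - pr.E_K)
    i_leak = pr.g_leak * (V - pr.E_leak)
    i_gaba = g_gaba * (V - e_gaba)
    dV = (i_stim - i_na - i_k - i_leak - i_gaba) / pr.C
    w_inf = gating_steady(V, pr.beta_w, pr.gamma_w)
    dw = pr.phi_w * (w_inf - w) / gating_tau(V, pr.beta_w, pr.gamma_w)
    h_inf = gating_steady(V, pr.beta_h, pr.gamma_h)
    dh = pr.phi_h * (h_inf - h) / gating_tau(V, pr.beta_h, pr.gamma_h)
    return np.array([dV, dw, dh])


def resting_state(
    params: NeuronParams,
    v_bracket: tuple = (-100.0, 0.0),
    tol: float = 1e-12,
) -> StateVector:
    """Fixed point of the unstimulated membrane.

    Solves the 1-D steady-state current equation with ``w = w_inf(V)`` and
    ``h = h_inf(V)`` by bracketed root finding, then polishes with one Newton
    step.  For the default parameters the rest sits just above E_leak
    (V_rest ~ -69.4 mV) because sodium and potassium currents are nearly shut
    at -70 mV.
    """

    def steady_current(V: float) -> float:
        w = gating_steady(V, params.beta_w, params.gamma_w)
        h = gating_steady(V, params.beta_h, params.gamma_h)
        return float(
            membrane_rhs(np.array([V, w, h]), 0.0, params)[0]
        )

    lo, hi = v_bracket
    f_lo, f_hi = steady_current(lo), steady_current(hi)
    if f_lo == 0.0:
        v0 = lo
    elif f_hi == 0.0:
        v0 = hi
    elif f_lo * f_hi > 0:
        raise ConvergenceError(
            f"no resting fixed point bracketed in [{lo}, {hi}] mV"
        )
    else:
        v0 = brentq(steady_current, lo, hi, xtol=tol, rtol=8.9e-16)
    # one Newton polish to push |dV/dt| to solver noise
    eps = 1e-7
    f0 = steady_current(v0)
    df = (steady_current(v0 + eps) - steady_current(v0 - eps)) / (2 * eps)
    if df != 0:
        v0 = v0 - f0 / df
    return StateVector(
        V=v0,
        w=float(gating_steady(v0, params.beta_w, params.gamma_w)),
        h=float(gating_steady(v0, params.beta_h, params.gamma_h)),
    )


# ---------------------------------------------------------------------------
# presets


def default_params(**overrides) -> NeuronParams:
    """Baseline single-compartment model; beta_w = -20 mV is the normal
    excitability of an uninjured afferent."""
    return NeuronParams(**overrides)


def revised_s1_params(**overrides) -> NeuronParams:
    """Variant retuned to the higher GABA sensitivity seen in dissociated
    DRG somata: leak reduced to 0.7 mS/cm^2, gK raised to 30 mS/cm^2."""
    base = dict(g_leak=0.7, g_K_bar=30.0)
    base.update(overrides)
    return NeuronParams(**base)


def cable_membrane_params(**overrides) -> NeuronParams:
    """Membrane used in the multicompartment axon: gNa = gK = 30 mS/cm^2."""
    base = dict(g_Na_bar=30.0, g_K_bar=30.0)
    base.update(overrides)
    return NeuronParams(**base)


PRESETS = {
    "default": default_params,
    "revised-s1": revised_s1_params,
    "cable": cable_membrane_params,
}
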