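"""Two-parameter region maps of PAD effects.

A :class:`RegionMap` classifies the response to a GABA conductance input over
a rectangular grid of two parameters — typically (E_GABA, beta_w) for the
spiking maps and (E_GABA, p) for the inhibition maps.  Region borders are
extracted by scanning for adjacent opposite-class cells, optionally refined
by bisection along the first axis.  Everything here is deterministic: each
cell is simulated from rest with no state carry-over, and boundaries come
from grid sweeps rather than numerical continuation (validated by refinement
invariance in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np

from .params import NeuronParams
from .waveforms import (
    ConductanceInput,
    CurrentInput,
    stimulus_window,
)
from .engine import (
    SolverOptions,
    classify_response,
    detect_spikes,
    simulate,
)

__all__ = [
    "RegionMap",
    "BoundaryCurve",
    "sweep_spiking_2d",
    "sweep_inhibition_2d",
    "extract_boundary",
    "boundary_family",
    "ProtocolError",
    "SPIKING_LABELS",
]

SPIKING_LABELS = ("transient", "repetitive")


class ProtocolError(RuntimeError):
    """A sweep's precondition failed (e.g. baseline not repetitive)."""


def apply_axis(
    params: NeuronParams,
    g_input: Optional[ConductanceInput],
    name: str,
    value: float,
):
    """Set one swept parameter: either a NeuronParams field or the GABA
    reversal potential ``E_GABA`` on the conductance input."""
    if name in ("E_GABA", "E_rev"):
        if g_input is None:
            raise ValueError("E_GABA axis requires a conductance input")
        return params, g_input.replace(E_rev=value)
    if hasattr(params, name):
        return params.replace(**{name: value}), g_input
    raise ValueError(f"unrecognized axis parameter {name!r}")


@dataclass
class RegionMap:
    """Classification over a rectangular 2-D parameter grid.

    ``labels[i, j]`` is the response class at ``axis1_values[i]``,
    ``axis2_values[j]``.  Inhibition sweeps add boolean layers in ``flags``
    (``pad_spiking``, ``inhibited``, ``inhibited_reduced``,
    ``baseline_repetitive``).
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    labels: np.ndarray                  # shape (n1, n2), dtype str
    flags: Dict[str, np.ndarray] = field(default_factory=dict)
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n1, n2 = len(self.axis1_values), len(self.axis2_values)
        if self.labels.shape != (n1, n2):
            raise ValueError("labels grid shape mismatch")

    def membership(self, label: str) -> np.ndarray:
        """Boolean membership grid for a label, the union 'any-spiking',
        or a boolean flag layer."""
        if label == "any-spiking":
            return np.isin(self.labels, SPIKING_LABELS)
        if label in self.flags:
            return self.flags[label].astype(bool)
        return self.labels == label

    def to_dataframe(self):
        import pandas as pd

        a1, a2 = np.meshgrid(
            self.axis1_values, self.axis2_values, indexing="ij"
        )
        data = {
            self.axis1_name: a1.ravel(),
            self.axis2_name: a2.ravel(),
            "label": self.labels.ravel(),
        }
        for name, layer in self.flags.items():
            data[name] = layer.ravel()
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax=None):
        """Quick-look pseudocolor of the label grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = ["none", "transient", "repetitive"]
        z = np.searchsorted(np.array(order), self.labels)
        ax.pcolormesh(
            self.axis2_values, self.axis1_values, z,
            shading="nearest", cmap="Greys", vmin=0, vmax=2,
        )
        ax.set_xlabel(self.axis2_name)
        ax.set_ylabel(self.axis1_name)
        return ax


@dataclass
class BoundaryCurve:
    """Ordered boundary points between two response classes."""

    label: str
    points: np.ndarray          # shape (n, 2): (axis1, axis2) pairs
    resolution: float           # axis1 grid spacing at extraction
    axis1_name: str = ""
    axis2_name: str = ""

    @property
    def empty(self) -> bool:
        return len(self.points) == 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.points, columns=[self.axis1_name or "axis1",
                                  self.axis2_name or "axis2"]
        )


# ---------------------------------------------------------------------------


def _classify_cell(
    params: NeuronParams,
    g_input: ConductanceInput,
    solver: Optional[SolverOptions],
    detect_kwargs: dict,
) -> str:
    window = stimulus_window(g_input)
    try:
        trace = simulate(params, [g_input], t_end=window[1] + 50.0,
                         solver=solver)
    except Exception as exc:  # re-raise naming the cell
        raise RuntimeError(
            f"simulation failed at cell (E_rev={g_input.E_rev}, "
            f"beta_w={params.beta_w}, p={params.p}): {exc}"
        ) from exc
    spikes = detect_spikes(trace, **detect_kwargs)
    return classify_response(spikes, window).label


def sweep_spiking_2d(
    base: NeuronParams,
    g_input: ConductanceInput,
    axis1: tuple,
    axis2: tuple,
    solver: Optional[SolverOptions] = None,
    detect_kwargs: Optional[dict] = None,
) -> RegionMap:
    """Classify the response to ``g_input`` over a 2-D grid.

    ``axis1``/``axis2`` are ``(name, values)`` pairs; names are NeuronParams
    fields or ``"E_GABA"``.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    detect_kwargs = detect_kwargs or {}
    labels = np.empty((len(vals1), len(vals2)), dtype="<U16")
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            p, g = apply_axis(base, g_input, name1, v1)
            p, g = apply_axis(p, g, name2, v2)
            labels[i, j] = _classify_cell(p, g, solver, detect_kwargs)
    return RegionMap(
        axis1_name=name1, axis1_values=vals1,
        axis2_name=name2, axis2_values=vals2,
        labels=labels,
        context={"base": base.to_dict(), "g_input": g_input.to_dict()},
    )


def _inhibition_cell(
    params: NeuronParams,
    g_input: ConductanceInput,
    i_input: CurrentInput,
    solver,
    detect_kwargs: dict,
    stop_tail_fraction: float = 0.5,
    reduce_factor: float = 0.5,
):
    """Run the three simulations for one inhibition-map cell."""
    g_win = stimulus_window(g_input)
    i_win = (i_input.t_on, i_input.t_on + i_input.duration)
    overlap = (max(g_win[0], i_win[0]), min(g_win[1], i_win[1]))
    if overlap[1] <= overlap[0]:
        raise ProtocolError("g_GABA and I_stim windows do not overlap")
    t_end = max(g_win[1], i_win[1]) + 50.0

    # I_stim alone: the baseline repetitive firing PAD is asked to stop
    tr_base = simulate(params, [i_input], t_end=t_end, solver=solver)
    spk_base = detect_spikes(tr_base, **detect_kwargs)
    baseline = classify_response(spk_base, i_win)
    n_base_overlap = spk_base.in_window(overlap).n_spikes

    # g_GABA alone: does PAD initiate its own spikes?
    tr_g = simulate(params, [g_input], t_end=t_end, solver=solver)
    pad_spiking = (
        detect_spikes(tr_g, **detect_kwargs).in_window(g_win).n_spikes > 0
    )

    # combined
    tr_both = simulate(params, [g_input, i_input], t_end=t_end,
                       solver=solver)
    spk_both = detect_spikes(tr_both, **detect_kwargs)
    late_window = (
        overlap[0] + (1.0 - stop_tail_fraction) * (overlap[1] - overlap[0]),
        overlap[1],
    )
    stopped = spk_both.in_window(late_window).n_spikes == 0
    n_overlap = spk_both.in_window(overlap).n_spikes
    reduced = n_overlap <= reduce_factor * n_base_overlap
    return {
        "baseline_repetitive": baseline.label == "repetitive",
        "pad_spiking": pad_spiking,
        "inhibited": stopped and baseline.label == "repetitive",
        "inhibited_reduced": reduced and baseline.label == "repetitive",
    }


def sweep_inhibition_2d(
    base: NeuronParams,
    g_input: ConductanceInput,
    i_input: CurrentInput,
    axis1: tuple,
    axis2: tuple,
    solver: Optional[SolverOptions] = None,
    detect_kwargs: Optional[dict] = None,
) -> RegionMap:
    """Map PAD-induced spiking versus PAD-mediated inhibition.

    For each cell three simulations run from rest: I_stim alone (must
    produce repetitive spiking for the inhibition question to be posed),
    g_GABA alone (PAD-induced spiking), and both.  A cell is ``inhibited``
    when interposing the g_GABA step silences the I_stim-driven firing over
    the last half of the overlap window; ``inhibited_reduced`` applies the
    weaker >= 50% rate-drop criterion.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    detect_kwargs = detect_kwargs or {}

    # precondition: at the base parameters I_stim alone drives repetitive
    i_win = (i_input.t_on, i_input.t_on + i_input.duration)
    tr = simulate(base, [i_input], t_end=i_win[1] + 50.0, solver=solver)
    label = classify_response(
        detect_spikes(tr, **detect_kwargs), i_win
    ).label
    if label != "repetitive":
        raise ProtocolError(
            f"I_stim alone gives '{label}', not repetitive, at the base "
            "parameters; raise the amplitude or excitability"
        )

    labels = np.empty((len(vals1), len(vals2)), dtype="<U16")
    flags = {
        k: np.zeros((len(vals1), len(vals2)), dtype=bool)
        for k in (
            "baseline_repetitive", "pad_spiking",
            "inhibited", "inhibited_reduced",
        )
    }
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            p, g = apply_axis(base, g_input, name1, v1)
            p, g = apply_axis(p, g, name2, v2)
            cell = _inhibition_cell(p, g, i_input, solver, detect_kwargs)
            for k in flags:
                flags[k][i, j] = cell[k]
            labels[i, j] = (
                "inhibited" if cell["inhibited"] else
                ("pad-spiking" if cell["pad_spiking"] else "neither")
            )
    return RegionMap(
        axis1_name=name1, axis1_values=vals1,
        axis2_name=name2, axis2_values=vals2,
        labels=labels, flags=flags,
        context={
            "base": base.to_dict(),
            "g_input": g_input.to_dict(),
            "i_input": i_input.to_dict(),
        },
    )


# ---------------------------------------------------------------------------
# boundaries


def extract_boundary(
    region_map: RegionMap,
    label: str,
    refine_fn: Optional[Callable[[float, float], bool]] = None,
    tol: float = 0.25,
) -> BoundaryCurve:
    """Locate the border of ``label`` along axis1, one point per axis2
    column and crossing.

    Boundary points sit midway between adjacent opposite-class cells; with
    ``refine_fn(axis1_value, axis2_value) -> bool`` (membership test run by
    full simulation) each point is sharpened by bisection to ``tol``.
    Returns an empty (flagged) curve when the label is absent.
    """
    member = region_map.membership(label)
    vals1 = region_map.axis1_values
    vals2 = region_map.axis2_values
    if not member.any():
        return BoundaryCurve(
            label=label, points=np.empty((0, 2)),
            resolution=float(np.min(np.diff(vals1))) if len(vals1) > 1 else 0.0,
            axis1_name=region_map.axis1_name,
            axis2_name=region_map.axis2_name,
        )
    pts = []
    res = float(np.min(np.diff(vals1))) if len(vals1) > 1 else 0.0
    for j, v2 in enumerate(vals2):
        col = member[:, j]
        for i in range(len(vals1) - 1):
            if col[i] == col[i + 1]:
                continue
            lo, hi = vals1[i], vals1[i + 1]
            if refine_fn is not None:
                in_lo = bool(col[i])
                a, b = lo, hi
                while b - a > tol:
                    mid = 0.5 * (a + b)
                    if refine_fn(mid, v2) == in_lo:
                        a = mid
                    else:
                        b = mid
                pts.append((0.5 * (a + b), v2))
            else:
                pts.append((0.5 * (lo + hi), v2))
    return BoundaryCurve(
        label=label,
        points=np.array(pts) if pts else np.empty((0, 2)),
        resolution=res if refine_fn is None else tol,
        axis1_name=region_map.axis1_name,
        axis2_name=region_map.axis2_name,
    )


def boundary_family(
    base: NeuronParams,
    g_input: ConductanceInput,
    g_bars: Sequence[float],
    axis1: tuple,
    axis2: tuple,
    label: str,
    solver: Optional[SolverOptions] = None,
    sweep=sweep_spiking_2d,
    **sweep_kwargs,
):
    """One boundary per g_bar value, on shared axes.

    ``sweep`` may be :func:`sweep_spiking_2d` (default) or
    :func:`sweep_inhibition_2d` (pass ``i_input`` through ``sweep_kwargs``).
    Returns ``(maps, curves)`` lists aligned with ``g_bars``.
    """
    if len(g_bars) < 2:
        raise ValueError("need at least two g_bar values for a family")
    maps = []
    curves = []
    for gb in g_bars:
        m = sweep(
            base, g_input.replace(g_bar=gb), axis1=axis1, axis2=axis2,
            solver=solver, **sweep_kwargs,
        )
        maps.append(m)
        curves.append(extract_boundary(m, label))
    return maps, curves
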