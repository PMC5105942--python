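"""Synthetic virtual-neuron populations.

Dissociated DRG neurons are heterogeneous in intrinsic excitability; here a
population is a set of model neurons whose ``beta_w`` is drawn from a
truncated normal (default mean -20 mV, SD 4 mV, truncated to [-30, -5] mV,
spanning the region structure of the spiking maps), optionally with
lognormal jitter on g_leak and gK.  Each cell is then titrated for the
minimum GABA conductance that makes it fire under a matrix of conditions —
combinations of E_GABA, a 4-AP-analog shift of beta_w, and a virtual sodium
conductance — producing proportion-of-spiking-cells tables.

No claim is made that the default distribution matches the real DRG
excitability distribution; the qualitative orderings (depolarized E_GABA
and raised excitability each recruit more cells, their combination the
most) are the reproducible content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .params import NeuronParams, default_params, InvalidParameterError
from .waveforms import ConductanceInput, fast_synaptic
from .engine import SolverOptions
from .protocols import TitrationResult, find_min_ggaba

__all__ = [
    "Condition",
    "PopulationSpec",
    "PopulationResult",
    "sample_population",
    "run_population_protocol",
    "DEFAULT_CONDITIONS",
]


@dataclass(frozen=True)
class Condition:
    """One test condition: E_GABA, excitability shift, virtual Na add-on."""

    name: str
    E_GABA: float                 # mV
    delta_beta_w: float = 0.0     # mV (4-AP analog: toward 0)
    g_Na_virtual: float = 0.0     # nS/pF


# the four-condition matrix of the proportion-of-spiking-cells experiment:
# naive / 4-AP analog, each at normal and depolarized E_GABA
DEFAULT_CONDITIONS = (
    Condition("naive_E-35", E_GABA=-35.0),
    Condition("naive_E-20", E_GABA=-20.0),
    Condition("4AP_E-35", E_GABA=-35.0, delta_beta_w=10.0),
    Condition("4AP_E-20", E_GABA=-20.0, delta_beta_w=10.0),
)


@dataclass(frozen=True)
class PopulationSpec:
    """Definition of a virtual population and its condition matrix."""

    n: int = 30
    beta_w_mean: float = -20.0
    beta_w_sd: float = 4.0
    beta_w_bounds: Tuple[float, float] = (-30.0, -5.0)
    g_leak_sigma: float = 0.0     # lognormal sigma for a g_leak multiplier
    g_K_sigma: float = 0.0        # lognormal sigma for a gK multiplier
    conditions: Tuple[Condition, ...] = DEFAULT_CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.beta_w_sd < 0 or self.g_leak_sigma < 0 or self.g_K_sigma < 0:
            raise ValueError("spread parameters must be nonnegative")
        lo, hi = self.beta_w_bounds
        if not lo < hi:
            raise ValueError("beta_w_bounds must be ordered")


class DistributionError(RuntimeError):
    """Sampling kept violating parameter invariants."""


def sample_population(
    spec: PopulationSpec,
    base: Optional[NeuronParams] = None,
) -> List[NeuronParams]:
    """Draw ``spec.n`` parameter sets, deterministic given ``spec.seed``.

    beta_w is sampled by rejection from the truncated normal; draws that
    violate any NeuronParams invariant are resampled, erroring out after
    10 * n total draws (a misspecified distribution, not bad luck).
    """
    base = base or default_params()
    rng = np.random.default_rng(spec.seed)
    cells: List[NeuronParams] = []
    draws = 0
    lo, hi = spec.beta_w_bounds
    while len(cells) < spec.n:
        if draws > 10 * spec.n + 10:
            raise DistributionError(
                f"exceeded {10 * spec.n} draws while sampling {spec.n} "
                "valid cells; check the distribution specification"
            )
        draws += 1
        bw = rng.normal(spec.beta_w_mean, spec.beta_w_sd) \
            if spec.beta_w_sd > 0 else spec.beta_w_mean
        if not lo <= bw <= hi:
            continue
        gl_mult = (
            float(np.exp(rng.normal(0.0, spec.g_leak_sigma)))
            if spec.g_leak_sigma > 0 else 1.0
        )
        gk_mult = (
            float(np.exp(rng.normal(0.0, spec.g_K_sigma)))
            if spec.g_K_sigma > 0 else 1.0
        )
        try:
            cells.append(
                base.replace(
                    beta_w=float(bw),
                    g_leak=base.g_leak * gl_mult,
                    g_K_bar=base.g_K_bar * gk_mult,
                )
            )
        except InvalidParameterError:
            continue
    return cells


@dataclass
class CellOutcome:
    """Per-cell, per-condition titration outcome."""

    cell_id: int
    condition: str
    beta_w: float
    min_g_bar: Optional[float]
    label_at_min: str
    error: Optional[str] = None


@dataclass
class PopulationResult:
    """Spiking proportions per condition plus per-cell records."""

    spec: PopulationSpec
    outcomes: List[CellOutcome]
    proportions: dict                 # condition name -> fraction spiking
    cells: List[NeuronParams]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([asdict(o) for o in self.outcomes])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n": self.spec.n,
            "seed": self.spec.seed,
            "proportions": dict(self.proportions),
        }


def run_population_protocol(
    cells: Sequence[NeuronParams],
    spec: PopulationSpec,
    template: Optional[ConductanceInput] = None,
    bounds: Tuple[float, float] = (0.0, 10.0),
    resolution: float = 0.05,
    solver: Optional[SolverOptions] = None,
) -> PopulationResult:
    """Titrate every cell under every condition.

    A cell counts as spiking in a condition when a minimum g_GABA within
    ``bounds`` is found.  Per-cell failures are recorded in the outcome
    (``error`` field), never fatal to the batch.
    """
    template = template or fast_synaptic(1.0)
    outcomes: List[CellOutcome] = []
    for cid, cell in enumerate(cells):
        for cond in spec.conditions:
            try:
                p = cell.replace(
                    beta_w=cell.beta_w + cond.delta_beta_w,
                    g_Na_virtual=cell.g_Na_virtual + cond.g_Na_virtual,
                )
                res: TitrationResult = find_min_ggaba(
                    p, template.replace(E_rev=cond.E_GABA),
                    bounds=bounds, resolution=resolution, solver=solver,
                )
                label = "none"
                if res.found:
                    # label recorded at the titrated minimum
                    for g, lab in reversed(res.tested):
                        if abs(g - res.min_g_bar) < 1e-12:
                            label = lab
                            break
                outcomes.append(
                    CellOutcome(
                        cell_id=cid, condition=cond.name,
                        beta_w=cell.beta_w, min_g_bar=res.min_g_bar,
                        label_at_min=label,
                    )
                )
            except Exception as exc:
                outcomes.append(
                    CellOutcome(
                        cell_id=cid, condition=cond.name,
                        beta_w=cell.beta_w, min_g_bar=None,
                        label_at_min="error", error=str(exc),
                    )
                )
    proportions = {}
    for cond in spec.conditions:
        hits = [
            o.min_g_bar is not None
            for o in outcomes
            if o.condition == cond.name and o.error is None
        ]
        proportions[cond.name] = float(np.mean(hits)) if hits else float("nan")
    return PopulationResult(
        spec=spec, outcomes=outcomes, proportions=proportions,
        cells=list(cells),
    )
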