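"""Discounted QALY and cost accrual, iNMB and strategy comparison.

QALYs multiply each cycle's state occupancy by the per-state annual
utility weight and the quarter-year cycle length, discounted at the
effects rate (1.5%/year by default).  Costs follow the three-phase
schedule: the one-off 0-3 month block is charged undiscounted at entry
(together with the surgical cost in the MIS arm), the quarterly 3-12
month costs at the 6/9/12-month cycles, and the long-term quarterly costs
thereafter, discounted at the costs rate (4%/year).  Time zero is model
entry and accrual uses cycle-start membership; an optional half-cycle
correction (off by default) down-weights the first and last cycle by one
half.

Strategies are compared by the incremental net monetary benefit
iNMB = WTP * dQALYs - dCosts; iNMB >= 0 means the new strategy is
cost-effective at that willingness-to-pay.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .inputs_io import (
    MRS_DEAD,
    N_STATES,
    CostPhaseSet,
    EconSettings,
    ModelInputs,
    UtilitySet,
    counts_to_row_stochastic,
)
from .markov import CohortTrace, run_trace
from .strategies import MisStrategySpec, apply_mis_effect


def discount_factor(t: float, rate: float) -> float:
    """Discrete annual discounting: (1 + rate)^(-t) for t in years."""
    if t < 0 or rate < 0:
        raise ValueError("time and rate must be non-negative")
    return float((1.0 + rate) ** (-t))


def _cycle_weights(n: int, half_cycle_correction: bool) -> np.ndarray:
    w = np.ones(n)
    if half_cycle_correction and n > 1:
        w[0] = 0.5
        w[-1] = 0.5
    return w


def accrue_qalys(trace: CohortTrace, utilities: UtilitySet, econ: EconSettings) -> float:
    """Discounted QALYs accrued over a cohort trace."""
    t = trace.years_since_entry
    df = (1.0 + econ.discount_rate_effects) ** (-t)
    w = _cycle_weights(trace.n_cycles, econ.half_cycle_correction)
    per_cycle = trace.distributions @ utilities.mean
    return float(np.sum(w * per_cycle * econ.cycle_length * df))


def accrue_costs(trace: CohortTrace, costs: CostPhaseSet, surgical_cost: float,
                 econ: EconSettings) -> float:
    """Discounted costs over a cohort trace, following the phase schedule.

    Cycle 0 charges the one-off 0-3 month block (plus any surgical cost),
    undiscounted; cycles 1-3 charge the quarterly 3-12 month costs and
    later cycles the long-term quarterly costs, both discounted.
    """
    total = float(trace.distributions[0] @ costs.phase(1)) + surgical_cost
    t = trace.years_since_entry
    df = (1.0 + econ.discount_rate_costs) ** (-t)
    w = _cycle_weights(trace.n_cycles, econ.half_cycle_correction)
    for k in range(1, trace.n_cycles):
        phase = costs.phase(2) if k <= 3 else costs.phase(3)
        total += w[k] * float(trace.distributions[k] @ phase) * df[k]
    return total


def compute_inmb(delta_qalys: float, delta_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dQALYs - dCosts."""
    return wtp * delta_qalys - delta_cost


@dataclass(frozen=True)
class StrategyOutcome:
    qalys: float
    cost: float
    trace: CohortTrace | None = None


@dataclass(frozen=True)
class CeaResult:
    usual_care: StrategyOutcome
    mis: StrategyOutcome
    delta_qalys: float
    delta_cost: float
    inmb: float
    icer: float | None
    wtp: float

    @property
    def dominant(self) -> str | None:
        """Dominance label: 'mis' dominates, 'usual_care' dominates, or None."""
        if self.delta_qalys > 0 and self.delta_cost < 0:
            return "mis"
        if self.delta_qalys < 0 and self.delta_cost > 0:
            return "usual_care"
        return None


def evaluate_strategy(initial: np.ndarray, inputs: ModelInputs, surgical_cost: float = 0.0,
                      matrices: tuple[np.ndarray, np.ndarray] | None = None,
                      keep_trace: bool = True) -> StrategyOutcome:
    """Run one arm's trace and accrue its discounted outcomes."""
    trace = run_trace(initial, inputs, matrices=matrices)
    return StrategyOutcome(
        qalys=accrue_qalys(trace, inputs.utilities, inputs.econ),
        cost=accrue_costs(trace, inputs.costs, surgical_cost, inputs.econ),
        trace=trace if keep_trace else None,
    )


def run_cea(inputs: ModelInputs, mis: MisStrategySpec,
            initial: np.ndarray | None = None,
            matrices: tuple[np.ndarray, np.ndarray] | None = None,
            keep_traces: bool = True) -> CeaResult:
    """Full comparison of MIS vs. usual care on one set of inputs.

    ``initial`` defaults to the cohort's observed distribution (the usual
    care arm); the MIS arm redistributes it per the strategy spec and adds
    the surgical cost at entry.
    """
    if initial is None:
        initial = inputs.cohort.distribution()
    if matrices is None:
        matrices = counts_to_row_stochastic(inputs.transitions)
    uc = evaluate_strategy(initial, inputs, 0.0, matrices, keep_traces)
    mis_dist = apply_mis_effect(initial, mis)
    ms = evaluate_strategy(mis_dist, inputs, mis.surgical_cost, matrices, keep_traces)
    dq = ms.qalys - uc.qalys
    dc = ms.cost - uc.cost
    return CeaResult(
        usual_care=uc, mis=ms, delta_qalys=dq, delta_cost=dc,
        inmb=compute_inmb(dq, dc, inputs.econ.wtp),
        icer=(dc / dq) if dq != 0.0 else None,
        wtp=inputs.econ.wtp,
    )


def per_state_outcomes(inputs: ModelInputs,
                       matrices: tuple[np.ndarray, np.ndarray] | None = None,
                       entry_age: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Discounted (QALYs, non-surgical costs) per unit of entry occupancy.

    Because the cohort model is linear in its entry distribution, any
    arm's outcome is the dot product of its entry occupancy with these
    vectors (plus any surgical cost).  The unit traces are run without the
    survival-epsilon stop so the decomposition is exact.
    """
    if matrices is None:
        matrices = counts_to_row_stochastic(inputs.transitions)
    noeps = dataclasses.replace(inputs, econ=dataclasses.replace(inputs.econ, survival_epsilon=0.0))
    q = np.zeros(N_STATES)
    c = np.zeros(N_STATES)
    for s in range(N_STATES):
        e = np.zeros(N_STATES)
        e[s] = 1.0
        trace = run_trace(e, noeps, matrices=matrices, entry_age=entry_age)
        q[s] = accrue_qalys(trace, inputs.utilities, inputs.econ)
        c[s] = accrue_costs(trace, inputs.costs, 0.0, inputs.econ)
    return q, c
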