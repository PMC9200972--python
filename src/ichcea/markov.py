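"""Quarterly-cycle Markov cohort engine.

A cohort enters the model 3 months after the index hemorrhage, distributed
over the seven mRS states, at the cohort's mean age.  Within the first
year the empirical transition matrices move patients between states: the
phase-A matrix covers 3->6 months and the phase-B matrix is applied at the
6->9 and 9->12 month steps.  Beyond one year the mRS state is assumed
stable for the remaining lifetime: each cycle a patient either stays put
or dies, with a quarterly death probability built from the life table's
annual risk at the patient's current (floored) age, scaled on the hazard
scale by the state-specific excess-mortality ratio.

Within the first year the empirical matrices are the sole source of
mortality (their death columns contain the observed deaths); background
mortality is not added on top of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inputs_io import (
    MRS_DEAD,
    N_STATES,
    ExcessMortality,
    LifeTable,
    ModelInputs,
    counts_to_row_stochastic,
)

ENTRY_MONTHS_POST_ICH = 3.0


@dataclass(frozen=True)
class CohortTrace:
    """The cohort's state occupancy at the start of every model cycle."""

    years_since_entry: np.ndarray
    age: np.ndarray
    distributions: np.ndarray  # shape (n_cycles, 7)

    @property
    def n_cycles(self) -> int:
        return len(self.years_since_entry)

    @property
    def months_post_ich(self) -> np.ndarray:
        return ENTRY_MONTHS_POST_ICH + 12.0 * self.years_since_entry

    @property
    def alive_mass(self) -> np.ndarray:
        return 1.0 - self.distributions[:, MRS_DEAD]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.distributions, columns=[f"mrs{s}" for s in range(N_STATES)])
        df.insert(0, "cycle", np.arange(self.n_cycles))
        df.insert(1, "years_since_entry", self.years_since_entry)
        df.insert(2, "months_post_ich", self.months_post_ich)
        df.insert(3, "age", self.age)
        df["alive_mass"] = self.alive_mass
        return df


def validate_distribution(dist: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_STATES,):
        raise ValueError("state distribution must have exactly 7 entries")
    if np.any(dist < -tol) or abs(dist.sum() - 1.0) > tol:
        raise ValueError("state distribution must be non-negative and sum to 1")
    return np.clip(dist, 0.0, None)


def annual_to_cycle_death_prob(q_annual: float, hr: float, cycle_length: float = 0.25) -> float:
    """Quarterly death probability from an annual one, scaled by a hazard ratio.

    The annual probability is converted to a hazard h = -ln(1 - q),
    multiplied by ``hr`` and converted back over one cycle:
    ``1 - exp(-hr * h * cycle_length)``.  Working on the hazard scale keeps
    the result a valid probability for any non-negative hazard ratio.
    ``q_annual = 1`` (the life table's terminal age) maps to 1.
    """
    if not 0.0 <= q_annual <= 1.0:
        raise ValueError("q_annual must lie in [0, 1]")
    if hr < 0:
        raise ValueError("hazard ratio must be non-negative")
    if q_annual >= 1.0:
        return 1.0
    h = -np.log1p(-q_annual)
    return float(-np.expm1(-hr * h * cycle_length))


def long_term_matrix(age: float, life_table: LifeTable, excess: ExcessMortality,
                     cycle_length: float = 0.25) -> np.ndarray:
    """One-cycle matrix for the stable long-term phase (stay or die).

    No movement between alive mRS states occurs; each alive state ``s``
    sends ``annual_to_cycle_death_prob(q(age), hr_s)`` to mRS 6 and retains
    the remainder. Ages beyond the table clamp to the terminal record.
    """
    q = life_table.q(age)
    m = np.zeros((N_STATES, N_STATES))
    for s in range(MRS_DEAD):
        p_die = annual_to_cycle_death_prob(q, float(excess.hr[s]), cycle_length)
        m[s, s] = 1.0 - p_die
        m[s, MRS_DEAD] = p_die
    m[MRS_DEAD, MRS_DEAD] = 1.0
    return m


def cycle_matrix(cycle: int, entry_age: float, inputs: ModelInputs,
                 matrices: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Transition matrix producing the distribution at ``cycle`` (>= 1).

    Cycle 1 applies phase A, cycles 2-3 phase B, later cycles the long-term
    stay-or-die matrix evaluated at the age at the start of the interval.
    ``matrices`` overrides the first-year matrices (used when they are
    sampled rather than derived from counts).
    """
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    if matrices is None:
        matrices = counts_to_row_stochastic(inputs.transitions)
    phase_a, phase_b = matrices
    if cycle == 1:
        return phase_a
    if cycle in (2, 3):
        return phase_b
    dt = inputs.econ.cycle_length
    return long_term_matrix(entry_age + dt * (cycle - 1), inputs.life_table,
                            inputs.excess, dt)


def run_trace(initial: np.ndarray, inputs: ModelInputs,
              matrices: tuple[np.ndarray, np.ndarray] | None = None,
              entry_age: float | None = None) -> CohortTrace:
    """Propagate a cohort from model entry until extinction or max age.

    Cycle 0 is the entry distribution (3 months post-ICH, at the cohort's
    mean age); the trace stops once the surviving mass falls below
    ``econ.survival_epsilon`` or age reaches ``econ.max_age``.
    """
    dist = validate_distribution(initial)
    if entry_age is None:
        entry_age = inputs.cohort.mean_entry_age
    if matrices is None:
        matrices = counts_to_row_stochastic(inputs.transitions)
    econ = inputs.econ
    dt = econ.cycle_length

    dists = [dist]
    k = 0
    while True:
        age = entry_age + dt * k
        alive = 1.0 - dists[-1][MRS_DEAD]
        if age >= econ.max_age or alive < econ.survival_epsilon:
            break
        m = cycle_matrix(k + 1, entry_age, inputs, matrices)
        dists.append(dists[-1] @ m)
        k += 1

    n = len(dists)
    times = dt * np.arange(n)
    return CohortTrace(years_since_entry=times, age=entry_age + times,
                       distributions=np.vstack(dists))
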