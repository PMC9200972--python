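"""Synthetic inputs and an individual-level validation oracle.

Everything the pipeline consumes can be generated here without any
download: a parametric (Gompertz-Makeham) life table standing in for a
national one, Dirichlet-multinomial transition counts with the same count
structure as the observed tables, and synthetic entry cohorts.  The
default life-table parameters are calibrated so that remaining life
expectancy at age 70 is about 15 years — an engineering choice for a
plausible elderly population, not national data; absolute published
results require substituting a real life table.

:func:`microsim_oracle` is a brute-force individual-level simulator that
follows the same transition rules as the cohort engine but samples each
patient's path stochastically.  Its means converge to the cohort model's
expectations, which makes it an independent check of the deterministic
trace and of the accrual arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inputs_io import (
    MRS_DEAD,
    N_STATES,
    CohortSpec,
    LifeTable,
    ModelInputs,
    TransitionCounts,
    counts_to_row_stochastic,
)
from .markov import cycle_matrix, validate_distribution
from .strategies import MisStrategySpec, apply_mis_effect


@dataclass(frozen=True)
class SyntheticLifeTableSpec:
    """Gompertz-Makeham mortality: h(a) = makeham + gompertz_a * exp(gompertz_b * a)."""

    model: str = "gompertz_makeham"
    makeham: float = 5e-4
    gompertz_a: float = 1.6e-5
    gompertz_b: float = 0.102
    start_age: int = 18
    max_age: int = 110

    def __post_init__(self):
        if self.model != "gompertz_makeham":
            raise ValueError("only the gompertz_makeham model is implemented")
        if min(self.makeham, self.gompertz_a, self.gompertz_b) < 0:
            raise ValueError("hazard parameters must be non-negative")
        if not self.start_age < self.max_age <= 120:
            raise ValueError("require start_age < max_age <= 120")


@dataclass(frozen=True)
class MicrosimResult:
    n: int
    seed: int
    mean_qalys: float
    se_qalys: float
    mean_cost: float
    se_cost: float


def make_life_table(spec: SyntheticLifeTableSpec = SyntheticLifeTableSpec()) -> LifeTable:
    """Annual death probabilities q(a) = 1 - exp(-h(a)), terminal q forced to 1."""
    ages = np.arange(spec.start_age, spec.max_age + 1)
    h = spec.makeham + spec.gompertz_a * np.exp(spec.gompertz_b * ages)
    q = 1.0 - np.exp(-h)
    q[-1] = 1.0
    return LifeTable(age=ages, qx=q)


def make_transition_counts(true_matrices: tuple[np.ndarray, np.ndarray],
                           n_per_row: int, seed: int) -> TransitionCounts:
    """Multinomial transition counts drawn row-wise from known true matrices."""
    if n_per_row < 1:
        raise ValueError("n_per_row must be >= 1")
    rng = np.random.default_rng(seed)
    mats = []
    for true in true_matrices:
        counts = np.zeros((N_STATES, N_STATES), dtype=int)
        for i in range(N_STATES):
            counts[i] = rng.multinomial(n_per_row, true[i])
        mats.append(counts)
    return TransitionCounts(phase_a=mats[0], phase_b=mats[1])


def make_synthetic_cohort(alpha, n: int, seed: int,
                          age_range: tuple[float, float] = (60.0, 80.0)) -> CohortSpec:
    """A synthetic entry cohort: Dirichlet state mix, multinomial counts."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (N_STATES,) or np.any(alpha <= 0):
        raise ValueError("alpha must be 7 positive concentration values")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dist = rng.dirichlet(alpha)
    counts = rng.multinomial(n, dist)
    age = float(rng.uniform(*age_range))
    return CohortSpec(id=f"synthetic-{seed}", label="synthetic cohort",
                      mean_entry_age=age, entry_time_months=3.0,
                      counts=tuple(int(c) for c in counts), source="synthetic")


def microsim_oracle(initial: np.ndarray, inputs: ModelInputs,
                    mis: MisStrategySpec | None = None,
                    n: int = 10_000, seed: int = 0) -> MicrosimResult:
    """Individual-level Monte Carlo replica of the cohort model.

    Simulates ``n`` patients cycle by cycle under the same matrices and
    accrual rules as the deterministic engine and returns mean discounted
    QALYs/costs with Monte Carlo standard errors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dist = validate_distribution(initial)
    surgical_cost = 0.0
    if mis is not None:
        dist = apply_mis_effect(dist, mis)
        dist = dist / dist.sum()
        surgical_cost = mis.surgical_cost
    econ = inputs.econ
    entry_age = inputs.cohort.mean_entry_age
    matrices = counts_to_row_stochastic(inputs.transitions)
    utilities = inputs.utilities.mean

    states = rng.choice(N_STATES, size=n, p=dist)
    qalys = utilities[states] * econ.cycle_length
    costs = inputs.costs.phase(1)[states] + surgical_cost

    k = 0
    while True:
        age = entry_age + econ.cycle_length * k
        if age >= econ.max_age or np.all(states == MRS_DEAD):
            break
        m = cycle_matrix(k + 1, entry_age, inputs, matrices)
        cum = np.cumsum(m, axis=1)
        r = rng.random(n)
        states = (r[:, None] > cum[states]).sum(axis=1)
        k += 1
        t = econ.cycle_length * k
        df_e = (1.0 + econ.discount_rate_effects) ** (-t)
        df_c = (1.0 + econ.discount_rate_costs) ** (-t)
        qalys += utilities[states] * econ.cycle_length * df_e
        phase = inputs.costs.phase(2) if k <= 3 else inputs.costs.phase(3)
        costs += phase[states] * df_c

    return MicrosimResult(
        n=n, seed=seed,
        mean_qalys=float(qalys.mean()), se_qalys=float(qalys.std(ddof=1) / np.sqrt(n)),
        mean_cost=float(costs.mean()), se_cost=float(costs.std(ddof=1) / np.sqrt(n)),
    )
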