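"""Threshold, two-way, scenario and probabilistic sensitivity analyses.

All four analyses ask the same question from different angles: under what
combinations of surgical effectiveness and surgical cost does the MIS arm
achieve a non-negative incremental net monetary benefit?

* threshold analysis — fix the surgical cost and find the smallest
  effectiveness with iNMB >= 0 (or fix effectiveness and solve for the
  maximal cost, which is closed-form: C* = WTP * dQALYs - dCosts_non-surgical);
* two-way sensitivity — map the preferred strategy over a grid of
  (effectiveness, cost) combinations and trace the break-even curve;
* scenario analysis — let MIS act in a single source state only, moving a
  cohort fraction one mRS level up, and find the break-even fraction per
  source state;
* probabilistic sensitivity analysis (PSA) — propagate parameter
  uncertainty by sampling transition rows and the entry distribution from
  Dirichlet posteriors of the observed counts, utilities from
  moment-matched beta distributions (normal for the negative-mean mRS 5
  weight), and costs from moment-matched gamma distributions, with the
  surgical effectiveness and cost held fixed.  Summaries use the mean and
  percentile 2.5/97.5 interval; both arms share each sampled parameter
  set (common random numbers).

Because the cohort model is linear in its entry distribution, every
analysis works from per-entry-state discounted outcome vectors
(:func:`ichcea.economics.per_state_outcomes`), which makes per-sample
break-even searches cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inputs_io import (
    MRS_DEAD,
    N_STATES,
    CostPhaseSet,
    ModelInputs,
    UtilitySet,
    counts_to_distribution,
    counts_to_row_stochastic,
)
from .economics import compute_inmb, per_state_outcomes
from .strategies import (
    InfeasibleEffectError,
    MisStrategySpec,
    apply_mis_effect,
    apply_single_state_shift,
    max_feasible_effectiveness,
    ScenarioShiftSpec,
)

logger = logging.getLogger(__name__)

#: Divisor converting a 95% CI width to a standard error under normality.
_CI_TO_SE = 2.0 * 1.959963984540054


@dataclass(frozen=True)
class PsaSettings:
    """Sampling plan for the probabilistic sensitivity analysis."""

    n_samples: int = 5000
    seed: int = 0
    #: distribution family per parameter block; any entry may be set to
    #: "fixed" to hold that block at its point estimate.
    families: dict = field(default_factory=lambda: {
        "transitions": "dirichlet",
        "initial": "dirichlet",
        "utilities": "beta",
        "utility_mrs5": "normal",
        "costs": "gamma",
    })

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class ThresholdResult:
    """A break-even point estimate with percentile CI and feasibility flag."""

    point: float | None
    lower95: float | None = None
    upper95: float | None = None
    feasible: bool = True
    n_samples: int = 0
    n_infeasible: int = 0
    note: str = ""


@dataclass(frozen=True)
class TwoWayGrid:
    effectiveness: np.ndarray
    cost: np.ndarray
    mis_preferred: np.ndarray  # shape (n_eff, n_cost), True where MIS wins
    threshold_cost: np.ndarray  # C*(effectiveness)
    threshold_lower95: np.ndarray | None = None
    threshold_upper95: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        e, c = np.meshgrid(self.effectiveness, self.cost, indexing="ij")
        return pd.DataFrame({
            "effectiveness": e.ravel(),
            "surgical_cost": c.ravel(),
            "mis_preferred": self.mis_preferred.ravel(),
        })


@dataclass(frozen=True)
class EvaluatedModel:
    """One (possibly sampled) parameter set reduced to what analyses need."""

    initial: np.ndarray
    qaly_vec: np.ndarray
    cost_vec: np.ndarray
    wtp: float


# ---------------------------------------------------------------------------
# Parameter sampling


def _fit_beta(mean: float, se: float) -> tuple[float, float] | None:
    if se <= 0 or not 0.0 < mean < 1.0:
        return None
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if not np.isfinite(nu) or nu <= 0:
        return None
    return mean * nu, (1.0 - mean) * nu


def _fit_gamma(mean: float, se: float) -> tuple[float, float] | None:
    if mean <= 0 or se <= 0:
        return None
    return (mean / se) ** 2, se**2 / mean


def _sample_dirichlet_rows(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        row = counts[i].astype(float)
        pos = row > 0
        if not pos.any():
            out[i, i] = 1.0
        elif pos.sum() == 1:
            out[i, pos] = 1.0
        else:
            out[i, pos] = rng.dirichlet(row[pos])
    return out


def _sample_simplex(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    pos = counts > 0
    out = np.zeros(N_STATES)
    if pos.sum() == 1:
        out[pos] = 1.0
    else:
        out[pos] = rng.dirichlet(counts[pos])
    return out


def _sample_utilities(u: UtilitySet, families: dict, rng: np.random.Generator) -> np.ndarray:
    mean = u.mean.copy()
    se = (u.upper95 - u.lower95) / _CI_TO_SE
    for s in range(N_STATES - 2):  # mRS 0-4: beta
        if families.get("utilities") == "fixed":
            break
        fit = _fit_beta(mean[s], se[s])
        if fit is None:
            logger.warning("beta moment fit failed for utility mRS %d; holding fixed", s)
            continue
        mean[s] = rng.beta(*fit)
    if families.get("utility_mrs5") != "fixed":
        mean[5] = rng.normal(u.mean[5], se[5])
    mean[MRS_DEAD] = 0.0
    return mean


def _sample_costs(c: CostPhaseSet, rng: np.random.Generator) -> np.ndarray:
    mean = c.mean.copy()
    se = (c.upper95 - c.lower95) / _CI_TO_SE
    for s in range(N_STATES):
        for p in range(3):
            fit = _fit_gamma(mean[s, p], se[s, p])
            if fit is None:
                if mean[s, p] > 0 and se[s, p] > 0:
                    logger.warning("gamma moment fit failed for cost mRS %d phase %d", s, p + 1)
                continue
            mean[s, p] = rng.gamma(*fit)
    return mean


def sample_parameter_set(inputs: ModelInputs, psa: PsaSettings,
                         rng: np.random.Generator):
    """Draw one parameter set; returns (matrices, initial, utilities, costs)."""
    fam = psa.families
    if fam.get("transitions") == "fixed":
        matrices = counts_to_row_stochastic(inputs.transitions)
    else:
        matrices = (_sample_dirichlet_rows(inputs.transitions.phase_a, rng),
                    _sample_dirichlet_rows(inputs.transitions.phase_b, rng))
    if fam.get("initial") == "fixed":
        initial = inputs.cohort.distribution()
    else:
        initial = _sample_simplex(np.asarray(inputs.cohort.counts), rng)
    if fam.get("utilities") == "fixed" and fam.get("utility_mrs5") == "fixed":
        utilities = inputs.utilities.mean.copy()
    else:
        utilities = _sample_utilities(inputs.utilities, fam, rng)
    costs = inputs.costs.mean.copy() if fam.get("costs") == "fixed" else _sample_costs(inputs.costs, rng)
    return matrices, initial, utilities, costs


def _evaluate(inputs: ModelInputs, matrices, initial, utilities, costs) -> EvaluatedModel:
    import dataclasses as dc

    sampled = dc.replace(
        inputs,
        utilities=UtilitySet(mean=utilities, lower95=np.minimum(utilities, inputs.utilities.lower95),
                             upper95=np.maximum(utilities, inputs.utilities.upper95)),
        costs=CostPhaseSet(mean=costs, lower95=np.minimum(costs, inputs.costs.lower95),
                           upper95=np.maximum(costs, inputs.costs.upper95)),
    )
    q, c = per_state_outcomes(sampled, matrices=matrices)
    return EvaluatedModel(initial=initial, qaly_vec=q, cost_vec=c, wtp=inputs.econ.wtp)


def point_model(inputs: ModelInputs) -> EvaluatedModel:
    """The deterministic model reduced for break-even searches."""
    matrices = counts_to_row_stochastic(inputs.transitions)
    q, c = per_state_outcomes(inputs, matrices=matrices)
    return EvaluatedModel(initial=inputs.cohort.distribution(), qaly_vec=q,
                          cost_vec=c, wtp=inputs.econ.wtp)


def draw_models(inputs: ModelInputs, psa: PsaSettings) -> list[EvaluatedModel]:
    """Sample and evaluate ``psa.n_samples`` parameter sets (seeded)."""
    rng = np.random.default_rng(psa.seed)
    out = []
    for _ in range(psa.n_samples):
        matrices, initial, utilities, costs = sample_parameter_set(inputs, psa, rng)
        out.append(_evaluate(inputs, matrices, initial, utilities, costs))
    return out


# ---------------------------------------------------------------------------
# Break-even machinery


def _mis_inmb(model: EvaluatedModel, mis: MisStrategySpec) -> float:
    """iNMB of the MIS arm vs usual care on one evaluated parameter set."""
    eps_max = max_feasible_effectiveness(model.initial, mis.decrement_rule)
    eps = min(mis.effectiveness, eps_max)
    spec = MisStrategySpec(effectiveness=eps, allocation_weights=mis.allocation_weights,
                           decrement_rule=mis.decrement_rule, surgical_cost=mis.surgical_cost)
    mis_dist = apply_mis_effect(model.initial, spec)
    dq = float((mis_dist - model.initial) @ model.qaly_vec)
    dc = float((mis_dist - model.initial) @ model.cost_vec) + mis.surgical_cost
    return compute_inmb(dq, dc, model.wtp)


def _shift_inmb(model: EvaluatedModel, spec: ScenarioShiftSpec) -> float:
    """iNMB of a single-state shift; the shift saturates at the source
    state's occupancy so sample-mean curves stay defined everywhere."""
    occ = float(model.initial[spec.from_state])
    if spec.fraction > occ:
        spec = ScenarioShiftSpec(from_state=spec.from_state, fraction=occ,
                                 surgical_cost=spec.surgical_cost)
    shifted = apply_single_state_shift(model.initial, spec)
    dq = float((shifted - model.initial) @ model.qaly_vec)
    dc = float((shifted - model.initial) @ model.cost_vec) + spec.surgical_cost
    return compute_inmb(dq, dc, model.wtp)


def _bisect_root(f, lo: float, hi: float, tol: float = 1e-6) -> float | None:
    """Smallest x in [lo, hi] with f(x) >= 0, for f non-decreasing.

    Returns None when even f(hi) < 0.
    """
    if f(lo) >= 0.0:
        return lo
    if f(hi) < 0.0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _summarize_roots(point: float | None, roots: list[float | None],
                     note_if_infeasible: str) -> ThresholdResult:
    n = len(roots)
    finite = np.array([r for r in roots if r is not None], dtype=float)
    n_inf = n - finite.size
    if point is None:
        return ThresholdResult(point=None, feasible=False, n_samples=n,
                               n_infeasible=n_inf, note=note_if_infeasible)
    lo = hi = None
    if finite.size >= 2:
        lo, hi = (float(np.percentile(finite, p)) for p in (2.5, 97.5))
    return ThresholdResult(point=float(point), lower95=lo, upper95=hi,
                           feasible=True, n_samples=n, n_infeasible=n_inf)


# ---------------------------------------------------------------------------
# The four analyses


def threshold_effectiveness(inputs: ModelInputs, surgical_cost: float,
                            psa: PsaSettings | None = None,
                            mis: MisStrategySpec | None = None,
                            models: list[EvaluatedModel] | None = None) -> ThresholdResult:
    """Smallest effectiveness with iNMB >= 0 at a fixed surgical cost.

    Solved by bisection (tolerance 1e-6 on the effectiveness) over
    [0, max feasible effectiveness].  Under PSA the point estimate is the
    root of the sample-mean iNMB and the CI the 2.5/97.5 percentiles of
    the per-sample roots.
    """
    if surgical_cost < 0:
        raise ValueError("surgical_cost must be non-negative")
    template = mis or MisStrategySpec()

    def make_f(mdl_list):
        # per-sample effects saturate at their own feasible maximum
        eps_max = max(max_feasible_effectiveness(m.initial, template.decrement_rule)
                      for m in mdl_list)

        def f(eps):
            spec = MisStrategySpec(effectiveness=eps,
                                   allocation_weights=template.allocation_weights,
                                   decrement_rule=template.decrement_rule,
                                   surgical_cost=surgical_cost)
            return float(np.mean([_mis_inmb(m, spec) for m in mdl_list]))

        return f, eps_max

    if psa is None and models is None:
        f, eps_max = make_f([point_model(inputs)])
        root = _bisect_root(f, 0.0, eps_max)
        if root is None:
            return ThresholdResult(point=None, feasible=False,
                                   note="never cost-effective within feasible effectiveness")
        return ThresholdResult(point=root)

    models = models if models is not None else draw_models(inputs, psa)
    roots = []
    for m in models:
        f, eps_max = make_f([m])
        roots.append(_bisect_root(f, 0.0, eps_max))
    f_mean, eps_max = make_f(models)
    point = _bisect_root(f_mean, 0.0, eps_max)
    return _summarize_roots(point, roots, "never cost-effective within feasible effectiveness")


def threshold_cost(inputs: ModelInputs, effectiveness: float,
                   psa: PsaSettings | None = None,
                   mis: MisStrategySpec | None = None,
                   models: list[EvaluatedModel] | None = None) -> ThresholdResult:
    """Maximal surgical cost with iNMB >= 0 at a fixed effectiveness.

    Closed form per parameter set: C* = WTP * dQALYs - dCosts_non-surgical.
    """
    template = mis or MisStrategySpec()
    spec = MisStrategySpec(effectiveness=effectiveness,
                           allocation_weights=template.allocation_weights,
                           decrement_rule=template.decrement_rule, surgical_cost=0.0)

    def cstar(m: EvaluatedModel) -> float:
        return _mis_inmb(m, spec)  # with zero surgical cost, iNMB == C*

    if psa is None and models is None:
        return ThresholdResult(point=cstar(point_model(inputs)))
    models = models if models is not None else draw_models(inputs, psa)
    roots = [cstar(m) for m in models]
    return _summarize_roots(float(np.mean(roots)), roots, "")


def two_way_grid(inputs: ModelInputs, resolution: int = 201,
                 effectiveness_range: tuple[float, float] = (0.0, 0.20),
                 cost_range: tuple[float, float] = (0.0, 50_000.0),
                 psa: PsaSettings | None = None,
                 mis: MisStrategySpec | None = None,
                 models: list[EvaluatedModel] | None = None) -> TwoWayGrid:
    """Preferred strategy over an (effectiveness, surgical cost) grid.

    A cell prefers MIS when its iNMB is non-negative, i.e. when the cost
    lies at or below the break-even curve C*(effectiveness).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2 per axis")
    eff_axis = np.linspace(*effectiveness_range, resolution)
    cost_axis = np.linspace(*cost_range, resolution)

    def curve(mdl_list):
        return np.array([
            threshold_cost(inputs, e, mis=mis, models=mdl_list).point for e in eff_axis
        ])

    if psa is None and models is None:
        thr = curve([point_model(inputs)])
        lo = hi = None
    else:
        models = models if models is not None else draw_models(inputs, psa)
        per_sample = np.vstack([curve([m]) for m in models])
        thr = per_sample.mean(axis=0)
        lo = np.percentile(per_sample, 2.5, axis=0)
        hi = np.percentile(per_sample, 97.5, axis=0)
    preferred = thr[:, None] >= cost_axis[None, :] - 1e-9
    return TwoWayGrid(effectiveness=eff_axis, cost=cost_axis, mis_preferred=preferred,
                      threshold_cost=thr, threshold_lower95=lo, threshold_upper95=hi)


def scenario_thresholds(inputs: ModelInputs, surgical_cost: float,
                        psa: PsaSettings | None = None,
                        models: list[EvaluatedModel] | None = None) -> dict[int, ThresholdResult]:
    """Break-even cohort fraction per single-source-state improvement.

    For each source state mRS 1..6 the whole cohort is charged the
    surgical cost but only a fraction q moves one state up; the result is
    the smallest q with iNMB >= 0, bisected over [0, source occupancy],
    or an infeasible flag (e.g. mRS 6 -> 5, which worsens both QALYs and
    costs, is never cost-effective).
    """
    if surgical_cost < 0:
        raise ValueError("surgical_cost must be non-negative")
    if models is None:
        models = [point_model(inputs)] if psa is None else draw_models(inputs, psa)
    deterministic = psa is None and len(models) == 1

    results: dict[int, ThresholdResult] = {}
    for s in range(1, N_STATES):
        def root_and_reason(mdl_list):
            # per-sample shifts saturate at their own occupancy, so the
            # sample-mean curve is defined up to the largest occupancy
            q_max = max(float(m.initial[s]) for m in mdl_list)
            if q_max <= 0.0:
                return None, "no occupancy in the source state"

            def f(q):
                spec = ScenarioShiftSpec(from_state=s, fraction=q, surgical_cost=surgical_cost)
                return float(np.mean([_shift_inmb(m, spec) for m in mdl_list]))

            root = _bisect_root(f, 0.0, q_max)
            if root is not None:
                return root, ""
            # iNMB(q) is linear in q: a non-positive slope can never recover
            # the surgical cost, otherwise the root merely exceeds occupancy
            if f(q_max) <= f(0.0):
                return None, "never cost-effective"
            return None, "break-even fraction exceeds source-state occupancy"

        if deterministic:
            r, reason = root_and_reason(models)
            results[s] = (ThresholdResult(point=r) if r is not None else
                          ThresholdResult(point=None, feasible=False, note=reason))
        else:
            roots = [root_and_reason([m])[0] for m in models]
            point, reason = root_and_reason(models)
            results[s] = _summarize_roots(point, roots, reason)
    return results


def run_psa(inputs: ModelInputs, mis: MisStrategySpec, psa: PsaSettings,
            models: list[EvaluatedModel] | None = None) -> pd.DataFrame:
    """Per-sample outcomes of both arms under parameter uncertainty.

    Returns one row per sample with each arm's discounted QALYs and costs,
    the increments and the iNMB at the configured willingness-to-pay.  The
    surgical effectiveness and cost stay fixed across samples.
    """
    if models is None:
        models = draw_models(inputs, psa)
    rows = []
    for i, m in enumerate(models):
        uc_q = float(m.initial @ m.qaly_vec)
        uc_c = float(m.initial @ m.cost_vec)
        eps_max = max_feasible_effectiveness(m.initial, mis.decrement_rule)
        if mis.effectiveness > eps_max:
            logger.warning("sample %d: effectiveness clamped to feasible %.4g", i, eps_max)
        try:
            mis_dist = apply_mis_effect(m.initial, mis)
        except InfeasibleEffectError:
            import dataclasses as dc
            mis_dist = apply_mis_effect(m.initial, dc.replace(mis, effectiveness=eps_max))
        mis_q = float(mis_dist @ m.qaly_vec)
        mis_c = float(mis_dist @ m.cost_vec) + mis.surgical_cost
        rows.append({
            "sample": i, "uc_qalys": uc_q, "uc_cost": uc_c,
            "mis_qalys": mis_q, "mis_cost": mis_c,
            "delta_qalys": mis_q - uc_q, "delta_cost": mis_c - uc_c,
            "inmb": compute_inmb(mis_q - uc_q, mis_c - uc_c, m.wtp),
        })
    return pd.DataFrame(rows)


def summarize_psa(values) -> tuple[float, float, float]:
    """Mean with percentile-method 95% interval (2.5th, 97.5th)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    return float(v.mean()), float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))
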