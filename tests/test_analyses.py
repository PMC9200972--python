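"""Threshold, two-way, scenario and probabilistic sensitivity analyses."""

import dataclasses

import numpy as np
import pytest

import ichcea
from ichcea import analyses
from ichcea.analyses import (
    PsaSettings,
    draw_models,
    point_model,
    run_psa,
    sample_parameter_set,
    scenario_thresholds,
    summarize_psa,
    threshold_cost,
    threshold_effectiveness,
    two_way_grid,
)
from ichcea.economics import run_cea
from ichcea.strategies import MisStrategySpec


def _toy_inputs(inputs1):
    """Linear toy: utility 1 in mRS 0-3, 0 in mRS 4-6, zero costs, no
    mortality below the age cap, no first-year movement, no discounting.

    Any redistributed unit of mass then gains exactly T QALYs, where T is
    the simulated horizon, so the break-even effectiveness at surgical
    cost C is C / (WTP * T) in closed form.
    """
    eye = np.eye(7, dtype=int)
    ages = np.arange(18, 111)
    qx = np.r_[np.zeros(92), 1.0]
    u = np.r_[np.ones(4), np.zeros(3)]
    toy = dataclasses.replace(
        inputs1,
        transitions=ichcea.TransitionCounts(phase_a=eye, phase_b=eye),
        life_table=ichcea.LifeTable(age=ages, qx=qx),
        utilities=ichcea.UtilitySet(mean=u, lower95=u, upper95=u),
        costs=ichcea.CostPhaseSet(mean=np.zeros((7, 3)), lower95=np.zeros((7, 3)),
                                  upper95=np.zeros((7, 3))),
        econ=dataclasses.replace(inputs1.econ, discount_rate_effects=0.0,
                                 discount_rate_costs=0.0),
    )
    horizon = 0.25 * ichcea.run_trace(np.eye(7)[0], toy).n_cycles
    return toy, horizon


def test_threshold_effectiveness_matches_toy_closed_form(inputs1):
    toy, T = _toy_inputs(inputs1)
    cost = 10_000.0
    expected = cost / (toy.econ.wtp * T)
    res = threshold_effectiveness(toy, cost)
    assert res.feasible
    assert res.point == pytest.approx(expected, abs=2e-6)


def test_threshold_effectiveness_zero_cost_is_zero(inputs1):
    assert threshold_effectiveness(inputs1, 0.0).point == 0.0


def test_threshold_cost_closed_form_examples(inputs1):
    toy, T = _toy_inputs(inputs1)
    # an effectiveness chosen to gain exactly 0.1 QALYs at WTP 80,000 with
    # no downstream cost change must break even at 8,000
    eps = 0.1 / T
    res = threshold_cost(toy, eps)
    assert res.point == pytest.approx(8000.0, rel=1e-9)
    assert threshold_cost(toy, 0.0).point == pytest.approx(0.0, abs=1e-9)


def test_threshold_monotonicity(inputs1):
    e1 = threshold_effectiveness(inputs1, 5_000.0).point
    e2 = threshold_effectiveness(inputs1, 10_000.0).point
    e3 = threshold_effectiveness(inputs1, 20_000.0).point
    assert e1 <= e2 <= e3
    c1 = threshold_cost(inputs1, 0.05).point
    c2 = threshold_cost(inputs1, 0.11).point
    assert c1 <= c2


def test_threshold_consistency_with_full_cea(inputs1):
    """The break-even point must make the full two-trace comparison neutral."""
    eps = threshold_effectiveness(inputs1, 10_000.0).point
    res = run_cea(inputs1, MisStrategySpec(effectiveness=eps, surgical_cost=10_000.0))
    assert res.inmb == pytest.approx(0.0, abs=1.0)


def test_two_way_grid_structure_and_boundary(inputs1):
    grid = two_way_grid(inputs1, resolution=41)
    assert grid.mis_preferred.shape == (41, 41)
    # effectiveness 0 with positive cost: usual care everywhere
    assert not grid.mis_preferred[0, 1:].any()
    # monotone boundary: once cost exceeds the curve, preference flips
    for i in range(41):
        col = grid.mis_preferred[i]
        assert np.all(np.diff(col.astype(int)) <= 0)
    # grid break-even curve consistent with the dedicated threshold search
    c_fixed = 10_000.0
    eps_star = threshold_effectiveness(inputs1, c_fixed).point
    crossing = grid.effectiveness[np.argmax(grid.threshold_cost >= c_fixed)]
    spacing = grid.effectiveness[1] - grid.effectiveness[0]
    assert abs(crossing - eps_star) <= spacing


def test_two_way_curve_points_have_zero_inmb(inputs1):
    grid = two_way_grid(inputs1, resolution=11)
    for eps, cstar in zip(grid.effectiveness[1:4], grid.threshold_cost[1:4]):
        res = run_cea(inputs1, MisStrategySpec(effectiveness=float(eps), surgical_cost=float(cstar)))
        assert res.inmb == pytest.approx(0.0, abs=1.0)


def test_scenario_degenerate_states_never_cost_effective(inputs1):
    u = np.full(7, 0.5)
    c = np.full((7, 3), 100.0)
    eye = np.eye(7, dtype=int)
    flat = dataclasses.replace(
        inputs1,
        transitions=ichcea.TransitionCounts(phase_a=eye, phase_b=eye),
        utilities=ichcea.UtilitySet(mean=u, lower95=u, upper95=u),
        costs=ichcea.CostPhaseSet(mean=c, lower95=c, upper95=c),
        excess=ichcea.ExcessMortality(hr=np.ones(6)),
    )
    # identical utilities, costs and mortality in adjacent states: the shift
    # changes nothing, iNMB == -surgical_cost for every fraction
    res = scenario_thresholds(flat, 10_000.0)
    assert not res[3].feasible
    assert "never" in res[3].note


def test_scenario_zero_occupancy_flagged(inputs3):
    res = scenario_thresholds(inputs3, 10_000.0)
    assert not res[1].feasible
    assert "occupancy" in res[1].note


def test_psa_sampling_reproducible_and_valid(inputs1):
    psa = PsaSettings(n_samples=5, seed=42)
    m1 = draw_models(inputs1, psa)
    m2 = draw_models(inputs1, psa)
    for a, b in zip(m1, m2):
        assert np.array_equal(a.initial, b.initial)
        assert np.array_equal(a.qaly_vec, b.qaly_vec)
        assert np.array_equal(a.cost_vec, b.cost_vec)
    rng = np.random.default_rng(0)
    matrices, initial, utilities, costs = sample_parameter_set(inputs1, psa, rng)
    for m in matrices:
        assert np.allclose(m.sum(axis=1), 1.0)
        assert m[6, 6] == 1.0
    assert initial.sum() == pytest.approx(1.0)
    assert np.all(costs >= 0)
    assert utilities[6] == 0.0


def test_psa_sample_means_approach_table_means(inputs1):
    n = 400
    rng = np.random.default_rng(7)
    psa = PsaSettings(n_samples=n, seed=7)
    utilities = []
    costs = []
    initials = []
    rows = []
    for _ in range(n):
        matrices, initial, u, c = sample_parameter_set(inputs1, psa, rng)
        utilities.append(u)
        costs.append(c)
        initials.append(initial)
        rows.append(matrices[0][3])
    utilities, costs, initials, rows = map(np.asarray, (utilities, costs, initials, rows))

    se = (inputs1.utilities.upper95 - inputs1.utilities.lower95) / 3.919927969081533
    for s in range(6):
        mc_se = se[s] / np.sqrt(n)
        assert abs(utilities[:, s].mean() - inputs1.utilities.mean[s]) < 3 * mc_se + 1e-12

    cse = (inputs1.costs.upper95 - inputs1.costs.lower95) / 3.919927969081533
    for s, p in ((2, 1), (5, 0), (4, 2)):
        mc_se = cse[s, p] / np.sqrt(n)
        assert abs(costs[:, s, p].mean() - inputs1.costs.mean[s, p]) < 3 * mc_se

    # Dirichlet sample means converge to the count proportions
    p_true = inputs1.cohort.distribution()
    total = inputs1.cohort.n
    for s in range(7):
        mc_se = np.sqrt(p_true[s] * (1 - p_true[s]) / (total + 1)) / np.sqrt(n)
        assert abs(initials[:, s].mean() - p_true[s]) < 3 * mc_se + 1e-12

    row_counts = inputs1.transitions.phase_a[3]
    p_row = row_counts / row_counts.sum()
    for j in range(7):
        mc_se = np.sqrt(p_row[j] * (1 - p_row[j]) / (row_counts.sum() + 1)) / np.sqrt(n)
        assert abs(rows[:, j].mean() - p_row[j]) < 3 * mc_se + 1e-12


def test_run_psa_outcome_table(inputs1):
    psa = PsaSettings(n_samples=40, seed=5)
    df = run_psa(inputs1, MisStrategySpec(), psa)
    assert len(df) == 40
    assert set(df.columns) >= {"uc_qalys", "uc_cost", "mis_qalys", "mis_cost",
                               "delta_qalys", "delta_cost", "inmb"}
    assert np.allclose(df.inmb, 80_000.0 * df.delta_qalys - df.delta_cost)
    df2 = run_psa(inputs1, MisStrategySpec(), psa)
    assert df.equals(df2)


def test_psa_percentile_interval_contains_deterministic_value(inputs1):
    psa = PsaSettings(n_samples=120, seed=11)
    models = draw_models(inputs1, psa)
    df = run_psa(inputs1, MisStrategySpec(), psa, models=models)
    det = run_cea(inputs1, MisStrategySpec())
    mean, lo, hi = summarize_psa(df.uc_qalys)
    assert lo <= det.usual_care.qalys <= hi
    mean, lo, hi = summarize_psa(df.inmb)
    assert lo <= det.inmb <= hi


def test_summarize_psa_behaviour():
    mean, lo, hi = summarize_psa([5.0] * 10)
    assert mean == 5.0 and lo == 5.0 and hi == 5.0
    assert summarize_psa([1.0, 2.0, 3.0])[0] == pytest.approx(2.0)
    draws = np.random.default_rng(123).standard_normal(5000)
    _, lo, hi = summarize_psa(draws)
    assert lo == pytest.approx(-1.96, abs=0.1)
    assert hi == pytest.approx(1.96, abs=0.1)
    with pytest.raises(ValueError):
        summarize_psa([1.0])


def test_threshold_psa_point_and_interval(inputs1):
    psa = PsaSettings(n_samples=60, seed=3)
    models = draw_models(inputs1, psa)
    res = threshold_effectiveness(inputs1, 10_000.0, models=models)
    assert res.feasible
    assert res.lower95 <= res.point <= res.upper95
    det = threshold_effectiveness(inputs1, 10_000.0).point
    assert res.lower95 <= det <= res.upper95
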