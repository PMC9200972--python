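"""Input types, fixtures, config round-trip and validation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ichcea
from ichcea.inputs_io import (
    InputError,
    ValidationError,
    counts_to_distribution,
    counts_to_row_stochastic,
    default_inputs,
    fixture_cohort,
    fixture_transitions,
    load_inputs,
    save_inputs,
    validate_inputs,
)

# Printed two-decimal transition probabilities for the two phases; None
# marks an empty cell.
PRINTED_PHASE_A = [
    [0.80, 0.20, None, None, None, None, None],
    [None, 0.95, None, None, 0.05, None, None],
    [None, 0.17, 0.75, None, None, None, 0.08],
    [None, 0.04, 0.20, 0.68, 0.04, None, 0.04],
    [None, None, None, 0.16, 0.81, 0.03, None],
    [None, None, None, None, None, 1.00, None],
    [None, None, None, None, None, None, 1.00],
]
PRINTED_PHASE_B = [
    [1.00, None, None, None, None, None, None],
    [None, 0.96, None, None, None, None, 0.04],
    [0.07, 0.21, 0.64, 0.07, None, None, None],
    [None, None, 0.09, 0.91, None, None, None],
    [None, None, None, 0.07, 0.71, 0.18, 0.04],
    [None, None, None, None, None, 1.00, None],
    [None, None, None, None, None, None, 1.00],
]

# Printed integer percentages of the three entry cohorts.
PRINTED_COHORT_PCT = {
    "cohort1": [3, 11, 6, 13, 17, 3, 46],
    "cohort2": [2, 11, 16, 17, 19, 14, 22],
    "cohort3": [0, 0, 4, 7, 25, 51, 14],
}


def test_fixture_cohort_counts_and_ages():
    c1 = fixture_cohort("cohort1")
    assert c1.counts == (5, 21, 12, 25, 32, 6, 87)
    assert c1.n == 188
    assert c1.mean_entry_age == 70.0
    assert fixture_cohort("cohort2").mean_entry_age == 69.0
    assert fixture_cohort("cohort3").mean_entry_age == 62.0
    with pytest.raises(InputError):
        fixture_cohort("cohort9")


@pytest.mark.parametrize("name", ["cohort1", "cohort2", "cohort3"])
def test_cohort_distribution_matches_printed_percentages(name):
    dist = fixture_cohort(name).distribution()
    printed = PRINTED_COHORT_PCT[name]
    assert np.array_equal(np.round(100 * dist), printed)


def test_counts_to_distribution_examples():
    d = counts_to_distribution((5, 21, 12, 25, 32, 6, 87))
    assert d[6] == pytest.approx(87 / 188)
    assert counts_to_distribution((0, 0, 0, 0, 0, 0, 10)).tolist() == [0, 0, 0, 0, 0, 0, 1]
    assert np.allclose(counts_to_distribution([1] * 7), 1 / 7)
    with pytest.raises(ValidationError):
        counts_to_distribution([0] * 7)
    with pytest.raises(ValidationError):
        counts_to_distribution([1, -1, 1, 1, 1, 1, 1])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=7, max_size=7)
       .filter(lambda c: sum(c) > 0))
def test_counts_to_distribution_is_simplex(counts):
    d = counts_to_distribution(counts)
    assert np.all(d >= 0)
    assert d.sum() == pytest.approx(1.0, abs=1e-12)


def test_row_stochastic_reproduces_every_printed_probability():
    a, b = counts_to_row_stochastic(fixture_transitions())
    for mat, printed in ((a, PRINTED_PHASE_A), (b, PRINTED_PHASE_B)):
        for i in range(7):
            assert mat[i].sum() == pytest.approx(1.0, abs=1e-12)
            for j in range(7):
                expected = printed[i][j]
                if expected is None:
                    assert mat[i, j] == 0.0
                else:
                    assert round(mat[i, j], 2) == pytest.approx(expected)


def test_row_stochastic_empty_row_becomes_identity():
    tc = ichcea.TransitionCounts(phase_a=np.zeros((7, 7), dtype=int),
                                 phase_b=np.zeros((7, 7), dtype=int))
    a, _ = counts_to_row_stochastic(tc)
    assert np.array_equal(a, np.eye(7))


def test_validate_inputs_clean_fixture(inputs1):
    assert validate_inputs(inputs1) == []


def test_validate_inputs_flags_bad_utilities(inputs1):
    u = inputs1.utilities
    bad = dataclasses.replace(inputs1, utilities=ichcea.UtilitySet(
        mean=np.where(np.arange(7) == 2, 0.9, u.mean), lower95=u.lower95, upper95=u.upper95))
    assert any("UtilitySet" in v for v in validate_inputs(bad))


def test_validate_inputs_flags_entry_age_outside_life_table(inputs1):
    lt = inputs1.life_table
    short = ichcea.LifeTable(age=lt.age[lt.age >= 80], qx=lt.qx[lt.age >= 80])
    bad = dataclasses.replace(inputs1, life_table=short)
    assert any("cross-check" in v for v in validate_inputs(bad))


def test_default_econ_settings(inputs1):
    e = inputs1.econ
    assert e.wtp == 80_000.0
    assert e.discount_rate_effects == 0.015
    assert e.discount_rate_costs == 0.04
    assert e.cycle_length == 0.25


def test_excess_hr_defaults_monotone(inputs1):
    hr = inputs1.excess.hr
    assert hr[0] == hr[1] == 1.0
    assert hr[2] == 1.11 and hr[5] == 2.38
    assert hr[3] == pytest.approx(1.11 + (2.38 - 1.11) / 3)
    assert np.all(np.diff(hr) >= 0)


def test_cost_fixture_key_values(inputs1):
    c = inputs1.costs
    assert c.phase(1)[6] == 5612.0
    assert c.phase(2)[5] == 28031.0
    assert c.phase(3)[6] == 0.0
    assert c.phase(2)[6] == pytest.approx(5.30)


def test_config_round_trip_bit_identical(tmp_path, inputs1):
    cfg = save_inputs(inputs1, tmp_path)
    reloaded = load_inputs(cfg)
    assert reloaded.cohort.counts == inputs1.cohort.counts
    assert reloaded.cohort.mean_entry_age == inputs1.cohort.mean_entry_age
    assert np.array_equal(reloaded.transitions.phase_a, inputs1.transitions.phase_a)
    assert np.array_equal(reloaded.transitions.phase_b, inputs1.transitions.phase_b)
    for attr in ("mean", "lower95", "upper95"):
        assert np.array_equal(getattr(reloaded.utilities, attr), getattr(inputs1.utilities, attr))
        assert np.array_equal(getattr(reloaded.costs, attr), getattr(inputs1.costs, attr))
    assert np.array_equal(reloaded.life_table.qx, inputs1.life_table.qx)
    assert np.array_equal(reloaded.excess.hr, inputs1.excess.hr)
    assert reloaded.econ == inputs1.econ


def test_load_inputs_defaults_and_errors(tmp_path):
    cfg = tmp_path / "c.yaml"
    cfg.write_text("cohort: cohort1\n")
    inputs = load_inputs(cfg)
    assert inputs.econ.wtp == 80_000.0
    assert inputs.cohort.counts == (5, 21, 12, 25, 32, 6, 87)

    missing = tmp_path / "m.yaml"
    missing.write_text("life_table: nowhere.csv\n")
    with pytest.raises(InputError, match="nowhere.csv"):
        load_inputs(missing)

    with pytest.raises(InputError):
        load_inputs(tmp_path / "does_not_exist.yaml")

    bad = tmp_path / "bad.yaml"
    bad.write_text(
        "costs:\n"
        "  - {mrs: 0, phase: 1, mean: -5, lower95: 0, upper95: 1}\n")
    with pytest.raises(ValidationError, match="CostPhaseSet"):
        load_inputs(bad)
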