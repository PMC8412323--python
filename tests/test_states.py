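"""Scenario presets, propensity calculus and the rescue constraint."""

import numpy as np
from dataclasses import replace
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epilock._kernels import total_propensity
from epilock.ssa import pack_population, pack_scenario
from epilock.states import (
    ConfigurationError,
    INITIAL_POPULATION,
    apply_rescue_constraint,
    preset_names,
    preset_scenario,
    propensities,
    resistant_death_coefficient,
)


@pytest.mark.parametrize(
    "name,state,expected",
    [
        # (birth, death, transition) per-cell coefficients, pre-drug
        ("control", "G-Tp", (2.0, 1.0, 0.1)),
        ("control", "Q", (0.0, 1.0, 0.1)),
        ("drug_sensitive", "GS-Tr", (2.0, 1.0, 0.1)),
        ("drug_resistant_stable", "G-Tp", (2.0, 1.0, 1.0)),
        ("drug_resistant_unstable", "GS-Tp", (2.0, 1.0, 1.0)),
    ],
)
def test_preset_pre_drug_coefficients(name, state, expected):
    p = preset_scenario(name)
    assert p.rates.coefficients(state, 0.0) == expected


@pytest.mark.parametrize(
    "name,state,expected",
    [
        ("drug_sensitive", "G-Tp", (2.0, 2.2, 0.1)),
        ("drug_resistant_stable", "G-Tp", (2.0, 2.2, 1.0)),
        ("drug_resistant_stable", "Q", (0.0, 2.2, 1.0)),
        ("drug_resistant_stable", "G-R", (2.0, 2.2, 0.0)),  # death = decay amplitude
        ("s1_low_resistant_birth", "G-R", (1.5, 2.2, 0.0)),
        ("s1_high_resistant_birth", "GS-R", (2.5, 2.2, 0.0)),
        ("s1_high_transitions", "G-Tp", (2.0, 2.2, 2.0)),
        ("s1_no_transitions", "G-Tp", (2.0, 2.2, 0.0)),
    ],
)
def test_preset_post_drug_coefficients(name, state, expected):
    p = preset_scenario(name)
    assert p.rates.coefficients(state, 3.0) == expected


def test_preset_catalogue_contents():
    names = preset_names()
    assert {"control", "drug_sensitive", "drug_resistant_stable",
            "drug_resistant_unstable"} <= set(names)
    assert sum(n.startswith("s1_") for n in names) == 6


def test_unknown_scenario_raises():
    with pytest.raises(ConfigurationError, match="unknown scenario"):
        preset_scenario("nonsense")


def test_initial_population_is_100_cells():
    p = preset_scenario("control")
    assert sum(p.initial.values()) == 100
    assert p.initial == INITIAL_POPULATION
    assert p.initial["Q"] == 80 and p.initial["G-Tp"] == 7 and p.initial["GS-Tp"] == 3


def test_control_has_no_resistant_channel():
    p = preset_scenario("control")
    assert p.space.to_resistant == {}
    assert p.space.destinations("G-Tp", post_drug=True) == p.space.destinations(
        "G-Tp", post_drug=False
    )


def test_propensity_examples_control():
    p = preset_scenario("control")
    rates = propensities(p.initial, 0.0, p.rates, p.space, rescue=False)
    assert rates[("birth", "G-Tp")] == pytest.approx(14.0)
    assert rates[("death", "G-Tp")] == pytest.approx(7.0)
    # per-destination convention (default): each lateral channel gets ct*n
    assert rates[("transition", "G-Tp", "Q")] == pytest.approx(0.7)


def test_propensity_total_outflow_convention():
    # under the total-outflow reading the whole initial event rate is 150
    # (Q: 80 death + 8 transition; G states 21.7 each; GS states 9.3 each)
    p = preset_scenario("control")
    total = replace(p.rates, apportionment="total")
    rates = propensities(p.initial, 0.0, total, p.space, rescue=False)
    assert rates[("transition", "G-Tp", "Q")] == pytest.approx(0.7 / 4)
    assert sum(rates.values()) == pytest.approx(150.0)


def test_propensity_total_with_rescue_applied():
    # four sensitive states sit below the threshold at t=0: their deaths
    # (7+7+3+3) are zeroed by the rescue constraint
    p = preset_scenario("control")
    total = replace(p.rates, apportionment="total")
    rates = propensities(p.initial, 0.0, total, p.space)
    assert sum(rates.values()) == pytest.approx(130.0)


def test_empty_state_has_zero_rates():
    p = preset_scenario("drug_resistant_stable")
    pop = dict(p.initial, **{"G-Tp": 0})
    rates = propensities(pop, 0.0, p.rates, p.space, rescue=False)
    assert all(v == 0 for k, v in rates.items() if len(k) > 1 and k[1] == "G-Tp")


def test_resistant_death_at_drug_onset():
    p = preset_scenario("drug_resistant_stable")
    pop = {s: 0 for s in p.space.states}
    pop["G-R"] = 10
    rates = propensities(pop, p.rates.drug_time, p.rates, p.space, rescue=False)
    assert rates[("death", "G-R")] == pytest.approx(22.0)


def test_resistant_death_coefficient_decay():
    p = preset_scenario("drug_resistant_stable")
    assert resistant_death_coefficient(2.0, p.rates, "G-R") == pytest.approx(2.2)
    grid = np.linspace(2.0, 20.0, 50)
    vals = [resistant_death_coefficient(t, p.rates, "G-R") for t in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    # alternative decay divisors of the sensitivity presets
    fast = preset_scenario("s1_low_resistant_death").rates
    slow = preset_scenario("s1_high_resistant_death").rates
    assert resistant_death_coefficient(12.0, fast, "G-R") == pytest.approx(
        2.2 * np.exp(-1.0)
    )
    assert resistant_death_coefficient(12.0, slow, "G-R") == pytest.approx(
        2.2 * np.exp(-0.1)
    )


def test_negative_population_rejected():
    p = preset_scenario("control")
    with pytest.raises(ValueError, match="nonnegative"):
        propensities(dict(p.initial, Q=-1), 0.0, p.rates, p.space)


def test_rescue_zeroes_death_and_resistant_channel():
    p = preset_scenario("drug_resistant_stable")
    pop = {s: 20 for s in p.space.states}
    pop["G-Tp"] = 9
    raw = propensities(pop, 3.0, p.rates, p.space, rescue=False)
    rescued = apply_rescue_constraint(pop, raw, p.space)
    assert rescued[("death", "G-Tp")] == 0.0
    assert rescued[("transition", "G-Tp", "G-R")] == 0.0
    # lateral transitions and births of the depleted state are untouched
    assert rescued[("transition", "G-Tp", "Q")] == raw[("transition", "G-Tp", "Q")]
    assert rescued[("birth", "G-Tp")] == raw[("birth", "G-Tp")]
    # other states untouched
    assert rescued[("death", "GS-Tp")] == raw[("death", "GS-Tp")]


def test_rescue_boundary_is_strict():
    p = preset_scenario("drug_resistant_stable")
    pop = {s: 20 for s in p.space.states}
    pop["G-Tp"] = 10
    raw = propensities(pop, 3.0, p.rates, p.space, rescue=False)
    assert apply_rescue_constraint(pop, raw, p.space) == raw


def test_rescue_ignores_resistant_states():
    p = preset_scenario("drug_resistant_stable")
    pop = {s: 20 for s in p.space.states}
    pop["G-R"] = 5
    raw = propensities(pop, 3.0, p.rates, p.space, rescue=False)
    assert apply_rescue_constraint(pop, raw, p.space)[("death", "G-R")] == raw[
        ("death", "G-R")
    ]


def test_control_and_drug_sensitive_identical_pre_drug():
    c = preset_scenario("control")
    d = preset_scenario("drug_sensitive")
    pop = {s: 13 for s in c.space.states}
    assert propensities(pop, 1.5, c.rates, c.space) == propensities(
        pop, 1.5, d.rates, d.space
    )


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    counts=st.lists(st.integers(0, 500), min_size=7, max_size=7),
    t=st.floats(0.0, 19.9),
    name=st.sampled_from(["control", "drug_resistant_stable"]),
)
def test_propensities_homogeneous_degree_one(counts, t, name):
    # doubling every count doubles every rate (rescue disabled: the count
    # threshold is deliberately not scale-invariant)
    p = preset_scenario(name)
    pop = dict(zip(p.space.states, counts))
    double = {k: 2 * v for k, v in pop.items()}
    r1 = propensities(pop, t, p.rates, p.space, rescue=False)
    r2 = propensities(double, t, p.rates, p.space, rescue=False)
    for k, v in r1.items():
        assert r2[k] == pytest.approx(2 * v, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    counts=st.lists(st.integers(0, 200), min_size=7, max_size=7),
    t=st.floats(0.0, 19.9),
    rescue=st.booleans(),
    name=st.sampled_from(["control", "drug_sensitive", "drug_resistant_stable"]),
)
def test_kernel_propensity_sum_matches_python(counts, t, rescue, name):
    # the compiled kernel and the reference implementation agree on the
    # total event rate at arbitrary states and times
    p = preset_scenario(name)
    pop = dict(zip(p.space.states, counts))
    expected = sum(propensities(pop, t, p.rates, p.space, rescue=rescue).values())
    packed = pack_scenario(p.rates, p.space)
    lam = total_propensity(
        pack_population(pop, p.space), t,
        packed["cb_pre"], packed["cd_pre"], packed["ct_pre"],
        packed["cb_post"], packed["cd_post"], packed["ct_post"],
        packed["is_res"], packed["lat_dest"], packed["lat_cnt"], packed["res_dest"],
        p.rates.drug_time, p.rates.resistant_death_divisor, 1,
        1 if rescue else 0, p.rates.rescue_threshold,
        1 if p.rates.apportionment == "per_destination" else 0,
    )
    assert lam == pytest.approx(expected, rel=1e-12, abs=1e-12)
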