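"""SSA engine: determinism, event bookkeeping, clock draws, lock-in ladder."""

import numpy as np
import pytest

from epilock.ssa import (
    SwitchChain,
    advance_clock,
    simulate_trajectory,
    switch_event,
)
from epilock.states import (
    Preset,
    ScenarioRates,
    StateRates,
    StateSpace,
    preset_scenario,
)


@pytest.fixture(scope="module")
def stable():
    return preset_scenario("drug_resistant_stable")


def test_identical_seed_identical_trajectory(stable):
    a = simulate_trajectory(stable, seed=42, horizon=4.0)
    b = simulate_trajectory(stable, seed=42, horizon=4.0)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.counts, b.counts)
    assert a.n_events == b.n_events


def test_different_seeds_differ(stable):
    a = simulate_trajectory(stable, seed=1, horizon=4.0)
    b = simulate_trajectory(stable, seed=2, horizon=4.0)
    assert not np.array_equal(a.times, b.times)


def test_times_strictly_increasing(stable):
    a = simulate_trajectory(stable, seed=7, horizon=5.0)
    assert np.all(np.diff(a.times) > 0)


def test_control_never_produces_resistant_cells():
    control = preset_scenario("control")
    traj = simulate_trajectory(control, seed=3, horizon=6.0)
    for s in ("G-R", "GS-R"):
        assert np.all(traj.counts[:, traj.states.index(s)] == 0)


@pytest.mark.parametrize("mode,p_off", [("single_step", None), ("multi_step", 0.5)])
def test_event_conservation_rules(stable, mode, p_off):
    # births/deaths change the total by exactly +-1 in one state;
    # transitions and completed lock-ins conserve the total
    switch = SwitchChain(p_off) if p_off is not None else None
    traj = simulate_trajectory(stable, mode=mode, switch=switch, seed=11, horizon=5.0)
    counts = np.vstack([traj.initial[None, :], traj.counts])
    diffs = np.diff(counts, axis=0)
    totals = diffs.sum(axis=1)
    for k, tot, d in zip(traj.kinds, totals, diffs):
        if k == 0:
            assert tot == 1 and np.sum(d != 0) == 1
        elif k == 1:
            assert tot == -1 and np.sum(d != 0) == 1
        elif k == 2:
            assert tot == 0 and np.sum(d == 1) == 1 and np.sum(d == -1) == 1
        else:  # resistant channel: conversion or (multi-step) a silent flip
            assert tot == 0
            assert np.sum(d != 0) in (0, 2)


def test_forward_lock_in_resistant_only_shrinks_by_death(stable):
    traj = simulate_trajectory(
        stable, mode="multi_step", switch=SwitchChain.forward_lock_in(),
        seed=5, horizon=6.0,
    )
    res_idx = [traj.states.index(s) for s in ("G-R", "GS-R")]
    counts = np.vstack([traj.initial[None, :], traj.counts])
    res = counts[:, res_idx].sum(axis=1)
    drops = np.nonzero(np.diff(res) < 0)[0]
    for i in drops:
        assert traj.kinds[i] == 1  # death in a resistant state
        assert traj.sources[i] in res_idx


def test_extinct_start_ends_immediately(stable):
    empty = {s: 0 for s in stable.space.states}
    traj = simulate_trajectory(stable, init=empty, seed=1, horizon=5.0)
    assert traj.extinct
    assert traj.n_events == 0


def test_frozen_state_advances_to_horizon():
    space = StateSpace(
        states=("A",), sensitive=("A",), resistant=(), lateral={"A": ()},
        to_resistant={},
    )
    rates = ScenarioRates(
        "inert", {"A": StateRates(0, 0, 0, 0, 0, 0)}, drug_time=2.0, t_max=20.0
    )
    traj = simulate_trajectory(Preset(rates, space, {"A": 5}), seed=1, horizon=9.0)
    assert traj.frozen
    assert traj.t_final == pytest.approx(9.0)
    assert traj.final_counts() == {"A": 5}


def test_multi_step_requires_switch(stable):
    with pytest.raises(ValueError, match="SwitchChain"):
        simulate_trajectory(stable, mode="multi_step", seed=0)


def test_per_cell_ladder_occupancy_tracks_population(stable):
    # in per-cell scope the ladder levels of each laddered state must sum
    # to that state's population after every event
    traj = simulate_trajectory(
        stable, mode="multi_step", switch=SwitchChain(0.5, scope="per_cell"),
        seed=9, horizon=4.0,
    )
    for s in ("G-Tp", "G-Tr", "GS-Tp", "GS-Tr"):
        i = traj.states.index(s)
        assert np.array_equal(traj.ladders[:, i, :].sum(axis=1), traj.counts[:, i])


def test_advance_clock_single_event():
    rng = np.random.default_rng(0)
    tau, ev = advance_clock({("birth", "A"): 4.0}, 0.0, rng)
    assert ev == ("birth", "A") and tau > 0


def test_advance_clock_zero_total_raises():
    with pytest.raises(ValueError, match="positive"):
        advance_clock({("death", "A"): 0.0}, 0.0, np.random.default_rng(0))


def test_advance_clock_proportional_selection():
    rng = np.random.default_rng(123)
    rates = {"a": 3.0, "b": 1.0}
    picks = sum(advance_clock(rates, 0.0, rng)[1] == "a" for _ in range(20_000))
    assert picks / 20_000 == pytest.approx(0.75, abs=0.01)


def test_advance_clock_exponential_mean():
    # empirical mean of tau at total rate 150 within 1%
    rng = np.random.default_rng(7)
    lam = 150.0
    taus = [advance_clock({"x": lam}, 0.0, rng)[0] for _ in range(100_000)]
    assert np.mean(taus) == pytest.approx(1.0 / lam, rel=0.01)


def test_switch_event_forward_completion():
    rng = np.random.default_rng(0)
    level, converted = switch_event(2, SwitchChain.forward_lock_in(), rng)
    assert level == 3 and converted


def test_switch_event_level_zero_cannot_go_down():
    rng = np.random.default_rng(0)
    for _ in range(50):
        level, converted = switch_event(0, SwitchChain(0.5), rng)
        assert level == 1 and not converted


def test_switch_event_invalid_level():
    with pytest.raises(ValueError):
        switch_event(3, SwitchChain(0.5), np.random.default_rng(0))


@pytest.mark.parametrize("p_off", [0.0, 0.5])
def test_ladder_walk_matches_matrix_power_oracle(p_off):
    # empirical absorption frequency within m firings vs the exact
    # (embedded matrix)^m linear-algebra solve
    chain = SwitchChain(p_off)
    m, n = 8, 4000
    rng = np.random.default_rng(2024)
    hits = 0
    for _ in range(n):
        level = 0
        for _ in range(m):
            level, converted = switch_event(level, chain, rng)
            if converted:
                hits += 1
                break
    exact = chain.absorption_probability(m)
    se = np.sqrt(max(exact * (1 - exact), 1e-12) / n)
    assert abs(hits / n - exact) <= max(3 * se, 1e-9)


def test_absorption_probability_limits():
    assert SwitchChain(0.0).absorption_probability(3) == pytest.approx(1.0)
    assert SwitchChain(0.0).absorption_probability(2) == 0.0
    assert SwitchChain(0.9).absorption_probability(3) == pytest.approx(0.01)  # (1-p)^2
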