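"""Replicate ensembles, reduction statistics and the mean-field oracle.

The headline statistic of the model family is the *reduction percentage*:
how much an instability mechanism (random transition-rate multipliers in
the single-step model, bidirectional lock-in switches in the multi-step
model) shrinks the day-6 ensemble-mean resistant population (G-R + GS-R)
relative to its stable / forward-lock-in counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from .ssa import SwitchChain, normalize_seed, pack_population, pack_scenario
from .states import Preset, ScenarioRates, StateSpace, preset_scenario

__all__ = [
    "EnsembleSummary",
    "run_ensemble",
    "reduction_percent",
    "instability_sweep",
    "mean_field_solution",
]


@dataclass
class EnsembleSummary:
    """Per-time mean +- SD of state counts over independent replicates."""

    states: tuple[str, ...]
    report_times: np.ndarray          # days
    counts: np.ndarray                # int64[R, T, S] raw replicate counts
    statuses: np.ndarray
    event_counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=1) if self.n_replicates > 1 else np.zeros(
            self.counts.shape[1:]
        )

    def _time_index(self, at: float) -> int:
        idx = np.nonzero(np.isclose(self.report_times, at))[0]
        if idx.size == 0:
            raise KeyError(f"no report time {at}; have {self.report_times}")
        return int(idx[0])

    def group_stats(self, states, at: float) -> tuple[float, float, float]:
        """(mean, SD, SE) of the summed count over ``states`` at time ``at``."""
        ti = self._time_index(at)
        cols = [self.states.index(s) for s in states]
        summed = self.counts[:, ti, cols].sum(axis=1)
        mean = float(summed.mean())
        sd = float(summed.std(ddof=1)) if self.n_replicates > 1 else 0.0
        return mean, sd, sd / np.sqrt(self.n_replicates)

    def to_frame(self) -> pd.DataFrame:
        """Tidy summary table: one row per (time, state)."""
        T, S = self.mean.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.report_times, S),
                "state": np.tile(self.states, T),
                "mean": self.mean.ravel(),
                "sd": self.sd.ravel(),
                "n_replicates": self.n_replicates,
            }
        )


def replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate kernel seeds derived from a master seed."""
    ss = np.random.SeedSequence(normalize_seed(seed))
    return (ss.generate_state(n, dtype=np.uint32).astype(np.int64)) & 0x7FFFFFFF


def run_ensemble(
    scenario: ScenarioRates | Preset,
    space: StateSpace | None = None,
    init: dict[str, int] | None = None,
    mode: str = "single_step",
    switch: SwitchChain | None = None,
    n_replicates: int = 2000,
    report_times=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    seed: int = 0,
    max_events: int = 10_000_000,
) -> EnsembleSummary:
    """Run ``n_replicates`` independent trajectories and summarize them.

    Replicate ``r`` uses an independent stream derived from ``(seed, r)``;
    the same master seed reproduces the ensemble exactly.  Counts at each
    report time are last-value interpolations of the jump trajectories.
    """
    if isinstance(scenario, Preset):
        space = space or scenario.space
        init = init or scenario.initial
        scenario = scenario.rates
    if space is None or init is None:
        raise ValueError("space and init are required with a bare ScenarioRates")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if mode == "multi_step" and switch is None:
        raise ValueError("multi_step mode requires a SwitchChain")

    packed = pack_scenario(scenario, space)
    n0 = pack_population(init, space)
    rt = np.asarray(sorted(report_times), dtype=float)
    t_end = float(rt[-1])
    R, T, S = n_replicates, len(rt), len(space.states)
    out = np.zeros((R, T, S), np.int64)
    statuses = np.zeros(R, np.int64)
    nev = np.zeros(R, np.int64)
    seeds = replicate_seeds(seed, n_replicates)
    _kernels.ensemble_run(
        seeds, n0,
        packed["cb_pre"], packed["cd_pre"], packed["ct_pre"],
        packed["cb_post"], packed["cd_post"], packed["ct_post"],
        packed["is_res"], packed["lat_dest"], packed["lat_cnt"], packed["res_dest"],
        scenario.drug_time, t_end, scenario.resistant_death_divisor,
        1 if scenario.resistant_death_decay else 0,
        1 if scenario.instability == "random_u" else 0,
        1 if scenario.rescue else 0, scenario.rescue_threshold,
        1 if scenario.apportionment == "per_destination" else 0,
        1 if mode == "multi_step" else 0,
        switch.p_off if switch is not None else 0.0,
        1 if (switch is not None and switch.scope == "per_cell") else 0,
        rt, out, statuses, nev, max_events,
    )
    return EnsembleSummary(
        states=space.states,
        report_times=rt,
        counts=out,
        statuses=statuses,
        event_counts=nev,
        metadata={
            "scenario": scenario.name,
            "mode": mode,
            "p_off": switch.p_off if switch is not None else None,
            "seed": normalize_seed(seed),
            "single_replicate": n_replicates == 1,
        },
    )


def reduction_percent(
    baseline: EnsembleSummary,
    treated: EnsembleSummary,
    states=None,
    at: float = 6.0,
) -> float:
    """100 * (mean_baseline - mean_treated) / mean_baseline over summed states.

    ``states`` defaults to the absorbing (resistant) states of the baseline
    summary's space.  Returns NaN when the baseline mean is zero (undefined).
    """
    if states is None:
        states = [s for s in baseline.states if s.endswith("-R") or s.endswith("MGMT")]
    mb, _, _ = baseline.group_stats(states, at)
    mt, _, _ = treated.group_stats(states, at)
    if mb == 0:
        return float("nan")
    return 100.0 * (mb - mt) / mb


def instability_sweep(
    p_off_grid,
    n_replicates: int = 2000,
    seed: int = 0,
    scenario: str | Preset = "drug_resistant_stable",
    report_time: float = 6.0,
) -> pd.DataFrame:
    """Mean day-6 resistant count of the multi-step model across p_off values.

    One independent ensemble per grid point (streams derived from
    ``(seed, index)``), shared scenario.  Returns a table with columns
    p_off, mean_resistant, sd, se, n_replicates.
    """
    preset = preset_scenario(scenario) if isinstance(scenario, str) else scenario
    rows = []
    for i, p_off in enumerate(p_off_grid):
        if not 0.0 <= p_off < 1.0:
            raise ValueError("p_off values must lie in [0, 1)")
        summ = run_ensemble(
            preset,
            mode="multi_step",
            switch=SwitchChain(p_off=p_off),
            n_replicates=n_replicates,
            report_times=(report_time,),
            seed=normalize_seed(seed) + 7919 * i,
        )
        mean, sd, se = summ.group_stats(preset.space.resistant, report_time)
        rows.append(
            {
                "p_off": p_off,
                "mean_resistant": mean,
                "sd": sd,
                "se": se,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)


def _mean_field_matrix(
    rates: ScenarioRates, space: StateSpace, post: bool, t: float
) -> np.ndarray:
    from .states import resistant_death_coefficient

    S = len(space.states)
    idx = {s: i for i, s in enumerate(space.states)}
    A = np.zeros((S, S))
    u = rates.u_mean if rates.instability == "random_u" else 1.0
    for s in space.states:
        i = idx[s]
        cb, cd, ct = rates.coefficients(s, t)
        if s in space.resistant and post:
            cd = resistant_death_coefficient(t, rates, s)
        A[i, i] += cb - cd
        dests = space.destinations(s, post_drug=post)
        if dests and ct > 0:
            share = ct * u if rates.apportionment == "per_destination" else ct * u / len(dests)
            for d in dests:
                A[idx[d], i] += share
                A[i, i] -= share
    return A


def mean_field_solution(
    scenario: ScenarioRates | Preset,
    space: StateSpace | None = None,
    init: dict[str, int] | None = None,
    times=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
) -> pd.DataFrame:
    """First-moment ODE solution dE[n]/dt = A(t) E[n] of the jump process.

    The linear oracle for single-step SSA ensemble means.  The rescue
    constraint is *ignored* (it is nonlinear in the counts); compare only
    against ensembles run with ``rescue=False``.  In instability mode the
    transition coefficients are scaled by the mean of the instability
    multiplier (``u_mean``).
    """
    if isinstance(scenario, Preset):
        space = space or scenario.space
        init = init or scenario.initial
        scenario = scenario.rates
    if space is None or init is None:
        raise ValueError("space and init are required with a bare ScenarioRates")

    y0 = pack_population(init, space).astype(float)
    times = np.asarray(sorted(times), dtype=float)
    t_end = float(times[-1])

    def rhs(t, y):
        A = _mean_field_matrix(scenario, space, t >= scenario.drug_time, t)
        return A @ y

    # integrate piecewise around the drug-onset discontinuity
    breaks = [0.0]
    if 0.0 < scenario.drug_time < t_end:
        breaks.append(scenario.drug_time)
    breaks.append(t_end)
    segs = []
    y = y0
    eval_times = np.unique(np.concatenate([[0.0], times]))
    for a, b in zip(breaks[:-1], breaks[1:]):
        te = eval_times[(eval_times >= a) & (eval_times <= b)]
        te = np.unique(np.concatenate([[a], te, [b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=te, rtol=1e-9, atol=1e-10)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"mean-field integration failed on [{a}, {b}]")
        segs.append((sol.t, sol.y))
        y = sol.y[:, -1]
    all_t = np.concatenate([s[0] for s in segs])
    all_y = np.concatenate([s[1] for s in segs], axis=1)
    out = np.empty((len(times), len(space.states)))
    for j, t in enumerate(times):
        k = int(np.argmin(np.abs(all_t - t)))
        out[j] = all_y[:, k]
    return pd.DataFrame(out, index=pd.Index(times, name="time"), columns=space.states)
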