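"""Direct stochastic simulation of cell-state trajectories.

Implements the Gillespie direct method over the birth/death/transition
channels defined in :mod:`epilock.states`, in two modes:

``single_step``
    a sensitive cell that fires its resistant channel converts at once;

``multi_step``
    the resistant channel fires *switch events* on a three-switch lock-in
    ladder; only when all three switches are on does a cell convert.  With
    switch-off probability ``p_off = 0`` the ladder is a forward lock-in;
    ``p_off > 0`` models epigenetic instability.  By default the ladder is
    scoped to the transition pathway (one ladder per sensitive->resistant
    pair, reset after each completed conversion); a per-cell variant, in
    which every cell carries its own ladder and loses its progress on
    death or lateral transition, is available via ``SwitchChain(scope=
    "per_cell")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .states import Preset, ScenarioRates, StateSpace

__all__ = [
    "SwitchChain",
    "Trajectory",
    "simulate_trajectory",
    "advance_clock",
    "switch_event",
    "pack_scenario",
]

N_SWITCHES = 3


@dataclass(frozen=True)
class SwitchChain:
    """Three-switch lock-in ladder of the sensitive->resistant pathways.

    ``p_off`` is the probability that a firing flips one on-switch off
    (possible only above level 0); otherwise one off-switch turns on
    (``p_on = 1 - p_off``).  Reaching level 3 completes a lock-in and
    converts one cell to the resistant state.  ``scope`` places the ladder
    on the transition pathway (default; the ladder persists through
    population turnover and resets after each conversion) or on each
    individual cell (``"per_cell"``: progress is lost when the cell dies
    or transitions laterally).
    """

    p_off: float = 0.0
    scope: str = "pathway"  # "pathway" | "per_cell"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_off <= 1.0:
            raise ValueError("p_off must lie in [0, 1]")
        if self.scope not in ("pathway", "per_cell"):
            raise ValueError(f"unknown ladder scope {self.scope!r}")

    @property
    def p_on(self) -> float:
        return 1.0 - self.p_off

    @classmethod
    def forward_lock_in(cls) -> "SwitchChain":
        return cls(p_off=0.0)

    @classmethod
    def bidirectional(cls, p_off: float) -> "SwitchChain":
        return cls(p_off=p_off)

    def embedded_matrix(self) -> np.ndarray:
        """Transition matrix of ladder level per switch firing (4 levels)."""
        p = self.p_off
        P = np.zeros((N_SWITCHES + 1, N_SWITCHES + 1))
        P[0, 1] = 1.0  # no on-switch available to turn off at level 0
        for k in (1, 2):
            P[k, k - 1] = p
            P[k, k + 1] = 1.0 - p
        P[3, 3] = 1.0
        return P

    def absorption_probability(self, n_firings: int, start_level: int = 0) -> float:
        """Exact probability of lock-in within ``n_firings`` switch events.

        Linear-algebra solve of the ladder chain (matrix power of the
        embedded transition matrix); the independent oracle for the SSA
        switch mechanics.
        """
        P = np.linalg.matrix_power(self.embedded_matrix(), n_firings)
        return float(P[start_level, N_SWITCHES])


def switch_event(
    level: int, chain: SwitchChain, rng: np.random.Generator
) -> tuple[int, bool]:
    """Apply one switch firing to a cell at ladder ``level``.

    Returns (new_level, converted).  ``converted`` is True when the third
    switch turns on and the cell leaves the ladder for the resistant state.
    """
    if not 0 <= level <= N_SWITCHES - 1:
        raise ValueError("ladder level must be 0, 1 or 2")
    if level >= 1 and rng.random() < chain.p_off:
        return level - 1, False
    if level == N_SWITCHES - 1:
        return N_SWITCHES, True
    return level + 1, False


def advance_clock(
    rates: dict, t: float, rng: np.random.Generator
) -> tuple[float, tuple]:
    """One SSA clock advance: waiting time ~ Exp(sum of rates), event
    chosen with probability proportional to its rate."""
    keys = list(rates)
    vals = np.fromiter((rates[k] for k in keys), dtype=float, count=len(keys))
    if np.any(vals < 0):
        raise ValueError("negative event rate")
    lam = vals.sum()
    if lam <= 0:
        raise ValueError("total propensity must be positive")
    tau = rng.exponential(1.0 / lam)
    pick = np.searchsorted(np.cumsum(vals), rng.random() * lam, side="right")
    pick = min(pick, len(keys) - 1)
    return tau, keys[pick]


@dataclass
class Trajectory:
    """Event-resolved record of one stochastic run."""

    states: tuple[str, ...]
    initial: np.ndarray           # int64[S]
    times: np.ndarray             # event times, strictly increasing
    counts: np.ndarray            # int64[n_events, S], counts after event
    kinds: np.ndarray             # 0 birth, 1 death, 2 lateral, 3 resistant channel
    sources: np.ndarray
    dests: np.ndarray
    ladders: np.ndarray | None    # int64[n_events, S, 3] in multi-step mode
    status: int
    n_events: int
    t_final: float
    seed: int
    mode: str

    @property
    def frozen(self) -> bool:
        return self.status == _kernels.STATUS_FROZEN

    @property
    def extinct(self) -> bool:
        return self.status == _kernels.STATUS_EXTINCT

    @property
    def truncated(self) -> bool:
        return self.status == _kernels.STATUS_TRUNCATED

    def final_counts(self) -> dict[str, int]:
        arr = self.counts[-1] if len(self.times) else self.initial
        return {s: int(arr[i]) for i, s in enumerate(self.states)}

    def to_frame(self):
        """Tidy long table: one row per (event time, state)."""
        import pandas as pd

        n = len(self.times)
        times = np.concatenate([[0.0], self.times])
        counts = np.vstack([self.initial[None, :], self.counts])
        return pd.DataFrame(
            {
                "time": np.repeat(times, len(self.states)),
                "state": np.tile(self.states, n + 1),
                "count": counts.ravel(),
            }
        )


def pack_scenario(rates: ScenarioRates, space: StateSpace):
    """Flatten a scenario + state space into the kernel's array form."""
    S = len(space.states)
    idx = {s: i for i, s in enumerate(space.states)}
    cb_pre = np.zeros(S)
    cd_pre = np.zeros(S)
    ct_pre = np.zeros(S)
    cb_post = np.zeros(S)
    cd_post = np.zeros(S)
    ct_post = np.zeros(S)
    for s in space.states:
        r = rates.rates[s]
        i = idx[s]
        cb_pre[i], cd_pre[i], ct_pre[i] = r.birth_pre, r.death_pre, r.trans_pre
        cb_post[i], cd_post[i], ct_post[i] = r.birth_post, r.death_post, r.trans_post
    is_res = np.array([1 if s in space.resistant else 0 for s in space.states], np.int64)
    max_lat = max((len(space.lateral.get(s, ())) for s in space.states), default=0)
    lat_dest = np.full((S, max(max_lat, 1)), -1, np.int64)
    lat_cnt = np.zeros(S, np.int64)
    res_dest = np.full(S, -1, np.int64)
    for s in space.states:
        i = idx[s]
        for j, d in enumerate(space.lateral.get(s, ())):
            lat_dest[i, j] = idx[d]
        lat_cnt[i] = len(space.lateral.get(s, ()))
        if s in space.to_resistant:
            res_dest[i] = idx[space.to_resistant[s]]
    return dict(
        cb_pre=cb_pre, cd_pre=cd_pre, ct_pre=ct_pre,
        cb_post=cb_post, cd_post=cd_post, ct_post=ct_post,
        is_res=is_res, lat_dest=lat_dest, lat_cnt=lat_cnt, res_dest=res_dest,
    )


def pack_population(pop: dict[str, int], space: StateSpace) -> np.ndarray:
    arr = np.zeros(len(space.states), np.int64)
    for i, s in enumerate(space.states):
        n = int(pop.get(s, 0))
        if n < 0:
            raise ValueError(f"negative count for state {s!r}")
        arr[i] = n
    return arr


def normalize_seed(seed: int) -> int:
    return int(seed) % (2**31 - 1)


def simulate_trajectory(
    scenario: ScenarioRates | Preset,
    space: StateSpace | None = None,
    init: dict[str, int] | None = None,
    mode: str = "single_step",
    switch: SwitchChain | None = None,
    seed: int = 0,
    horizon: float | None = None,
    record_events: bool = True,
    max_events: int = 2_000_000,
    record_cap: int = 200_000,
) -> Trajectory:
    """Simulate one trajectory with the direct SSA.

    ``scenario`` may be a :class:`Preset` (its space and initial population
    are then used unless overridden).  ``horizon`` defaults to the
    scenario's ``t_max``.  Identical arguments and seed give bit-identical
    trajectories.  Event logging stops after ``record_cap`` events (the
    simulation itself continues to the horizon or ``max_events``).
    """
    if isinstance(scenario, Preset):
        space = space or scenario.space
        init = init or scenario.initial
        scenario = scenario.rates
    if space is None or init is None:
        raise ValueError("space and init are required with a bare ScenarioRates")
    if mode not in ("single_step", "multi_step"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "multi_step" and switch is None:
        raise ValueError("multi_step mode requires a SwitchChain")

    packed = pack_scenario(scenario, space)
    n = pack_population(init, space)
    S = len(space.states)
    ladder = np.zeros((S, 3), np.int64)
    per_cell = switch is not None and switch.scope == "per_cell"
    if per_cell:
        for i in range(S):
            if packed["res_dest"][i] >= 0:
                ladder[i, 0] = n[i]

    t_end = float(horizon if horizon is not None else scenario.t_max)
    cap = min(max_events, record_cap) if record_events else 0
    ev_times = np.zeros(cap)
    ev_kind = np.zeros(cap, np.int64)
    ev_src = np.zeros(cap, np.int64)
    ev_dst = np.zeros(cap, np.int64)
    ev_pops = np.zeros((cap, S), np.int64)
    ev_ladder = np.zeros((cap, S, 3), np.int64)
    rt = np.empty(0)
    oc = np.empty((0, S), np.int64)

    kseed = normalize_seed(seed)
    initial = n.copy()
    nrec, nev, status, t_final = _kernels.ssa_run(
        kseed, n, ladder, 0.0,
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
        1 if per_cell else 0,
        rt, oc,
        ev_times, ev_kind, ev_src, ev_dst, ev_pops, ev_ladder,
        max_events,
    )
    return Trajectory(
        states=space.states,
        initial=initial,
        times=ev_times[:nrec].copy(),
        counts=ev_pops[:nrec].copy(),
        kinds=ev_kind[:nrec].copy(),
        sources=ev_src[:nrec].copy(),
        dests=ev_dst[:nrec].copy(),
        ladders=ev_ladder[:nrec].copy() if mode == "multi_step" else None,
        status=status,
        n_events=int(nev),
        t_final=float(t_final),
        seed=kseed,
        mode=mode,
    )
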