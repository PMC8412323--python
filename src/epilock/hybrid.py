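"""Hybrid stochastic-deterministic co-simulation of cell states and TMZ-MGMT.

The multi-step cell-state model (with the lock-in ladder feeding the
MGMT-expressing states G-Tp-MGMT / GS-Tp-MGMT instead of explicit
resistant states) and the deterministic PK/PD system are advanced
alternately over short synchronization windows (operator splitting):

1. the SSA advances the integer cell counts for one window, with death
   coefficients computed from the O6mG concentration frozen at the window
   start (more adducts, more death);
2. the ODE advances for the same window with the transcription gate set
   from the current cell populations (the MGMT-state fraction of all
   G/GS cells).

Cell-model coefficients are those of the multi-step model (birth 2/day
for G/GS states, transitions 1/day, baseline death 1/day) re-expressed
per hour; the lock-in channel toward the MGMT states opens with the first
TMZ dose.  Time inside this module is in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .pkpd import SPECIES, DoseSchedule, PKPDParameters, integrate, steady_state
from .ssa import SwitchChain, normalize_seed, pack_population, pack_scenario
from .states import StateSpace, hybrid_space

__all__ = [
    "HybridConfig",
    "HybridResult",
    "HYBRID_INITIAL",
    "gate_from_population",
    "death_rate_from_o6mg",
    "calibrate_kill_gain",
    "run_hybrid",
    "run_hybrid_ensemble",
]

HYBRID_INITIAL = {
    "Q": 80,
    "G-Tp": 7,
    "G-Tr": 7,
    "GS-Tp": 3,
    "GS-Tr": 3,
    "G-Tp-MGMT": 0,
    "GS-Tp-MGMT": 0,
}

#: Per-day cell coefficients of the hybrid model, by state (multi-step values).
_CB_DAY = {"Q": 0.0, "G-Tp": 2.0, "G-Tr": 2.0, "GS-Tp": 2.0, "GS-Tr": 2.0,
           "G-Tp-MGMT": 2.0, "GS-Tp-MGMT": 2.0}
_CT_DAY = {"Q": 1.0, "G-Tp": 1.0, "G-Tr": 1.0, "GS-Tp": 1.0, "GS-Tr": 1.0,
           "G-Tp-MGMT": 0.0, "GS-Tp-MGMT": 0.0}
_CD_BASE_DAY = {s: 1.0 for s in HYBRID_INITIAL}


@dataclass(frozen=True)
class HybridConfig:
    """Coupling configuration of the hybrid model.

    The O6mG -> death mapping is ``base + gain * o6mg`` (day^-1), optionally
    saturating as ``base + gain * o6mg / (1 + o6mg / saturation_o6mg)``.
    ``kill_gain_per_o6mg=None`` triggers a calibration run: the gain is set
    so that the repair-free mean post-dose O6mG level maps to the
    drug-phase death coefficient 2.2/day of the pure cell-state models.
    MGMT-expressing states feel only ``mgmt_kill_fraction`` of the kill
    term (their chemical protection is already explicit in the ODE).
    """

    dt_h: float = 1.0
    horizon_h: float = 144.0
    kill_base_per_day: float = 1.0
    kill_gain_per_o6mg: float | None = None
    kill_target_per_day: float = 2.2
    mgmt_kill_fraction: float = 0.2
    saturation_o6mg: float | None = None
    gate_mode: str = "fraction"  # "fraction" | "threshold"
    gate_threshold: float = 0.5
    ode_dt_h: float = 0.02
    rescue: bool = True
    rescue_threshold: int = 10
    apportionment: str = "per_destination"
    max_events_per_window: int = 1_000_000

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError("dt_h must be > 0")
        if self.kill_gain_per_o6mg is not None and self.kill_gain_per_o6mg < 0:
            raise ValueError("kill gain must be >= 0")
        if self.gate_mode not in ("fraction", "threshold"):
            raise ValueError(f"unknown gate mode {self.gate_mode!r}")


def gate_from_population(pop: dict[str, int]) -> float:
    """MGMT-state fraction of all G/GS cells (quiescent cells excluded).

    Returns 0 for an empty denominator.
    """
    mgmt = sum(v for k, v in pop.items() if k.endswith("MGMT"))
    total = sum(v for k, v in pop.items() if k != "Q")
    return mgmt / total if total > 0 else 0.0


def death_rate_from_o6mg(o6mg: float, cfg: HybridConfig) -> float:
    """Death coefficient (day^-1) of a non-MGMT state at adduct level o6mg."""
    if o6mg < 0:
        raise ValueError("o6mg must be >= 0")
    if cfg.kill_gain_per_o6mg is None:
        raise ValueError("kill gain not set; call calibrate_kill_gain first")
    if cfg.saturation_o6mg:
        excess = cfg.kill_gain_per_o6mg * o6mg / (1.0 + o6mg / cfg.saturation_o6mg)
    else:
        excess = cfg.kill_gain_per_o6mg * o6mg
    return cfg.kill_base_per_day + excess


def calibrate_kill_gain(
    params: PKPDParameters,
    schedule: DoseSchedule,
    cfg: HybridConfig,
) -> float:
    """Kill gain mapping the mean repair-free post-dose O6mG to the
    drug-phase death coefficient of the pure cell-state models.

    Runs the PK cascade with the gate closed (no MGMT, no repair), averages
    O6mG from the first dose to the horizon, and solves
    base + gain * mean = target.
    """
    if schedule.n_doses == 0 or schedule.dose_concentration == 0:
        return 0.0
    df = integrate(
        params, schedule, gate_fn=0.0, horizon_h=cfg.horizon_h, grid_dt_h=0.25
    )
    post = df[df.index >= schedule.start_h]
    mean_o6mg = float(post["o6mg"].mean())
    if mean_o6mg <= 0:
        return 0.0
    return (cfg.kill_target_per_day - cfg.kill_base_per_day) / mean_o6mg


@dataclass
class HybridResult:
    """Joint output of one hybrid run on the synchronization grid."""

    species: pd.DataFrame        # time_h x PK/PD species
    cells: pd.DataFrame          # time_h x cell states (integer counts)
    gate: pd.Series              # gate value per window
    config: HybridConfig
    switch: SwitchChain
    seed: int
    status: int

    def terminal(self, column: str) -> float:
        return float(self.species[column].iloc[-1])


def _build_arrays(space: StateSpace):
    # reuse the scenario packer with a throwaway coefficient table
    from .states import ScenarioRates, StateRates

    tbl = {
        s: StateRates(
            _CB_DAY[s], _CD_BASE_DAY[s], _CT_DAY[s],
            _CB_DAY[s], _CD_BASE_DAY[s], _CT_DAY[s],
        )
        for s in space.states
    }
    packed = pack_scenario(ScenarioRates("hybrid", tbl), space)
    cb = packed["cb_post"]
    cd = packed["cd_post"]
    ct = packed["ct_post"]
    return packed, cb, cd, ct


def run_hybrid(
    switch: SwitchChain,
    params: PKPDParameters | None = None,
    schedule: DoseSchedule | None = None,
    cfg: HybridConfig | None = None,
    seed: int = 0,
    init: dict[str, int] | None = None,
) -> HybridResult:
    """Co-simulate cell states and PK/PD to the horizon; reproducible by seed."""
    params = params or PKPDParameters()
    schedule = schedule or DoseSchedule()
    cfg = cfg or HybridConfig()
    init = init or HYBRID_INITIAL
    if schedule.n_doses and cfg.horizon_h < schedule.dose_times[-1]:
        raise ValueError("horizon must cover the dose schedule")

    gain = cfg.kill_gain_per_o6mg
    if gain is None:
        gain = calibrate_kill_gain(params, schedule, cfg)

    space = hybrid_space()
    packed, cb, cd_base, ct = _build_arrays(space)
    n0 = pack_population(init, space)
    is_mgmt = packed["is_res"]

    n_windows = int(round(cfg.horizon_h / cfg.dt_h))
    if abs(n_windows * cfg.dt_h - cfg.horizon_h) > 1e-9:
        raise ValueError("horizon_h must be an integer number of windows")
    S = len(space.states)
    out_cells = np.zeros((n_windows + 1, S), np.int64)
    out_species = np.zeros((n_windows + 1, len(SPECIES)))
    out_gate = np.zeros(n_windows + 1)

    gate0 = gate_from_population(init)
    y0 = steady_state(params, gate0)
    dose_times = schedule.dose_times.astype(float)

    status = _kernels.hybrid_run(
        normalize_seed(seed), n0,
        cb, cd_base, ct,
        is_mgmt,
        packed["lat_dest"], packed["lat_cnt"], packed["res_dest"],
        1 if cfg.rescue else 0, cfg.rescue_threshold,
        1 if cfg.apportionment == "per_destination" else 0,
        switch.p_off,
        1 if switch.scope == "per_cell" else 0,
        gain, cfg.mgmt_kill_fraction,
        cfg.saturation_o6mg if cfg.saturation_o6mg else 0.0,
        1 if cfg.gate_mode == "threshold" else 0, cfg.gate_threshold,
        params.to_array(), dose_times, schedule.dose_concentration,
        cfg.dt_h, cfg.horizon_h, cfg.ode_dt_h,
        y0,
        out_cells, out_species, out_gate,
        cfg.max_events_per_window,
    )

    times = np.arange(n_windows + 1) * cfg.dt_h
    idx = pd.Index(times, name="time_h")
    return HybridResult(
        species=pd.DataFrame(out_species, index=idx, columns=SPECIES),
        cells=pd.DataFrame(out_cells, index=idx, columns=space.states),
        gate=pd.Series(out_gate, index=idx, name="gate"),
        config=cfg,
        switch=switch,
        seed=normalize_seed(seed),
        status=int(status),
    )


def run_hybrid_ensemble(
    switch: SwitchChain,
    n_replicates: int = 200,
    seed: int = 0,
    params: PKPDParameters | None = None,
    schedule: DoseSchedule | None = None,
    cfg: HybridConfig | None = None,
    init: dict[str, int] | None = None,
) -> dict:
    """Ensemble of hybrid runs: mean species/cell grids and terminal values.

    Returns a dict with 'species_mean' and 'cells_mean' DataFrames on the
    synchronization grid, per-replicate 'terminal' DataFrame (one row per
    replicate: terminal MGMT protein, O6mG and MGMT-state cell count) and
    the replicate count.
    """
    from .ensemble import replicate_seeds

    params = params or PKPDParameters()
    schedule = schedule or DoseSchedule()
    cfg = cfg or HybridConfig()
    if cfg.kill_gain_per_o6mg is None:
        # calibrate once and share across replicates
        cfg = HybridConfig(
            **{
                **cfg.__dict__,
                "kill_gain_per_o6mg": calibrate_kill_gain(params, schedule, cfg),
            }
        )
    seeds = replicate_seeds(seed, n_replicates)
    species_sum = None
    cells_sum = None
    terminal = []
    for r in range(n_replicates):
        res = run_hybrid(
            switch, params=params, schedule=schedule, cfg=cfg,
            seed=int(seeds[r]), init=init,
        )
        if species_sum is None:
            species_sum = res.species.copy()
            cells_sum = res.cells.astype(float).copy()
        else:
            species_sum += res.species
            cells_sum += res.cells
        mgmt_cells = int(
            res.cells.iloc[-1][[c for c in res.cells.columns if c.endswith("MGMT")]].sum()
        )
        terminal.append(
            {
                "mgmt_protein": res.terminal("mgmt_protein"),
                "o6mg": res.terminal("o6mg"),
                "mgmt_cells": mgmt_cells,
            }
        )
    return {
        "species_mean": species_sum / n_replicates,
        "cells_mean": cells_sum / n_replicates,
        "terminal": pd.DataFrame(terminal),
        "n_replicates": n_replicates,
        "p_off": switch.p_off,
    }
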