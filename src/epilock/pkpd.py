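"""Deterministic TMZ pharmacokinetics and MGMT transcription-translation.

Temozolomide (TMZ) given on a multiple-dose schedule enters the blood,
distributes to interstitial fluid and into cells, undergoes pH-dependent
chemical activation to a short-lived methylating cation, and a fraction of
the converted cation methylates DNA at guanine-O6 (the O6mG adduct).  The
repair protein MGMT is produced by a two-stage transcription-translation
model gated by the epigenetic state of the cell population (gate in
[0, 1]: 0 transcriptionally restrictive, 1 permissive) with a positive
feedback of the MGMT-O6mG complex on transcription.  MGMT is a suicide
repair protein: removing one adduct consumes one protein molecule into a
degraded complex.

Time base is hours; concentrations are model units normalized so that one
standard 150 mg/m^2 dose adds unit concentration to the blood compartment.
All rate constants are package defaults chosen to give realistic TMZ-like
kinetics (plasma half-life ~2 h, fast cation turnover, slow protein
turnover); they are assumptions of this implementation, not literature
values, and every one can be overridden or loaded from a parameter file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "DoseSchedule",
    "PKPDParameters",
    "pk_rhs",
    "mgmt_rhs",
    "full_rhs",
    "steady_state",
    "integrate",
]

#: State-vector layout used throughout (kernel and solver agree on it).
SPECIES = (
    "tmz_blood",
    "tmz_isf",
    "tmz_intra",
    "cation",
    "o6mg",
    "mgmt_mrna",
    "mgmt_protein",
    "mgmt_o6mg_complex",
)


@dataclass(frozen=True)
class DoseSchedule:
    """Repeated-bolus TMZ schedule; default 150 mg/m^2 q24h x 5, start 24 h."""

    amount_mg_per_m2: float = 150.0
    interval_h: float = 24.0
    n_doses: int = 5
    start_h: float = 24.0
    #: dose that defines one unit of blood concentration
    reference_mg_per_m2: float = 150.0

    def __post_init__(self) -> None:
        if self.interval_h <= 0 or self.n_doses < 0 or self.start_h < 0:
            raise ValueError("schedule fields must be positive")
        if self.amount_mg_per_m2 < 0:
            raise ValueError("dose amount must be >= 0")

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_h + self.interval_h * np.arange(self.n_doses)

    @property
    def dose_concentration(self) -> float:
        """Blood-concentration jump per dose (model units)."""
        return self.amount_mg_per_m2 / self.reference_mg_per_m2

    @classmethod
    def none(cls) -> "DoseSchedule":
        return cls(amount_mg_per_m2=0.0, n_doses=0)


@dataclass(frozen=True)
class PKPDParameters:
    """Rate constants of the PK cascade and the MGMT gene-expression model.

    PK cascade (all h^-1): blood -> interstitial (k_bi) -> intracellular
    (k_ic) -> methylating cation (k_act, the pH-dependent activation
    collapsed to a fixed constant) -> conversion (k_conv), of which the
    fraction f_ad forms O6mG; k_eb/k_ei/k_eic eliminate from the transit
    compartments.  MGMT model: transcription k_tx (units/h, scaled by the
    gate and the feedback term 1 + f_fb * complex), mRNA decay k_dm,
    translation k_tl, protein decay k_dp, second-order suicide repair
    k_rep (per concentration per h), complex degradation k_dc.
    """

    k_bi: float = 0.4
    k_eb: float = 0.3
    k_ic: float = 1.0
    k_ei: float = 0.2
    k_act: float = 0.4
    k_eic: float = 0.1
    k_conv: float = 2.0
    f_ad: float = 0.1
    k_rep: float = 0.05
    k_tx: float = 1.0
    k_dm: float = 0.0866   # mRNA half-life ~8 h
    k_tl: float = 1.0
    k_dp: float = 0.0289   # protein half-life ~24 h
    k_dc: float = 0.35
    f_fb: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"parameter {f.name} must be >= 0")
        if self.f_ad > 1.0:
            raise ValueError("adduct fraction f_ad must be <= 1")

    def to_array(self) -> np.ndarray:
        """Kernel parameter vector (order fixed by the compiled RHS)."""
        return np.array(
            [
                self.k_bi, self.k_eb, self.k_ic, self.k_ei, self.k_act,
                self.k_eic, self.k_conv, self.f_ad, self.k_rep, self.k_tx,
                self.k_dm, self.k_tl, self.k_dp, self.k_dc, self.f_fb,
            ]
        )


def pk_rhs(state: np.ndarray, t: float, params: PKPDParameters) -> np.ndarray:
    """Time-derivatives of the drug species (linear transit cascade).

    Doses are impulses handled by :func:`integrate`, not source terms here.
    O6mG only gains here; its repair loss belongs to :func:`mgmt_rhs`.
    """
    p = params
    b, i, c, m = state[0], state[1], state[2], state[3]
    dy = np.zeros(len(SPECIES))
    dy[0] = -(p.k_bi + p.k_eb) * b
    dy[1] = p.k_bi * b - (p.k_ic + p.k_ei) * i
    dy[2] = p.k_ic * i - (p.k_act + p.k_eic) * c
    dy[3] = p.k_act * c - p.k_conv * m
    dy[4] = p.f_ad * p.k_conv * m
    return dy


def mgmt_rhs(
    state: np.ndarray, t: float, params: PKPDParameters, gate: float
) -> np.ndarray:
    """Time-derivatives of the MGMT species plus the O6mG repair loss.

    gate in [0, 1] scales transcription (0 restrictive, 1 permissive).
    """
    if not 0.0 <= gate <= 1.0:
        raise ValueError("gate must lie in [0, 1]")
    p = params
    o6mg, mrna, prot, cplx = state[4], state[5], state[6], state[7]
    repair = p.k_rep * prot * o6mg
    dy = np.zeros(len(SPECIES))
    dy[4] = -repair
    dy[5] = p.k_tx * gate * (1.0 + p.f_fb * cplx) - p.k_dm * mrna
    dy[6] = p.k_tl * mrna - p.k_dp * prot - repair
    dy[7] = repair - p.k_dc * cplx
    return dy


def full_rhs(state, t, params, gate):
    return pk_rhs(state, t, params) + mgmt_rhs(state, t, params, gate)


def steady_state(params: PKPDParameters, gate: float) -> np.ndarray:
    """Pre-dose steady state of the MGMT model (closed form).

    With no drug present the complex is zero and the two-stage linear
    model settles at mRNA* = k_tx * gate / k_dm and
    protein* = k_tl * mRNA* / k_dp.  Used to initialize every run.
    """
    if not 0.0 <= gate <= 1.0:
        raise ValueError("gate must lie in [0, 1]")
    y = np.zeros(len(SPECIES))
    if params.k_dm > 0:
        y[5] = params.k_tx * gate / params.k_dm
    if params.k_dp > 0:
        y[6] = params.k_tl * y[5] / params.k_dp
    return y


def integrate(
    params: PKPDParameters,
    schedule: DoseSchedule,
    gate_fn=1.0,
    horizon_h: float = 144.0,
    grid_dt_h: float = 0.5,
    init: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> pd.DataFrame:
    """Integrate the PK/PD system with impulse dosing.

    ``gate_fn`` is a constant or a callable t -> [0, 1].  The solver is
    restarted at every dose event (blood concentration jumps by the dose
    amount).  Returns a tidy-wide frame indexed by ``time_h`` with one
    column per species, sampled on a uniform grid; any solver undershoot
    below zero (within tolerance) is clipped to zero on output.
    """
    if schedule.n_doses and horizon_h < schedule.dose_times[-1]:
        raise ValueError("horizon must cover the dose schedule")
    gate = gate_fn if callable(gate_fn) else (lambda t, g=float(gate_fn): g)

    if init is None:
        init = steady_state(params, gate(0.0))
    y = np.asarray(init, dtype=float).copy()

    grid = np.arange(0.0, horizon_h + 1e-9, grid_dt_h)
    doses = [t for t in schedule.dose_times if t <= horizon_h]
    breaks = np.unique(np.concatenate([[0.0, horizon_h], doses]))
    dose_set = set(np.round(doses, 9))

    def rhs(t, yv):
        return full_rhs(yv, t, params, min(1.0, max(0.0, gate(t))))

    rows = [(0.0, y.copy())]
    for a, b in zip(breaks[:-1], breaks[1:]):
        if round(float(a), 9) in dose_set:
            y[0] += schedule.dose_concentration
        te = grid[(grid > a) & (grid <= b)]
        t_eval = np.unique(np.concatenate([te, [b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, rtol=rtol, atol=atol, method=method)
        if not sol.success:
            raise RuntimeError(f"PK/PD integration failed on [{a}, {b}]: {sol.message}")
        for tk, yk in zip(sol.t, sol.y.T):
            if tk in set(te):
                rows.append((tk, yk))
        y = sol.y[:, -1].copy()
    times = np.array([r[0] for r in rows])
    vals = np.clip(np.array([r[1] for r in rows]), 0.0, None)
    df = pd.DataFrame(vals, columns=SPECIES)
    df.insert(0, "time_h", times)
    return df.set_index("time_h")
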