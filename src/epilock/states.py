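"""Cell-state space, scenario presets and propensity (event-rate) calculus.

The model describes a glioma cell population distributed over discrete
states: quiescent cells (Q), differentiated glioma (G) and glioma stem
cells (GS), each of the latter two in a transcriptionally-permissive (Tp)
or -restrictive (Tr) epigenetic state, plus absorbing drug-resistant
states (G-R, GS-R) that open up once drug is present.  Every event
channel (birth, death, state transition) has a rate proportional to the
occupancy of its source state; the per-cell coefficients are scenario
presets with a pre-drug and a post-drug phase.

All rate coefficients are per day.  Time is in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSpace",
    "StateRates",
    "ScenarioRates",
    "Preset",
    "single_step_space",
    "hybrid_space",
    "preset_scenario",
    "preset_names",
    "INITIAL_POPULATION",
    "propensities",
    "apply_rescue_constraint",
    "resistant_death_coefficient",
]

#: Initial condition used throughout: 100 cells total.
INITIAL_POPULATION = {
    "Q": 80,
    "G-Tp": 7,
    "G-Tr": 7,
    "GS-Tp": 3,
    "GS-Tr": 3,
    "G-R": 0,
    "GS-R": 0,
}


class ConfigurationError(ValueError):
    """Raised for unknown scenario names or invalid coefficients."""


@dataclass(frozen=True)
class StateSpace:
    """Topology of the cell-state model.

    ``lateral`` holds the bidirectional sensitive<->sensitive transition
    targets per state; ``to_resistant`` maps a sensitive state to its
    one-way resistant target (the channel exists only after drug).
    Resistant states are absorbing: no outgoing transitions.
    """

    states: tuple[str, ...]
    sensitive: tuple[str, ...]
    resistant: tuple[str, ...]
    lateral: dict[str, tuple[str, ...]]
    to_resistant: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.resistant:
            if s in self.lateral and self.lateral[s]:
                raise ConfigurationError(f"resistant state {s!r} must be absorbing")
            if s in self.to_resistant:
                raise ConfigurationError(f"resistant state {s!r} cannot re-transition")
        for s, dests in self.lateral.items():
            for d in dests:
                if s not in self.lateral.get(d, ()):
                    raise ConfigurationError(
                        f"lateral transitions must be symmetric: {s}->{d}"
                    )

    def index(self, state: str) -> int:
        return self.states.index(state)

    def destinations(self, state: str, *, post_drug: bool) -> tuple[str, ...]:
        """Admissible transition targets of ``state`` in the given phase."""
        dests = self.lateral.get(state, ())
        if post_drug and state in self.to_resistant:
            dests = dests + (self.to_resistant[state],)
        return dests


def single_step_space() -> StateSpace:
    """Five sensitive states, fully connected laterally, plus G-R/GS-R."""
    sens = ("Q", "G-Tp", "G-Tr", "GS-Tp", "GS-Tr")
    lateral = {s: tuple(t for t in sens if t != s) for s in sens}
    return StateSpace(
        states=sens + ("G-R", "GS-R"),
        sensitive=sens,
        resistant=("G-R", "GS-R"),
        lateral=lateral,
        to_resistant={
            "G-Tp": "G-R",
            "G-Tr": "G-R",
            "GS-Tp": "GS-R",
            "GS-Tr": "GS-R",
        },
    )


def hybrid_space() -> StateSpace:
    """State space of the hybrid model.

    No explicit resistant states; instead the transcriptionally-permissive
    states can lock into MGMT-expressing variants (G-Tp-MGMT, GS-Tp-MGMT),
    which play the structural role of the absorbing states.
    """
    sens = ("Q", "G-Tp", "G-Tr", "GS-Tp", "GS-Tr")
    lateral = {s: tuple(t for t in sens if t != s) for s in sens}
    return StateSpace(
        states=sens + ("G-Tp-MGMT", "GS-Tp-MGMT"),
        sensitive=sens,
        resistant=("G-Tp-MGMT", "GS-Tp-MGMT"),
        lateral=lateral,
        to_resistant={"G-Tp": "G-Tp-MGMT", "GS-Tp": "GS-Tp-MGMT"},
    )


@dataclass(frozen=True)
class StateRates:
    """Per-cell rate coefficients (day^-1) of one state, by drug phase.

    For resistant states ``death_post`` is the amplitude of the decaying
    death law  death = amplitude * n * exp(-(t - drug_time)/divisor).
    """

    birth_pre: float = 0.0
    death_pre: float = 0.0
    trans_pre: float = 0.0
    birth_post: float = 0.0
    death_post: float = 0.0
    trans_post: float = 0.0

    def __post_init__(self) -> None:
        for f in (
            self.birth_pre,
            self.death_pre,
            self.trans_pre,
            self.birth_post,
            self.death_post,
            self.trans_post,
        ):
            if f < 0:
                raise ConfigurationError("rate coefficients must be >= 0")


@dataclass(frozen=True)
class ScenarioRates:
    """A full scenario: per-state coefficients plus global knobs.

    instability "random_u" multiplies every transition propensity by an
    independent Uniform(0, 1) draw at each propensity evaluation.
    ``apportionment`` controls how a state's single transition coefficient
    maps to per-destination rates: "per_destination" (default) gives every
    admissible destination the full coefficient (each channel has rate
    ct * n); "total" treats the coefficient as the state's total outflow,
    split evenly over destinations.
    """

    name: str
    rates: dict[str, StateRates]
    drug_time: float = 2.0
    t_max: float = 20.0
    instability: str = "none"  # "none" | "random_u"
    resistant_death_divisor: float = 20.0
    apportionment: str = "per_destination"  # "per_destination" | "total"
    resistant_death_decay: bool = True  # False: constant post-drug coefficient
    rescue: bool = True
    rescue_threshold: int = 10
    u_mean: float = 0.5  # mean of the instability multiplier (mean-field use)

    def __post_init__(self) -> None:
        if self.instability not in ("none", "random_u"):
            raise ConfigurationError(f"unknown instability mode {self.instability!r}")
        if self.apportionment not in ("total", "per_destination"):
            raise ConfigurationError(f"unknown apportionment {self.apportionment!r}")
        if not self.drug_time < self.t_max:
            raise ConfigurationError("drug_time must be < t_max")
        if self.resistant_death_divisor <= 0:
            raise ConfigurationError("resistant_death_divisor must be > 0")

    def coefficients(self, state: str, t: float) -> tuple[float, float, float]:
        """(birth, death, transition) per-cell coefficients at time ``t``."""
        r = self.rates[state]
        if t < self.drug_time:
            return r.birth_pre, r.death_pre, r.trans_pre
        return r.birth_post, r.death_post, r.trans_post


@dataclass(frozen=True)
class Preset:
    rates: ScenarioRates
    space: StateSpace
    initial: dict[str, int] = field(default_factory=lambda: dict(INITIAL_POPULATION))


def _resistant_rates(
    birth: float = 2.0, death_amplitude: float = 2.2
) -> dict[str, StateRates]:
    r = StateRates(birth, death_amplitude, 0.0, birth, death_amplitude, 0.0)
    return {"G-R": r, "GS-R": r}


def _build_presets() -> dict[str, Preset]:
    space = single_step_space()
    presets: dict[str, Preset] = {}

    # Control, no drug: low transitions, no drug effect, no resistant channel.
    control_tbl = {
        "Q": StateRates(0.0, 1.0, 0.1, 0.0, 1.0, 0.1),
        **{
            s: StateRates(2.0, 1.0, 0.1, 2.0, 1.0, 0.1)
            for s in ("G-Tp", "G-Tr", "GS-Tp", "GS-Tr")
        },
        **_resistant_rates(),
    }
    no_res_space = StateSpace(
        states=space.states,
        sensitive=space.sensitive,
        resistant=space.resistant,
        lateral=space.lateral,
        to_resistant={},
    )
    presets["control"] = Preset(
        ScenarioRates("control", control_tbl), no_res_space
    )

    # Drug sensitive: drug raises death to 2.2 at t >= 2, still no resistance.
    drug_sens_tbl = {
        "Q": StateRates(0.0, 1.0, 0.1, 0.0, 2.2, 0.1),
        **{
            s: StateRates(2.0, 1.0, 0.1, 2.0, 2.2, 0.1)
            for s in ("G-Tp", "G-Tr", "GS-Tp", "GS-Tr")
        },
        **_resistant_rates(),
    }
    presets["drug_sensitive"] = Preset(
        ScenarioRates("drug_sensitive", drug_sens_tbl), no_res_space
    )

    def drug_resistant(name: str, **kw) -> Preset:
        tbl = {
            "Q": StateRates(0.0, 1.0, kw.get("ct", 1.0), 0.0, 2.2, kw.get("ct", 1.0)),
            **{
                s: StateRates(2.0, 1.0, kw.get("ct", 1.0), 2.0, 2.2, kw.get("ct", 1.0))
                for s in ("G-Tp", "G-Tr", "GS-Tp", "GS-Tr")
            },
            **_resistant_rates(
                birth=kw.get("r_birth", 2.0),
                death_amplitude=kw.get("r_death", 2.2),
            ),
        }
        return Preset(
            ScenarioRates(
                name,
                tbl,
                instability=kw.get("instability", "none"),
                resistant_death_divisor=kw.get("divisor", 20.0),
            ),
            space,
        )

    presets["drug_resistant_stable"] = drug_resistant("drug_resistant_stable")
    presets["drug_resistant_unstable"] = drug_resistant(
        "drug_resistant_unstable", instability="random_u"
    )

    # Sensitivity variants: altered resistant birth/death and transition rates.
    presets["s1_low_resistant_birth"] = drug_resistant(
        "s1_low_resistant_birth", r_birth=1.5
    )
    presets["s1_high_resistant_birth"] = drug_resistant(
        "s1_high_resistant_birth", r_birth=2.5
    )
    presets["s1_low_resistant_death"] = drug_resistant(
        "s1_low_resistant_death", divisor=10.0
    )
    presets["s1_high_resistant_death"] = drug_resistant(
        "s1_high_resistant_death", divisor=100.0
    )
    presets["s1_no_transitions"] = drug_resistant("s1_no_transitions", ct=0.0)
    presets["s1_high_transitions"] = drug_resistant("s1_high_transitions", ct=2.0)
    return presets


_PRESETS = _build_presets()


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


def preset_scenario(name: str) -> Preset:
    """Return the named scenario preset (rates + state space + initial pop)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; known: {', '.join(_PRESETS)}"
        ) from None


def resistant_death_coefficient(t: float, rates: ScenarioRates, state: str) -> float:
    """Per-cell death coefficient of a resistant state at time t (days)."""
    r = rates.rates[state]
    if t < rates.drug_time:
        return r.death_pre
    if not rates.resistant_death_decay:
        return r.death_post
    return r.death_post * math.exp(-(t - rates.drug_time) / rates.resistant_death_divisor)


def _validate_population(pop: dict[str, int], space: StateSpace) -> None:
    for s in space.states:
        n = pop.get(s, 0)
        if n < 0 or int(n) != n:
            raise ValueError(f"population of {s!r} must be a nonnegative integer")


def propensities(
    pop: dict[str, int],
    t: float,
    rates: ScenarioRates,
    space: StateSpace,
    rng: np.random.Generator | None = None,
    rescue: bool | None = None,
) -> dict[tuple, float]:
    """Event-rate map at time ``t`` (rates in day^-1).

    Keys are ("birth", s), ("death", s) and ("transition", s, dst).
    In instability mode "random_u" each state's transition outflow is
    multiplied by an independent Uniform(0,1) draw from ``rng`` (required).
    The rescue constraint is applied unless ``rescue=False``.
    """
    _validate_population(pop, space)
    if rates.instability == "random_u" and rng is None:
        raise ValueError("instability mode 'random_u' requires an rng")
    post = t >= rates.drug_time
    out: dict[tuple, float] = {}
    for s in space.states:
        n = pop.get(s, 0)
        cb, cd, ct = rates.coefficients(s, t)
        out[("birth", s)] = cb * n
        if s in space.resistant and post:
            out[("death", s)] = resistant_death_coefficient(t, rates, s) * n
        else:
            out[("death", s)] = cd * n
        outflow = ct * n
        if rates.instability == "random_u":
            outflow *= rng.random()
        dests = space.destinations(s, post_drug=post)
        if dests and outflow > 0:
            share = outflow if rates.apportionment == "per_destination" else outflow / len(dests)
            for d in dests:
                out[("transition", s, d)] = share
        else:
            for d in dests:
                out[("transition", s, d)] = 0.0
    if rescue if rescue is not None else rates.rescue:
        out = apply_rescue_constraint(pop, out, space, rates.rescue_threshold)
    return out


def apply_rescue_constraint(
    pop: dict[str, int],
    rate_map: dict[tuple, float],
    space: StateSpace,
    threshold: int = 10,
) -> dict[tuple, float]:
    """Zero death and sensitive->resistant rates for depleted sensitive states.

    Any sensitive state with strictly fewer than ``threshold`` cells has its
    death rate and its transition rate toward resistant states set to zero;
    every other rate is left unchanged.
    """
    out = dict(rate_map)
    for s in space.sensitive:
        if pop.get(s, 0) < threshold:
            if ("death", s) in out:
                out[("death", s)] = 0.0
            target = space.to_resistant.get(s)
            if target is not None and ("transition", s, target) in out:
                out[("transition", s, target)] = 0.0
    return out
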