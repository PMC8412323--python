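"""Structured-text configuration, fixtures and run manifests.

Scenario, PK/PD and hybrid configurations round-trip through YAML with a
small schema validator; every simulation output is tied to a JSON manifest
(config hash + master seed + mode + package version) from which the run
can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .hybrid import HybridConfig
from .pkpd import DoseSchedule, PKPDParameters
from .states import (
    ConfigurationError,
    Preset,
    ScenarioRates,
    StateRates,
    StateSpace,
    preset_names,
    preset_scenario,
    single_step_space,
)

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
    "save_pkpd",
    "load_pkpd",
    "save_hybrid_config",
    "load_hybrid_config",
    "RunManifest",
    "generate_fixtures",
]

_RATE_KEYS = (
    "birth_pre", "death_pre", "trans_pre", "birth_post", "death_post", "trans_post"
)


def scenario_to_dict(preset: Preset) -> dict:
    r = preset.rates
    return {
        "schema": "epilock/scenario/1",
        "name": r.name,
        "drug_time_days": r.drug_time,
        "t_max_days": r.t_max,
        "instability": r.instability,
        "resistant_death_divisor_days": r.resistant_death_divisor,
        "resistant_death_decay": r.resistant_death_decay,
        "apportionment": r.apportionment,
        "rescue": r.rescue,
        "rescue_threshold": r.rescue_threshold,
        "resistant_transitions": bool(preset.space.to_resistant),
        "initial_population": dict(preset.initial),
        "states": {
            s: {k: getattr(r.rates[s], k) for k in _RATE_KEYS} for s in r.rates
        },
        "units": "rate coefficients in day^-1; times in days",
    }


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"config key {key!r}: {msg}")


def scenario_from_dict(d: dict) -> Preset:
    _require(d.get("schema") == "epilock/scenario/1", "schema", "unsupported schema")
    space = single_step_space()
    if not d.get("resistant_transitions", True):
        space = StateSpace(
            states=space.states,
            sensitive=space.sensitive,
            resistant=space.resistant,
            lateral=space.lateral,
            to_resistant={},
        )
    states = d.get("states")
    _require(isinstance(states, dict), "states", "must be a mapping")
    tbl = {}
    for s in space.states:
        _require(s in states, f"states.{s}", "missing state")
        row = states[s]
        for k in _RATE_KEYS:
            _require(k in row, f"states.{s}.{k}", "missing coefficient")
            _require(row[k] >= 0, f"states.{s}.{k}", "must be >= 0")
        tbl[s] = StateRates(**{k: float(row[k]) for k in _RATE_KEYS})
    rates = ScenarioRates(
        name=str(d.get("name", "custom")),
        rates=tbl,
        drug_time=float(d.get("drug_time_days", 2.0)),
        t_max=float(d.get("t_max_days", 20.0)),
        instability=d.get("instability", "none"),
        resistant_death_divisor=float(d.get("resistant_death_divisor_days", 20.0)),
        resistant_death_decay=bool(d.get("resistant_death_decay", True)),
        apportionment=d.get("apportionment", "total"),
        rescue=bool(d.get("rescue", True)),
        rescue_threshold=int(d.get("rescue_threshold", 10)),
    )
    init = {k: int(v) for k, v in d.get("initial_population", {}).items()}
    return Preset(rates, space, init)


def _dump(d: dict, path: Path) -> None:
    path.write_text(yaml.safe_dump(d, sort_keys=True))


def save_scenario(preset: Preset, path) -> None:
    _dump(scenario_to_dict(preset), Path(path))


def load_scenario(path) -> Preset:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def save_pkpd(params: PKPDParameters, schedule: DoseSchedule, path) -> None:
    _dump(
        {
            "schema": "epilock/pkpd/1",
            "parameters": asdict(params),
            "schedule": asdict(schedule),
            "units": "rate constants in h^-1 (f_ad, f_fb dimensionless); "
            "dose in mg/m^2; times in hours; concentrations in model units "
            "(one reference dose = 1 blood unit)",
        },
        Path(path),
    )


def load_pkpd(path) -> tuple[PKPDParameters, DoseSchedule]:
    d = yaml.safe_load(Path(path).read_text())
    _require(d.get("schema") == "epilock/pkpd/1", "schema", "unsupported schema")
    try:
        return (
            PKPDParameters(**d.get("parameters", {})),
            DoseSchedule(**d.get("schedule", {})),
        )
    except (TypeError, ValueError) as e:
        raise ConfigurationError(str(e)) from e


def save_hybrid_config(cfg: HybridConfig, path) -> None:
    _dump(
        {
            "schema": "epilock/hybrid/1",
            "config": asdict(cfg),
            "units": "dt/horizon in hours; kill rates in day^-1",
        },
        Path(path),
    )


def load_hybrid_config(path) -> HybridConfig:
    d = yaml.safe_load(Path(path).read_text())
    _require(d.get("schema") == "epilock/hybrid/1", "schema", "unsupported schema")
    try:
        return HybridConfig(**d.get("config", {}))
    except (TypeError, ValueError) as e:
        raise ConfigurationError(str(e)) from e


@dataclass
class RunManifest:
    """Provenance record tying an output file to its exact inputs."""

    command: str
    scenario: str
    mode: str
    seed: int
    config: dict
    config_sha256: str = ""
    package_version: str = ""

    def __post_init__(self) -> None:
        canon = json.dumps(self.config, sort_keys=True)
        self.config_sha256 = hashlib.sha256(canon.encode()).hexdigest()
        if not self.package_version:
            from . import __version__

            self.package_version = __version__

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        m = cls(
            command=d["command"],
            scenario=d["scenario"],
            mode=d["mode"],
            seed=d["seed"],
            config=d["config"],
        )
        if m.config_sha256 != d["config_sha256"]:  # pragma: no cover
            raise ConfigurationError("manifest hash mismatch")
        return m


def generate_fixtures(outdir) -> list[Path]:
    """Write every scenario preset plus default PK/PD and hybrid configs.

    Regeneration is idempotent (stable key order, no timestamps).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in preset_names():
        p = out / f"scenario_{name}.yaml"
        save_scenario(preset_scenario(name), p)
        written.append(p)
    p = out / "pkpd_default.yaml"
    save_pkpd(PKPDParameters(), DoseSchedule(), p)
    written.append(p)
    p = out / "hybrid_default.yaml"
    save_hybrid_config(HybridConfig(), p)
    written.append(p)
    return written
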