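"""Structured run configuration: the single entry point for protocol
parameters (model, ladder, temperatures, iteration schedule, seeds).

Every field is validated before any computation starts and unknown keys are
rejected, so a typo fails fast instead of silently running defaults. The
configuration hash embedded in output artifacts enables provenance replay.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .models import (
    PotentialModel,
    cg_peptide_potential,
    double_well_potential,
    harmonic_potential,
)

_MODEL_KEYS = {
    "harmonic": {"d", "k"},
    "double_well": {"barrier_height", "well_separation", "asymmetry", "extra_dims", "extra_k"},
    "cg_peptide": {
        "n_sites", "bond_k", "angle_k", "torsion_amp", "contact_eps",
        "contact_sigma", "bond_r0", "angle_theta0", "torsion_phi0", "core_softening",
    },
}
_LADDER_KEYS = {"e_low", "e_high", "n_vs", "overlap_fraction", "confinement_strength"}
_TEMP_KEYS = {"t_sim", "seed_temps", "analysis"}
_SCHED_KEYS = {
    "cycles", "n_runs", "n_int", "record_every", "seed_steps", "seed_burn_in",
    "grid_bins", "flatness_target", "dt", "thermostat", "friction", "window",
    "scaling_time",
}
_TOP_KEYS = {"model", "ladder", "temperatures", "schedule", "seed", "output"}


def _check_keys(section: dict, allowed: set, where: str):
    if not isinstance(section, dict):
        raise ConfigError(f"section '{where}' must be a mapping")
    for k in section:
        if k not in allowed:
            raise ConfigError(f"unknown key '{k}' in section '{where}'")


@dataclass
class RunConfig:
    model: dict
    temperatures: dict = field(default_factory=dict)
    ladder: dict | None = None
    schedule: dict = field(default_factory=dict)
    seed: int = 0
    output: dict = field(default_factory=dict)

    def __post_init__(self):
        if "kind" not in self.model:
            raise ConfigError("model section needs a 'kind' key")
        kind = self.model["kind"]
        if kind not in _MODEL_KEYS:
            raise ConfigError(f"unknown model kind '{kind}'")
        _check_keys({k: v for k, v in self.model.items() if k != "kind"},
                    _MODEL_KEYS[kind], f"model ({kind})")
        if self.ladder is not None:
            _check_keys(self.ladder, _LADDER_KEYS, "ladder")
        _check_keys(self.temperatures, _TEMP_KEYS, "temperatures")
        _check_keys(self.schedule, _SCHED_KEYS, "schedule")
        _check_keys(self.output, {"dir", "prefix"}, "output")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: invalid YAML: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        for k in raw:
            if k not in _TOP_KEYS:
                raise ConfigError(f"unknown top-level key '{k}'")
        if "model" not in raw:
            raise ConfigError("configuration needs a 'model' section")
        return cls(
            model=raw["model"],
            temperatures=raw.get("temperatures", {}),
            ladder=raw.get("ladder"),
            schedule=raw.get("schedule", {}),
            seed=raw.get("seed", 0),
            output=raw.get("output", {}),
        )

    def build_model(self) -> PotentialModel:
        params = {k: v for k, v in self.model.items() if k != "kind"}
        kind = self.model["kind"]
        if kind == "harmonic":
            return harmonic_potential(**params)
        if kind == "double_well":
            return double_well_potential(**params)
        return cg_peptide_potential(**params)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "model": self.model, "temperatures": self.temperatures,
                "ladder": self.ladder, "schedule": self.schedule, "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def iterate_kwargs(self) -> dict:
        """Keyword arguments for :func:`vmcmd.vsampler.iterate_vmcmd`."""
        kw: dict = {"seed": self.seed}
        t = self.temperatures
        if "t_sim" in t:
            kw["T_sim"] = float(t["t_sim"])
        if "seed_temps" in t:
            kw["seed_temps"] = [float(x) for x in t["seed_temps"]]
        s = self.schedule
        if "cycles" in s:
            kw["schedule"] = [int(x) for x in s["cycles"]]
        for src, dst in [
            ("n_runs", "n_runs"), ("n_int", "N_int"), ("record_every", "record_every"),
            ("seed_steps", "seed_steps"), ("seed_burn_in", "seed_burn_in"),
            ("grid_bins", "grid_bins"), ("flatness_target", "flatness_target"),
            ("dt", "dt"), ("thermostat", "thermostat"), ("friction", "friction"),
        ]:
            if src in s:
                kw[dst] = s[src]
        if "window" in s:
            kw["window"] = tuple(float(x) for x in s["window"])
        if self.ladder is not None and {"e_low", "e_high", "n_vs"} <= set(self.ladder):
            from .vsampler import build_ladder

            kw["ladder"] = build_ladder(
                float(self.ladder["e_low"]), float(self.ladder["e_high"]),
                int(self.ladder["n_vs"]),
                float(self.ladder.get("overlap_fraction", 0.25)),
                float(self.ladder.get("confinement_strength", 25.0)),
            )
        elif self.ladder is not None:
            if "n_vs" in self.ladder:
                kw["n_vs"] = int(self.ladder["n_vs"])
            if "overlap_fraction" in self.ladder:
                kw["overlap_fraction"] = float(self.ladder["overlap_fraction"])
            if "confinement_strength" in self.ladder:
                kw["confinement_strength"] = float(self.ladder["confinement_strength"])
        return kw
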