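"""Scenario configuration: flat key-value files, validation, defaults.

A scenario file is a flat mapping in YAML, JSON, or TOML.  Model parameters
use exactly the keys ``alpha, beta, delta, mu, tau, sigma, rho, T, t_l``
(omitted keys take the baseline defaults); ``experiment`` selects one of the
six experiment kinds and the remaining keys are experiment-specific controls.
Unknown keys are rejected by name before any computation starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParams, DEFAULT_PARAM_VALUES

__all__ = ["ScenarioConfig", "load_config", "save_config", "EXPERIMENTS"]

EXPERIMENTS = ("simulate", "bifurcation", "phase_diagram", "ess", "invade", "evolve")

#: Experiment-control keys accepted per experiment, with defaults.
_COMMON = {"seed": None, "s_hat0": 1e4, "v_hat0": 1e2}
_SETTING_KEYS: dict[str, dict] = {
    "simulate": {**_COMMON, "n_seasons": 900, "burn_in": 800, "window": 100},
    "bifurcation": {
        **_COMMON,
        "tau_min": 2.5, "tau_max": 3.5, "tau_step": 0.01,
        "burn_in": 800, "window": 100, "amplitude_threshold": 1e-3,
    },
    "phase_diagram": {
        **_COMMON,
        "T_grid": [3.0, 4.0, 5.0, 6.0], "t_l_grid": [0.5, 1.0, 2.0],
        "burn_in": 800, "window": 100,
    },
    "ess": {**_COMMON, "host_constant": None},
    "invade": {
        **_COMMON,
        "resident_tau": 2.8, "mutant_tau": 2.81,
        "burn_in": 800, "intro_count": 15, "horizon": 300, "persist": 50,
    },
    "evolve": {
        **_COMMON,
        "tau0": None, "n_replicates": 12,
        "mutant_interval_seasons": 1000, "first_mutant_season": 100,
        "mutation_sd": 0.1, "extinction_threshold": 1.0,
        "constant_cohort": False, "max_events": 80,
    },
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully validated scenario: model parameters plus experiment controls."""

    experiment: str
    params: ModelParams
    settings: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        allowed = _SETTING_KEYS[self.experiment]
        unknown = set(self.settings) - set(allowed)
        if unknown:
            raise ValueError(
                f"unknown setting keys for experiment {self.experiment!r}: {sorted(unknown)}"
            )
        resolved = {**allowed, **self.settings}
        for key in ("T_grid", "t_l_grid"):
            if key in resolved and len(resolved[key]) == 0:
                raise ValueError(f"setting {key!r} must be a non-empty grid")
        if self.experiment == "bifurcation":
            if resolved["tau_step"] <= 0 or resolved["tau_max"] <= resolved["tau_min"]:
                raise ValueError("bifurcation grid requires tau_step > 0 and tau_max > tau_min")
        object.__setattr__(self, "settings", resolved)

    def to_flat_dict(self) -> dict:
        """Flat mapping suitable for a config file (only non-default settings)."""
        out: dict = {"experiment": self.experiment, **self.params.to_dict()}
        defaults = _SETTING_KEYS[self.experiment]
        for k, v in self.settings.items():
            if v != defaults.get(k):
                out[k] = v
        return out


def _parse_file(path: Path) -> dict:
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml", ""):
        data = yaml.safe_load(text)
    elif suffix == ".json":
        data = json.loads(text) if text.strip() else None
    elif suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        raise ValueError(f"unsupported config format {suffix!r} (use .yaml, .json, or .toml)")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    return data


def load_config(path: str | Path, experiment: str | None = None) -> ScenarioConfig:
    """Read and validate a scenario file; omitted parameters take defaults.

    ``experiment`` overrides or supplies the experiment kind (a bare
    parameter file can be used with any experiment).
    """
    path = Path(path)
    data = _parse_file(path)
    exp = experiment or data.pop("experiment", "simulate")
    data.pop("experiment", None)
    param_keys = {k: float(v) for k, v in data.items() if k in DEFAULT_PARAM_VALUES}
    rest = {k: v for k, v in data.items() if k not in DEFAULT_PARAM_VALUES}
    unknown = set(rest) - set(_SETTING_KEYS.get(exp, {}))
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = ModelParams.from_dict(param_keys)
    return ScenarioConfig(experiment=exp, params=params, settings=rest, name=path.stem)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as a flat YAML/JSON mapping (round-trips via load_config)."""
    path = Path(path)
    data = config.to_flat_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
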