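"""Config-file schema and the packaged default study conditions.

A config file (YAML; JSON is a YAML subset and also accepted) describes the
shared regimen plus a list of generate/scale fu pairs::

    dose: 10.0          # mg/kg
    mic: 1.0            # mg/L
    n: 5000
    seed: 12929
    clearance: {kind: lognormal, mean: 7.0, cv: 0.10}
    scenarios:
      - label: "fu 0.50 scalar"
        fu_generate: {kind: lognormal, mean: 0.5, cv: 0.15}
        fu_scale: {kind: scalar, value: 0.5}

All scenarios share the top-level seed unless one overrides it, so the
reference population (and any shared total distribution) is literally the
same sample across rows of the output table.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .distributions import spec_from_dict, spec_to_dict
from .scenario import DEFAULT_N, DEFAULT_SEED, ScenarioConfig

__all__ = ["ConfigError", "default_config_dict", "default_scenarios",
           "parse_config_dict", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message carries the offending field path."""


def default_config_dict() -> dict:
    """The packaged study conditions: four generate/scale fu pairs.

    Dose 10 mg/kg, MIC 1 mg/L, lognormal clearance (mean 7 L/kg/day, CV 10%),
    n = 5000. Moderate binding: true fu lognormal (mean 0.5, CV 15%),
    back-scaled by the scalar 0.5 or by Uniform(0.40, 0.60). High binding:
    true fu Uniform(0.05, 0.15), back-scaled by the scalar 0.1 or by an
    independent Uniform(0.05, 0.15).
    """
    return {
        "dose": 10.0,
        "mic": 1.0,
        "n": DEFAULT_N,
        "seed": DEFAULT_SEED,
        "clearance": {"kind": "lognormal", "mean": 7.0, "cv": 0.10},
        "scenarios": [
            {
                "label": "fu 0.50 scalar",
                "fu_generate": {"kind": "lognormal", "mean": 0.5, "cv": 0.15},
                "fu_scale": {"kind": "scalar", "value": 0.5},
            },
            {
                "label": "fu 0.10 scalar",
                "fu_generate": {"kind": "uniform", "lo": 0.05, "hi": 0.15},
                "fu_scale": {"kind": "scalar", "value": 0.1},
            },
            {
                "label": "fu 0.40-0.60 uniform",
                "fu_generate": {"kind": "lognormal", "mean": 0.5, "cv": 0.15},
                "fu_scale": {"kind": "uniform", "lo": 0.40, "hi": 0.60},
            },
            {
                "label": "fu 0.05-0.15 uniform",
                "fu_generate": {"kind": "uniform", "lo": 0.05, "hi": 0.15},
                "fu_scale": {"kind": "uniform", "lo": 0.05, "hi": 0.15},
            },
        ],
    }


def _spec_at(d: dict, path: str):
    try:
        return spec_from_dict(d)
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def parse_config_dict(cfg: dict) -> list[ScenarioConfig]:
    """Validate a config dict and expand it into one ScenarioConfig per scenario."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key in ("dose", "mic", "clearance", "scenarios"):
        if key not in cfg:
            raise ConfigError(f"{key}: required field missing")
    try:
        dose = float(cfg["dose"])
        mic = float(cfg["mic"])
        n = int(cfg.get("n", DEFAULT_N))
        seed = int(cfg.get("seed", DEFAULT_SEED))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"dose/mic/n/seed: {exc}") from exc
    cl_spec = _spec_at(cfg["clearance"], "clearance")
    scenarios = cfg["scenarios"]
    if not isinstance(scenarios, list) or not scenarios:
        raise ConfigError("scenarios: must be a non-empty list")

    out = []
    for i, sc in enumerate(scenarios):
        path = f"scenarios[{i}]"
        if not isinstance(sc, dict):
            raise ConfigError(f"{path}: must be a mapping")
        for key in ("fu_generate", "fu_scale"):
            if key not in sc:
                raise ConfigError(f"{path}.{key}: required field missing")
        try:
            out.append(ScenarioConfig(
                dose=dose,
                mic=mic,
                cl_spec=cl_spec,
                fu_generate=_spec_at(sc["fu_generate"], f"{path}.fu_generate"),
                fu_scale=_spec_at(sc["fu_scale"], f"{path}.fu_scale"),
                n=int(sc.get("n", n)),
                seed=int(sc.get("seed", seed)),
                label=str(sc.get("label", f"scenario_{i + 1}")),
            ))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    return out


def default_scenarios() -> list[ScenarioConfig]:
    """The packaged default conditions as ready-to-run ScenarioConfigs."""
    return parse_config_dict(default_config_dict())


def load_config(path: str | Path) -> tuple[list[ScenarioConfig], dict]:
    """Read and validate a YAML/JSON config file.

    Returns the expanded scenario list and the raw dict (for the manifest).
    """
    raw = yaml.safe_load(Path(path).read_text())
    return parse_config_dict(raw), raw


def dump_config(configs: list[ScenarioConfig]) -> dict:
    """Re-serialize expanded scenarios to the config-dict form (manifest echo)."""
    if not configs:
        raise ValueError("no scenarios to dump")
    first = configs[0]
    return {
        "dose": first.dose,
        "mic": first.mic,
        "n": first.n,
        "seed": first.seed,
        "clearance": spec_to_dict(first.cl_spec),
        "scenarios": [
            {
                "label": c.label,
                "fu_generate": spec_to_dict(c.fu_generate),
                "fu_scale": spec_to_dict(c.fu_scale),
                "n": c.n,
                "seed": c.seed,
            }
            for c in configs
        ],
    }
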