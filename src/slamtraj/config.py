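"""Pipeline configuration: YAML tree with defaults and strict key checking."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "reads": {
            "n_genes": 20,
            "n_cells": 30,
            "mean_molecules_per_cell": 60.0,
            "mean_reads_per_molecule": 1.5,
            "labeled_fraction": 0.3,
            "conversion_rate": 0.05,
            "error_rate": 0.001,
            "mean_T_per_read": 20.0,
            "snp_density": 0.002,
        },
        "kinetics": {
            "n_genes": 60,
            "n_cells": 200,
            "one_sided_fraction": 0.2,
            "noise": "poisson",
        },
        "clones": {
            "n_genes": 400,
            "n_normal_cells": 80,
            "n_clone_cells": [80],
            "shift": 1.0,
            "noise_sd": 0.2,
        },
        "conditions": {
            "n_conditions": 3,
            "n_cells_per_condition": 150,
            "separation": 4.0,
            "dim": 2,
        },
    },
    "filter": {"min_genes": 2000, "max_genes": 5000,
               "mito_range": [0.075, 0.2], "enabled": False},
    "hvg": {"n": 2000, "enabled": False},
    "moments": {"n_pcs": 30, "k": 30},
    "kinetics": {"min_shared": 20, "lambda": 0.0, "theta": 0.5,
                 "max_iter": 5, "tol": 1e-3},
    "scna": {"window": 101, "clip": 3.0, "k": 2},
    "similarity": {"k": 30, "metric": "composition"},
    "gradient": {"n_bins": 40, "scheme": "quantile", "head_fraction": 0.25},
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve user config (YAML file and/or dict) against the defaults.

    Unknown keys are rejected before any stage runs.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = _merge_raw(user, overrides)
    return _merge(DEFAULTS, user)


def _merge_raw(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_raw(out[k], v)
        else:
            out[k] = v
    return out


def write_resolved_config(config: dict, out_dir) -> None:
    path = Path(out_dir) / "config.resolved.yaml"
    path.write_text(yaml.safe_dump(config, sort_keys=True))
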