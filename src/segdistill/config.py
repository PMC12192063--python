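"""Run configuration: YAML loading, validation, profiles, seeding.

The ``reference`` profile stores the published training hyperparameters
(SGD, initial learning rate 2e-4, poly decay, weight decay 1e-4, momentum
0.9, batch size 160, 1000 epochs, reward scale 0.1, difficulty scale 10,
160x160 crops).  The ``tiny`` profile is the desk-scale override used for
CPU-sized runs and tests: small images, thin networks, short schedules.
Unknown keys anywhere in a user YAML are rejected with the offending key
named.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

__all__ = ["REFERENCE", "TINY_OVERRIDES", "RunConfig", "load_config"]

REFERENCE: dict = {
    "seed": 0,
    "out_dir": "runs",
    "data": {
        "n_cases": 100,
        "image_size": 160,
        "noise_sigma": 0.10,
        "drop_empty_slices": False,
        "split_fractions": [0.8, 0.1, 0.1],
    },
    "model": {
        "base_channels": 32,
        "mhmoe": {"num_heads": 4, "num_experts": 4},
        "assistant": {"num_attention_heads": 2, "base_channels": 64, "backbone": "compact"},
        "use_mhmoe": True,
    },
    "train": {
        "optimizer": "sgd",
        "lr": 2.0e-4,
        "momentum": 0.9,
        "weight_decay": 1.0e-4,
        "lr_decay": "poly",
        "poly_power": 0.9,
        "batch_size": 160,
        "epochs": 1000,
        "teacher_epochs": 1000,
        "ema_decay": 0.98,
    },
    "distill": {
        "temperature": 4.0,
        "alpha": 0.8,
        "lambda_reward": 0.1,
        "mu": 10.0,
        "lambda_student": 1.25,
        "lambda_comp": 1.0,
        "lambda_res": 1.0,
        "ta_weight": 0.9,
        "modality": "t1",
    },
    "eval": {"empty_dice": 1.0},
}

TINY_OVERRIDES: dict = {
    "data": {"n_cases": 30, "image_size": 64},
    "model": {
        "base_channels": 4,
        "mhmoe": {"num_heads": 2, "num_experts": 2},
        "assistant": {"num_attention_heads": 2, "base_channels": 8},
    },
    "train": {"lr": 0.05, "batch_size": 8, "epochs": 40, "teacher_epochs": 120},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        full = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {full!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {full!r} must be a mapping")
            out[key] = _merge(base[key], value, full)
        else:
            out[key] = value
    return out


class RunConfig:
    """Validated, merged configuration with dotted access."""

    def __init__(self, values: dict):
        self.values = values

    def __getitem__(self, dotted: str):
        node = self.values
        for part in dotted.split("."):
            node = node[part]
        return node

    def get(self, dotted: str, default=None):
        try:
            return self[dotted]
        except KeyError:
            return default

    def snapshot(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config.yaml"
        path.write_text(yaml.safe_dump(self.values, sort_keys=False))
        return path

    def to_json(self) -> str:
        return json.dumps(self.values, indent=2)


def load_config(
    path: str | Path | None = None,
    profile: str = "tiny",
    overrides: dict | None = None,
) -> RunConfig:
    """Build a RunConfig from the profile, an optional YAML file and overrides.

    Precedence: reference defaults < profile < YAML file < overrides.
    Unknown keys raise ``KeyError`` naming the key.
    """
    values = copy.deepcopy(REFERENCE)
    if profile == "tiny":
        values = _merge(values, TINY_OVERRIDES)
    elif profile != "reference":
        raise ValueError(f"unknown profile {profile!r} (use 'reference' or 'tiny')")
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration file must contain a mapping")
        values = _merge(values, loaded)
    if overrides:
        values = _merge(values, overrides)
    return RunConfig(values)
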