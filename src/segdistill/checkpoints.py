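"""Checkpoint I/O: serialized parameter dictionary + JSON config sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .assistant import AssistantNet
from .student import StudentNet
from .teacher import TeacherNet

__all__ = ["save_checkpoint", "load_checkpoint"]

_BUILDERS = {
    "teacher": lambda arch, rng: TeacherNet(
        rng,
        base_channels=arch["base_channels"],
        mhmoe_heads=arch.get("mhmoe_heads", 4),
        mhmoe_experts=arch.get("mhmoe_experts", 4),
        use_mhmoe=arch.get("use_mhmoe", True),
    ),
    "student": lambda arch, rng: StudentNet(rng, base_channels=arch["base_channels"]),
    "assistant": lambda arch, rng: AssistantNet(
        rng,
        base_channels=arch["base_channels"],
        num_attention_heads=arch.get("num_attention_heads", 2),
    ),
}


def save_checkpoint(model, kind: str, arch: dict, path: str | Path) -> Path:
    """Write weights (.npz) plus a JSON sidecar describing the architecture."""
    if kind not in _BUILDERS:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, **state)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"kind": kind, "arch": arch}, indent=2))
    return path


def load_checkpoint(path: str | Path, frozen: bool = False):
    """Rebuild a network from a checkpoint; optionally freeze its parameters."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"checkpoint sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    model = _BUILDERS[meta["kind"]](meta["arch"], np.random.default_rng(0))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    if frozen:
        model.freeze()
    return model, meta
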