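"""Run configuration: YAML files deep-merged over package defaults, with a
single global seed from which every stage derives its own stream."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["DEFAULTS", "load_config", "derive_seed", "config_hash"]

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "medcap_out",
    "curation": {
        "threshold": 500,
        "min_size": 10,
        "max_size": 80,
        "fractions": [0.6, 0.2, 0.2],
    },
    "synth": {
        "n_per_triple": 60,
        "image_size": [64, 64],
        "noise_sd": 8.0,
    },
    "features": {
        "backbone": "tiny_cnn",
        "pretrained": False,
        "trainable": False,
        "augment": {
            "enabled": False,
            "max_rotation": 15.0,
            "max_zoom": 0.1,
            "mirror": True,
        },
    },
    "model": {
        "embed_dim": 64,
        "n_heads": 2,
        "ff_dim": 128,
        "max_len": 8,
    },
    "train": {
        "optimizer": "adam",
        "learning_rate": None,
        "batch_size": 32,
        "max_epochs": 20,
        "early_stop_patience": 3,
    },
}


def _merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults <- YAML file <- explicit overrides (highest precedence)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        try:
            loaded = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        if loaded:
            if not isinstance(loaded, dict):
                raise ConfigurationError("config file must hold a mapping")
            cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, {k: v for k, v in overrides.items() if v is not None})
    return cfg


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
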