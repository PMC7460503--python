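"""Versioned model checkpoints: NumPy ``.npz`` of all parameters plus the
JSON-encoded model config and a config hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np

from ..preprocessing import WindowingSpec
from .models import ConvLayerSpec, LSTMSpec, ModelConfig, build_model

__all__ = ["save_model", "load_model", "config_hash"]

FORMAT_VERSION = 1


def _config_to_dict(config: ModelConfig) -> dict:
    d = dataclasses.asdict(config)
    d["windowing"]["map_shape"] = list(config.windowing.map_shape)
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    w = d["windowing"]
    return ModelConfig(
        windowing=WindowingSpec(
            sub_len=w["sub_len"], n_sub=w["n_sub"], stride=w["stride"],
            map_shape=tuple(w["map_shape"]),
        ),
        conv_stack=tuple(ConvLayerSpec(**c) for c in d["conv_stack"]),
        lstm=LSTMSpec(**d["lstm"]),
        fc_units=tuple(d["fc_units"]),
        fc_activation=d["fc_activation"],
        bn_eps=d["bn_eps"],
        bn_momentum=d["bn_momentum"],
        seed=d["seed"],
        dtype=d.get("dtype", "float32"),
    )


def config_hash(config: ModelConfig, variant: str = "") -> str:
    blob = json.dumps({"variant": variant, **_config_to_dict(config)},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def save_model(model, variant: str, path) -> None:
    """Serialize parameters, running BN statistics and config to ``path``.

    Stacked replicate models are not checkpointable as a whole; extract the
    member of interest first (``model.extract_member(j)``).
    """
    if getattr(model, "stack", None) is not None:
        raise ValueError(
            "cannot checkpoint a stacked model; use extract_member(j) first"
        )
    arrays: dict[str, np.ndarray] = {}
    for li, layer in enumerate(model.iter_layers()):
        for name, p in layer.params.items():
            arrays[f"layer{li:03d}.{name}"] = p
        if hasattr(layer, "running_mean"):
            arrays[f"layer{li:03d}.running_mean"] = layer.running_mean
            arrays[f"layer{li:03d}.running_var"] = layer.running_var
    meta = json.dumps(
        {
            "format_version": FORMAT_VERSION,
            "variant": variant,
            "config": _config_to_dict(model.config),
            "config_hash": config_hash(model.config, variant),
        }
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path):
    """Rebuild a model from a checkpoint; returns ``(model, variant)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta['format_version']}"
            )
        config = _config_from_dict(meta["config"])
        model = build_model(meta["variant"], config)
        for li, layer in enumerate(model.iter_layers()):
            for name in layer.params:
                layer.params[name][...] = data[f"layer{li:03d}.{name}"]
            if hasattr(layer, "running_mean"):
                layer.running_mean = data[f"layer{li:03d}.running_mean"]
                layer.running_var = data[f"layer{li:03d}.running_var"]
    return model, meta["variant"]
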