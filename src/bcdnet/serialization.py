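"""JSON serialization of trained classifier state (architecture + flat weights)."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .classifier import ClassifierState, TrainConfig

__all__ = ["classifier_to_json", "classifier_from_json"]


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__array__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    return obj


def _decode(obj):
    if isinstance(obj, dict) and "__array__" in obj:
        return np.asarray(obj["__array__"], dtype=obj["dtype"])
    if isinstance(obj, dict):
        return {k: _decode(v) for k, v in obj.items()}
    return obj


def classifier_to_json(state: ClassifierState) -> str:
    payload = {
        "config": dataclasses.asdict(state._config),
        "conv_params": _encode(state.conv_params) if state.conv_params else None,
        "dense_params": _encode(state.dense_params) if state.dense_params else None,
        "output_weights": _encode(state.output_weights),
        "errors": list(state.errors),
        "phi0": state.phi0,
        "learning_rate": state.learning_rate,
        "phi_max": state.phi_max,
        "feature_mean": _encode(state.feature_mean) if state.feature_mean is not None else None,
        "feature_scale": _encode(state.feature_scale) if state.feature_scale is not None else None,
        "loss_history": list(state.loss_history),
        "n_classes": state.n_classes,
    }
    return json.dumps(payload)


def classifier_from_json(text: str) -> ClassifierState:
    payload = json.loads(text)
    state = ClassifierState(
        conv_params=_decode(payload["conv_params"]) if payload["conv_params"] else None,
        dense_params=_decode(payload["dense_params"]) if payload["dense_params"] else None,
        output_weights=_decode(payload["output_weights"]),
        errors=payload["errors"],
        phi0=payload["phi0"],
        learning_rate=payload["learning_rate"],
        phi_max=payload["phi_max"],
        feature_mean=_decode(payload["feature_mean"]) if payload["feature_mean"] is not None else None,
        feature_scale=_decode(payload["feature_scale"]) if payload["feature_scale"] is not None else None,
        loss_history=payload["loss_history"],
        n_classes=payload["n_classes"],
    )
    state._config = TrainConfig(**payload["config"])
    state._config.conv_channels = tuple(state._config.conv_channels)
    return state
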