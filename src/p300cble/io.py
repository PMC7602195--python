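"""HDF5 persistence for feature matrices and trained models."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .classifiers import LinearModel, SaeModel
from .preprocess import FeatureMatrix, Standardizer

__all__ = ["save_features", "load_features", "save_model", "load_model"]


def save_features(fm: FeatureMatrix, path: str | Path, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=fm.X)
        f.create_dataset("y", data=fm.y)
        f.create_dataset("stim_code", data=fm.stim_code)
        f.create_dataset("char_index", data=fm.char_index)
        f.create_dataset("sequence_index", data=fm.sequence_index)
        layout = np.array([(c, b) for c, b in fm.feature_layout], dtype="S16")
        f.create_dataset("feature_layout", data=layout)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_features(path: str | Path) -> tuple[FeatureMatrix, dict]:
    with h5py.File(path, "r") as f:
        layout = [
            (c.decode(), int(b.decode())) for c, b in np.asarray(f["feature_layout"])
        ]
        fm = FeatureMatrix(
            X=np.asarray(f["X"]),
            y=np.asarray(f["y"]),
            feature_layout=layout,
            stim_code=np.asarray(f["stim_code"]),
            char_index=np.asarray(f["char_index"]),
            sequence_index=np.asarray(f["sequence_index"]),
        )
        attrs = dict(f.attrs)
    return fm, attrs


def save_model(model, path: str | Path, channel_labels: list[str] | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["method"] = model.method
        if channel_labels is not None:
            f.attrs["channel_labels"] = json.dumps(list(channel_labels))
        f.create_dataset("standardizer_mean", data=model.standardizer.mean)
        f.create_dataset("standardizer_scale", data=model.standardizer.scale)
        if isinstance(model, LinearModel):
            f.create_dataset("weights", data=model.weights)
            f.attrs["bias"] = model.bias
            if model.selected_features is not None:
                f.create_dataset("selected_features", data=model.selected_features)
        elif isinstance(model, SaeModel):
            f.create_dataset("encoder_weights", data=model.encoder_weights)
            f.create_dataset("encoder_bias", data=model.encoder_bias)
            f.create_dataset("decoder_weights", data=model.decoder_weights)
            f.create_dataset("decoder_bias", data=model.decoder_bias)
            f.create_dataset("softmax_weights", data=model.softmax_weights)
            f.create_dataset("minmax_lo", data=model.minmax_lo)
            f.create_dataset("minmax_range", data=model.minmax_range)
            f.create_dataset("training_trace", data=np.asarray(model.training_trace))
            f.attrs["hidden_units"] = model.hidden_units
            f.attrs["hyperparams"] = json.dumps(model.hyperparams)
        else:
            raise TypeError(f"cannot persist model of type {type(model).__name__}")


def load_model(path: str | Path):
    with h5py.File(path, "r") as f:
        method = str(f.attrs["method"])
        std = Standardizer(
            mean=np.asarray(f["standardizer_mean"]),
            scale=np.asarray(f["standardizer_scale"]),
        )
        channels = None
        if "channel_labels" in f.attrs:
            channels = json.loads(f.attrs["channel_labels"])
        if method in ("ls", "swlda"):
            model = LinearModel(
                weights=np.asarray(f["weights"]),
                bias=float(f.attrs["bias"]),
                standardizer=std,
                method=method,
                selected_features=(
                    np.asarray(f["selected_features"]) if "selected_features" in f else None
                ),
            )
        elif method == "sae":
            model = SaeModel(
                encoder_weights=np.asarray(f["encoder_weights"]),
                encoder_bias=np.asarray(f["encoder_bias"]),
                decoder_weights=np.asarray(f["decoder_weights"]),
                decoder_bias=np.asarray(f["decoder_bias"]),
                softmax_weights=np.asarray(f["softmax_weights"]),
                standardizer=std,
                minmax_lo=np.asarray(f["minmax_lo"]),
                minmax_range=np.asarray(f["minmax_range"]),
                hidden_units=int(f.attrs["hidden_units"]),
                hyperparams=json.loads(f.attrs["hyperparams"]),
                training_trace=list(np.asarray(f["training_trace"])),
            )
        else:
            raise ValueError(f"unknown model method {method!r}")
    return model, channels
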