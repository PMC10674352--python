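"""Save/load trained models together with their configuration and stats."""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .blocks import ECAConfig
from .features import NormStats
from .networks import FCN8s, ImprovedUNet, ModelConfig, SVMPixelClassifier

__all__ = ["save_model", "load_model"]

_KINDS = {"improved_unet": ImprovedUNet, "fcn8s": FCN8s}


def save_model(model, directory: str | Path, stats: NormStats | None = None) -> Path:
    """Serialize a model artifact: config + weights (+ normalization stats)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, SVMPixelClassifier):
        meta = {"kind": "svm", "params": model.params,
                "max_train_pixels": model.max_train_pixels, "seed": model.seed}
        (directory / "model.pkl").write_bytes(pickle.dumps(model))
    else:
        kind = "fcn8s" if isinstance(model, FCN8s) else "improved_unet"
        meta = {"kind": kind, "config": asdict(model.config), "seed": model.seed}
        if kind == "fcn8s":
            meta["use_pool3_skip"] = model.use_pool3_skip
        state = model.get_state()
        np.savez_compressed(directory / "weights.npz",
                            **{f"arr{i}": a for i, a in enumerate(state)})
    if stats is not None:
        meta["normalization"] = stats.to_dict()
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_model(directory: str | Path):
    """Rebuild a saved model; returns (model, NormStats | None)."""
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    stats = NormStats.from_dict(meta["normalization"]) if "normalization" in meta else None
    if meta["kind"] == "svm":
        model = pickle.loads((directory / "model.pkl").read_bytes())
        return model, stats
    cfg_dict = dict(meta["config"])
    cfg_dict["encoder_block_types"] = tuple(cfg_dict["encoder_block_types"])
    cfg_dict["eca_sites"] = tuple(cfg_dict["eca_sites"])
    cfg_dict["eca"] = ECAConfig(**cfg_dict["eca"])
    config = ModelConfig(**cfg_dict)
    if meta["kind"] == "fcn8s":
        model = FCN8s(config, seed=meta["seed"], use_pool3_skip=meta.get("use_pool3_skip", True))
    else:
        model = ImprovedUNet(config, seed=meta["seed"])
    with np.load(directory / "weights.npz") as z:
        state = [z[f"arr{i}"] for i in range(len(z.files))]
    model.set_state(state)
    return model, stats
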