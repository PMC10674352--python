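"""YAML run configuration: validated blocks for every pipeline stage.

Unknown keys are rejected (typos fail loudly). One master seed fans out to
per-stage seeds through `redtidenet.benchmark.stage_seed`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .features import DEFAULT_BAND_SELECTION

__all__ = [
    "FeatureBlock",
    "ModelBlock",
    "TrainBlock",
    "SynthBlock",
    "SVMBlock",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FeatureBlock(_Strict):
    bands: list[float] = Field(default_factory=lambda: list(DEFAULT_BAND_SELECTION))
    ndvi: bool = True
    normalization: Literal["minmax", "zscore", "none"] = "minmax"


class ModelBlock(_Strict):
    name: Literal["improved_unet", "unet", "unet_eca", "fcn8s", "svm"] = "improved_unet"
    base_width: int = 64
    depth: int = 4
    num_classes: int = 2
    dropout_rate: float = 0.3
    batchnorm: bool = True


class TrainBlock(_Strict):
    batch_size: int = 50
    epochs: int = 120
    learning_rate: float = 1e-3
    optimizer: Literal["adam"] = "adam"


class SynthBlock(_Strict):
    n_train_scenes: int = 4
    n_test_scenes: int = 1
    height: int = 256
    width: int = 256
    red_tide_fraction: float = 0.15
    morphology: Literal["banded_dispersed", "concentrated"] = "banded_dispersed"
    turbidity_fraction: float = 0.10
    land_fraction: float = 0.08
    ndvi_contrast: float = 0.25
    bluegreen_shift: float = -0.15
    noise_sd: float = 0.005
    boundary_roughness: Optional[float] = None


class SVMBlock(_Strict):
    C: float = 1.0
    gamma: float | Literal["scale", "auto"] = "scale"
    max_train_pixels: int = 50_000


class RunConfig(_Strict):
    seed: int = 0
    feature: FeatureBlock = Field(default_factory=FeatureBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    synth: SynthBlock = Field(default_factory=SynthBlock)
    svm: SVMBlock = Field(default_factory=SVMBlock)

    def scene_params(self, seed: int = 0):
        from .synthetic import SyntheticSceneParams

        return SyntheticSceneParams(**self.synth.model_dump(exclude={"n_train_scenes", "n_test_scenes"}), seed=seed)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; None yields the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
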