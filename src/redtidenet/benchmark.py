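"""Seeded end-to-end benchmark: synthetic scenes -> training -> scores.

This is the package's self-contained test bed. For each master seed it
generates the default five-scene benchmark (four training time slots, one
held-out test slot), trains the requested models under the study's
optimization settings, and reports pixel-pooled test metrics per model.

Desk-scale choices: benchmark models run at base width 8 (the full-width
architecture is identical up to channel counts) and 30 training epochs —
enough for every U-Net variant to converge on the synthetic conditions —
and the SVM baseline trains on 4000 subsampled pixels.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, confusion_on_patches, metrics
from .networks import MODEL_BUILDERS, ModelConfig, svm_pixel_baseline
from .raster_io import PatchDataset
from .synthetic import SyntheticSceneParams, generate_benchmark
from .training import TrainConfig, train

__all__ = ["stage_seed", "benchmark_once", "run_benchmark", "BENCHMARK_MODELS"]

BENCHMARK_MODELS = ("unet", "unet_eca", "improved_unet", "fcn8s", "svm")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derived per-stage seed: stable hash of the stage name and master seed."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _train_pixels(dataset: PatchDataset):
    tr = dataset.subset("train")
    x = tr.features[tr.valid]
    y = tr.labels[tr.valid]
    return x, y


def benchmark_once(
    seed: int,
    model_names: tuple[str, ...] = BENCHMARK_MODELS,
    params: SyntheticSceneParams = SyntheticSceneParams(),
    base_width: int = 8,
    epochs: int = 30,
    batch_size: int = 50,
    learning_rate: float = 1e-3,
    svm_train_pixels: int = 4000,
    dataset: PatchDataset | None = None,
) -> dict[str, MetricsReport]:
    """Generate (or reuse) one benchmark dataset and score the given models."""
    if dataset is None:
        dataset = generate_benchmark(params=params, seed=stage_seed(seed, "synth"))
    reports: dict[str, MetricsReport] = {}
    for name in model_names:
        if name == "svm":
            x, y = _train_pixels(dataset)
            model = svm_pixel_baseline(
                x, y, max_train_pixels=svm_train_pixels, seed=stage_seed(seed, "svm")
            )
        else:
            config = ModelConfig(in_channels=dataset.num_channels, base_width=base_width)
            model = MODEL_BUILDERS[name](config, seed=stage_seed(seed, f"init:{name}"))
            model, _ = train(
                model,
                dataset,
                TrainConfig(epochs=epochs, batch_size=batch_size,
                            learning_rate=learning_rate,
                            seed=stage_seed(seed, f"train:{name}")),
            )
        reports[name] = metrics(confusion_on_patches(model, dataset, split="test"))
    return reports


def run_benchmark(
    seeds: tuple[int, ...] = (0, 1, 2),
    model_names: tuple[str, ...] = BENCHMARK_MODELS,
    **kwargs,
) -> pd.DataFrame:
    """Benchmark over several master seeds; one row per (seed, model)."""
    rows = []
    for seed in seeds:
        for name, report in benchmark_once(seed, model_names, **kwargs).items():
            rows.append({"seed": seed, "model": name, **report.to_dict()})
    return pd.DataFrame(rows)


def mean_f1(table: pd.DataFrame) -> dict[str, float]:
    """Mean F1 per model over the seeds of a `run_benchmark` table."""
    return table.groupby("model")["f1"].mean().to_dict()
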