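"""Spectral feature engineering: NDVI and the model-input channel stack.

Red tides reflect strongly in the red and near-infrared bands, so the
normalized difference vegetation index

    NDVI = (Rrs_865 - Rrs_660) / (Rrs_865 + Rrs_660)

separates bloom water from seawater better than any single band. The
default model input stacks the six shortest-wavelength bands
(412, 443, 490, 555, 660, 680 nm) plus the NDVI plane, giving 7 channels;
the 745/865 nm NIR bands enter only through the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster_io import Scene

__all__ = [
    "DEFAULT_BAND_SELECTION",
    "FeatureCube",
    "NormStats",
    "compute_ndvi",
    "stack_features",
    "fit_norm_stats",
    "normalize_features",
    "denormalize_features",
]

#: Default six-band subset for the model input (red/NIR beyond 680 nm enters
#: via NDVI only).
DEFAULT_BAND_SELECTION = (412.0, 443.0, 490.0, 555.0, 660.0, 680.0)

NDVI_RED_NM = 660.0
NDVI_NIR_NM = 865.0


@dataclass
class FeatureCube:
    """(H, W, C) model-input stack with channel names."""

    data: np.ndarray
    channel_names: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("feature cube must be H x W x C")
        if self.data.shape[2] != len(self.channel_names):
            raise ValueError("channel_names must match the channel count")

    @property
    def num_channels(self) -> int:
        return self.data.shape[2]


def compute_ndvi(rrs865: np.ndarray, rrs660: np.ndarray) -> np.ndarray:
    """(NIR - red) / (NIR + red), elementwise; 0 where the denominator is 0.

    The zero convention is neutral: such pixels are dark/masked water and are
    excluded from classification anyway.
    """
    rrs865 = np.asarray(rrs865, dtype=np.float64)
    rrs660 = np.asarray(rrs660, dtype=np.float64)
    if rrs865.shape != rrs660.shape:
        raise ValueError(f"band shapes differ: {rrs865.shape} vs {rrs660.shape}")
    num = rrs865 - rrs660
    den = rrs865 + rrs660
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den != 0)
    return out


def stack_features(
    scene: Scene,
    band_selection: tuple[float, ...] = DEFAULT_BAND_SELECTION,
    include_ndvi: bool = True,
) -> FeatureCube:
    """Assemble the (H, W, C) input: selected bands in order, NDVI last."""
    planes, names = [], []
    for wl in band_selection:
        planes.append(scene.band(wl))  # KeyError names the missing wavelength
        names.append(f"{wl:g}nm")
    if include_ndvi:
        ndvi = compute_ndvi(scene.band(NDVI_NIR_NM), scene.band(NDVI_RED_NM))
        planes.append(ndvi.astype(np.float32))
        names.append("NDVI")
    return FeatureCube(np.stack(planes, axis=2), names)


@dataclass
class NormStats:
    """Per-channel normalization parameters fitted on the training split.

    method "minmax" maps the training range to [0, 1]; "zscore" centers and
    scales; "none" is the identity. Channels with zero spread are left
    unscaled (scale 1) with a warning.
    """

    method: str
    offset: np.ndarray
    scale: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "offset": [float(v) for v in self.offset],
            "scale": [float(v) for v in self.scale],
            "channel_names": list(self.channel_names),
        }

    @staticmethod
    def from_dict(d: dict) -> "NormStats":
        return NormStats(d["method"], np.asarray(d["offset"]), np.asarray(d["scale"]),
                         list(d.get("channel_names", [])))


def fit_norm_stats(
    cubes: "FeatureCube | list[FeatureCube]",
    method: str = "minmax",
    valid_masks: "np.ndarray | list[np.ndarray] | None" = None,
) -> NormStats:
    """Fit per-channel stats on training data (optionally valid pixels only)."""
    if isinstance(cubes, FeatureCube):
        cubes = [cubes]
    if valid_masks is not None and not isinstance(valid_masks, list):
        valid_masks = [valid_masks]
    pixels = []
    for i, cube in enumerate(cubes):
        flat = cube.data.reshape(-1, cube.num_channels)
        if valid_masks is not None:
            flat = flat[valid_masks[i].reshape(-1)]
        pixels.append(flat)
    x = np.concatenate(pixels, axis=0).astype(np.float64)
    names = list(cubes[0].channel_names)
    if method == "none":
        c = x.shape[1]
        return NormStats("none", np.zeros(c), np.ones(c), names)
    if method == "minmax":
        lo, hi = x.min(axis=0), x.max(axis=0)
        offset, scale = lo, hi - lo
    elif method == "zscore":
        offset, scale = x.mean(axis=0), x.std(axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    flat_channels = scale == 0
    if flat_channels.any():
        warnings.warn(
            f"{int(flat_channels.sum())} constant channel(s) left unscaled", stacklevel=2
        )
        offset = np.where(flat_channels, 0.0, offset)
        scale = np.where(flat_channels, 1.0, scale)
    return NormStats(method, offset, scale, names)


def normalize_features(cube: FeatureCube, stats: NormStats) -> FeatureCube:
    """Apply fitted stats: (x - offset) / scale per channel, deterministic."""
    data = (cube.data.astype(np.float64) - stats.offset) / stats.scale
    return FeatureCube(data.astype(np.float32), list(cube.channel_names))


def denormalize_features(cube: FeatureCube, stats: NormStats) -> FeatureCube:
    data = cube.data.astype(np.float64) * stats.scale + stats.offset
    return FeatureCube(data.astype(np.float32), list(cube.channel_names))
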