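"""Segmentation models: improved U-Net, basic U-Net, FCN-8s, pixel SVM.

The improved U-Net keeps the classic encoder-decoder-with-skips layout
(two convolution stages then 2x2 max pooling per encoder level, channel
width doubling per level; transposed-convolution up-sampling with skip
concatenation on the way back up) and changes three things:

* the convolution stages of encoder levels 1-2 become ASPC-3 pyramids and
  those of level 3 ASPC-2 pyramids, enlarging the receptive field without
  extra pooling;
* ECA channel attention re-weights the channels after each encoder block
  and the bottleneck;
* a dropout layer sits before up-sampling (bottleneck -> decoder entry).

The head is a 1x1 convolution to 2 classes followed by softmax; the red
tide class wins a pixel iff p(red) >= 0.5 (argmax with ties to red).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.svm import SVC

from . import nn
from .blocks import ASPC2, ASPC3, ASPCBlock, ECA, ECAConfig
from .features import FeatureCube
from .nn import autograd as ag
from .nn.autograd import Tensor
from .raster_io import LabelMap, VALID_CLASSES

__all__ = [
    "ModelConfig",
    "ImprovedUNet",
    "FCN8s",
    "SVMPixelClassifier",
    "build_improved_unet",
    "build_basic_unet",
    "build_unet_eca",
    "build_fcn8s",
    "svm_pixel_baseline",
    "predict_scene",
    "MODEL_BUILDERS",
]

_BLOCK_PRESETS = {"aspc3": ASPC3, "aspc2": ASPC2, "conv": None}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters shared by the U-Net family.

    encoder_block_types selects the convolution stage per encoder level;
    the improved model default is (aspc3, aspc3, aspc2, conv). eca_sites
    are drawn from {"input", "enc1".."enc{depth}", "bottleneck"}.
    """

    in_channels: int = 7
    num_classes: int = 2
    base_width: int = 64
    depth: int = 4
    encoder_block_types: tuple[str, ...] = ("aspc3", "aspc3", "aspc2", "conv")
    eca_sites: tuple[str, ...] = ("enc1", "enc2", "enc3", "enc4", "bottleneck")
    eca: ECAConfig = ECAConfig()
    dropout_rate: float = 0.3
    batchnorm: bool = True

    def __post_init__(self):
        if len(self.encoder_block_types) != self.depth:
            raise ValueError("encoder_block_types must list one block per level")
        unknown = set(self.encoder_block_types) - set(_BLOCK_PRESETS)
        if unknown:
            raise ValueError(f"unknown block types {sorted(unknown)}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def _conv_stage(kind: str, c_in: int, c_out: int, batchnorm: bool, rng) -> nn.Module:
    preset = _BLOCK_PRESETS[kind]
    if preset is None:
        return nn.ConvUnit(c_in, c_out, batchnorm=batchnorm, rng=rng)
    return ASPCBlock(c_in, c_out, preset, batchnorm=batchnorm, rng=rng)


class _EncoderLevel(nn.Module):
    def __init__(self, kind: str, c_in: int, c_out: int, batchnorm: bool, rng):
        self.stage1 = _conv_stage(kind, c_in, c_out, batchnorm, rng)
        self.stage2 = _conv_stage(kind, c_out, c_out, batchnorm, rng)

    def forward(self, x: Tensor, train: bool) -> Tensor:
        return self.stage2(self.stage1(x, train), train)


class _DecoderLevel(nn.Module):
    def __init__(self, c_in: int, c_skip: int, c_out: int, batchnorm: bool, rng):
        self.up = nn.ConvTranspose2x2(c_in, c_skip, rng=rng)
        self.stage1 = nn.ConvUnit(2 * c_skip, c_out, batchnorm=batchnorm, rng=rng)
        self.stage2 = nn.ConvUnit(c_out, c_out, batchnorm=batchnorm, rng=rng)

    def forward(self, x: Tensor, skip: Tensor, train: bool) -> Tensor:
        y = ag.concat([skip, self.up(x)], axis=1)
        return self.stage2(self.stage1(y, train), train)


class ImprovedUNet(nn.Module):
    """U-Net family model; plain U-Net is the all-"conv", no-ECA special case."""

    patch_size_multiple: int

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.seed = seed
        self.in_channels = config.in_channels
        self.patch_size_multiple = 2**config.depth
        w = config.base_width
        widths = [w * 2**i for i in range(config.depth)]
        bottleneck_w = w * 2**config.depth

        self.input_eca = (
            ECA(config.in_channels, config.eca, rng=rng) if "input" in config.eca_sites else None
        )
        self.encoder: list[_EncoderLevel] = []
        self.encoder_eca: list[ECA | None] = []
        c_in = config.in_channels
        for i, (kind, c_out) in enumerate(zip(config.encoder_block_types, widths)):
            self.encoder.append(_EncoderLevel(kind, c_in, c_out, config.batchnorm, rng))
            self.encoder_eca.append(
                ECA(c_out, config.eca, rng=rng) if f"enc{i + 1}" in config.eca_sites else None
            )
            c_in = c_out
        self.bottleneck = _EncoderLevel("conv", widths[-1], bottleneck_w, config.batchnorm, rng)
        self.bottleneck_eca = (
            ECA(bottleneck_w, config.eca, rng=rng) if "bottleneck" in config.eca_sites else None
        )
        self.decoder: list[_DecoderLevel] = []
        c_prev = bottleneck_w
        for c_skip in reversed(widths):
            self.decoder.append(_DecoderLevel(c_prev, c_skip, c_skip, config.batchnorm, rng))
            c_prev = c_skip
        self.head = nn.Conv2d(widths[0], config.num_classes, kernel_size=1, rng=rng)
        self._dropout_rng = np.random.default_rng(rng.integers(0, 2**31))

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    def forward_logits(self, x: Tensor, train: bool = False) -> Tensor:
        H, W = x.data.shape[2:]
        m = self.patch_size_multiple
        if H % m or W % m:
            raise ValueError(f"input {H}x{W} not divisible by 2^depth = {m}")
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: model expects {self.in_channels}, got {x.data.shape[1]}"
            )
        if self.input_eca is not None:
            x = self.input_eca(x)
        skips = []
        for level, eca in zip(self.encoder, self.encoder_eca):
            x = level(x, train)
            if eca is not None:
                x = eca(x)
            skips.append(x)
            x = ag.maxpool2x2(x)
        x = self.bottleneck(x, train)
        if self.bottleneck_eca is not None:
            x = self.bottleneck_eca(x)
        x = ag.dropout(x, self.config.dropout_rate, self._dropout_rng, train)
        for level, skip in zip(self.decoder, reversed(skips)):
            x = level(x, skip, train)
        return self.head(x)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """(N, C, P, P) float32 -> (N, K, P, P) softmax probabilities."""
        logits = self.forward_logits(Tensor(patches), train=False).data
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict_patches(self, patches: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """(N, C, P, P) -> (N, P, P) labels; red tide iff p(red) >= 0.5."""
        out = []
        for i in range(0, len(patches), batch_size):
            p = self.predict_proba(patches[i : i + batch_size])
            out.append((p[:, 1] >= 0.5).astype(np.uint8))
        return np.concatenate(out)


class FCN8s(nn.Module):
    """Slim VGG-style fully convolutional network with x8/x16/x32 fusion.

    Five conv+pool stages take a 32x32 input to 1x1; 1x1 score layers on the
    pool3, pool4 and final streams are fused through learned 2x up-sampling
    steps and restored to input size. Disabling the pool3 skip yields
    FCN-16s-style coarser fusion.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, use_pool3_skip: bool = True):
        rng = np.random.default_rng(seed)
        self.config = config
        self.seed = seed
        self.in_channels = config.in_channels
        self.use_pool3_skip = use_pool3_skip
        self.patch_size_multiple = 32
        w = config.base_width
        widths = [w, 2 * w, 4 * w, 8 * w, 8 * w]
        bn = config.batchnorm
        c_in = config.in_channels
        self.stages: list[nn.ConvUnit] = []
        for c_out in widths:
            self.stages.append(nn.ConvUnit(c_in, c_out, batchnorm=bn, rng=rng))
            c_in = c_out
        k = config.num_classes
        self.conv7 = nn.ConvUnit(widths[4], widths[4], kernel_size=1, batchnorm=bn, rng=rng)
        self.score_final = nn.Conv2d(widths[4], k, 1, rng=rng)
        self.score_pool4 = nn.Conv2d(widths[3], k, 1, rng=rng)
        self.score_pool3 = nn.Conv2d(widths[2], k, 1, rng=rng)
        self.up2a = nn.ConvTranspose2x2(k, k, rng=rng)
        self.up2b = nn.ConvTranspose2x2(k, k, rng=rng)
        self.up8 = [nn.ConvTranspose2x2(k, k, rng=rng) for _ in range(3)]
        self._dropout_rng = np.random.default_rng(rng.integers(0, 2**31))

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    def forward_logits(self, x: Tensor, train: bool = False) -> Tensor:
        H, W = x.data.shape[2:]
        if H < 32 or W < 32 or H % 32 or W % 32:
            raise ValueError("FCN-8s needs input dimensions that are multiples of 32")
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: model expects {self.in_channels}, got {x.data.shape[1]}"
            )
        pools = []
        for stage in self.stages:
            x = stage(x, train)
            x = ag.maxpool2x2(x)
            pools.append(x)
        x = self.conv7(pools[4], train)
        x = ag.dropout(x, self.config.dropout_rate, self._dropout_rng, train)
        score = self.score_final(x)  # H/32
        score = ag.add(self.up2a(score), self.score_pool4(pools[3]))  # H/16
        up = self.up2b(score)  # H/8
        score = ag.add(up, self.score_pool3(pools[2])) if self.use_pool3_skip else up
        for up_layer in self.up8:
            score = up_layer(score)
        return score

    predict_proba = ImprovedUNet.predict_proba
    predict_patches = ImprovedUNet.predict_patches


class SVMPixelClassifier:
    """Per-pixel RBF support-vector baseline over the C-channel spectra.

    Trained on a seeded subsample of at most `max_train_pixels` valid
    pixels; prediction maps are assembled pixelwise, so the classifier uses
    no spatial context at all.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 max_train_pixels: int = 50_000, seed: int = 0):
        self.params = {"C": C, "gamma": gamma}
        self.max_train_pixels = max_train_pixels
        self.seed = seed
        self.in_channels: int | None = None
        self._svc: SVC | None = None

    def fit(self, train_pixels: np.ndarray, train_labels: np.ndarray) -> "SVMPixelClassifier":
        train_pixels = np.asarray(train_pixels, dtype=np.float64)
        train_labels = np.asarray(train_labels).astype(int).ravel()
        if np.unique(train_labels).size < 2:
            raise ValueError("SVM training requires both classes among the pixels")
        rng = np.random.default_rng(self.seed)
        if len(train_pixels) > self.max_train_pixels:
            sel = rng.choice(len(train_pixels), self.max_train_pixels, replace=False)
            train_pixels, train_labels = train_pixels[sel], train_labels[sel]
        self.in_channels = train_pixels.shape[1]
        self._svc = SVC(kernel="rbf", random_state=int(self.seed), **self.params)
        self._svc.fit(train_pixels, train_labels)
        return self

    @property
    def support_vector_count(self) -> int:
        if self._svc is None:
            raise RuntimeError("classifier is not fitted")
        return int(self._svc.n_support_.sum())

    def predict_pixels(self, pixels: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("classifier is not fitted")
        return self._svc.predict(np.asarray(pixels, dtype=np.float64)).astype(np.uint8)

    def predict_patches(self, patches: np.ndarray, batch_size: int = 0) -> np.ndarray:
        """(N, C, P, P) -> (N, P, P), pixelwise."""
        n, c, p, _ = patches.shape
        if self.in_channels is not None and c != self.in_channels:
            raise ValueError(f"channel mismatch: model expects {self.in_channels}, got {c}")
        flat = patches.transpose(0, 2, 3, 1).reshape(-1, c)
        return self.predict_pixels(flat).reshape(n, p, p)


def build_improved_unet(config: ModelConfig | None = None, seed: int = 0) -> ImprovedUNet:
    """NDVI-ready U-Net with ASPC encoder levels 1-3 and ECA attention."""
    return ImprovedUNet(config or ModelConfig(), seed=seed)


def build_basic_unet(config: ModelConfig | None = None, seed: int = 0) -> ImprovedUNet:
    """Plain U-Net: all-conv encoder, no attention; same trunk otherwise."""
    config = config or ModelConfig()
    config = replace(config, encoder_block_types=("conv",) * config.depth, eca_sites=())
    return ImprovedUNet(config, seed=seed)


def build_unet_eca(config: ModelConfig | None = None, seed: int = 0) -> ImprovedUNet:
    """Middle rung of the ablation ladder: U-Net + ECA, without ASPC."""
    config = config or ModelConfig()
    config = replace(config, encoder_block_types=("conv",) * config.depth)
    return ImprovedUNet(config, seed=seed)


def build_fcn8s(config: ModelConfig | None = None, seed: int = 0, use_pool3_skip: bool = True) -> FCN8s:
    return FCN8s(config or ModelConfig(), seed=seed, use_pool3_skip=use_pool3_skip)


def svm_pixel_baseline(
    train_pixels: np.ndarray, train_labels: np.ndarray,
    C: float = 1.0, gamma: str | float = "scale",
    max_train_pixels: int = 50_000, seed: int = 0,
) -> SVMPixelClassifier:
    clf = SVMPixelClassifier(C=C, gamma=gamma, max_train_pixels=max_train_pixels, seed=seed)
    return clf.fit(train_pixels, train_labels)


MODEL_BUILDERS = {
    "improved_unet": build_improved_unet,
    "unet": build_basic_unet,
    "unet_eca": build_unet_eca,
    "fcn8s": build_fcn8s,
}


def predict_scene(model, cube: FeatureCube, label_map: LabelMap,
                  patch_size: int = 32) -> LabelMap:
    """Whole-scene inference by non-overlapping tiling.

    The scene is cut into the same half-open patch grid as `patchify`,
    each tile predicted independently and stitched back. Pixels whose truth
    class is land/coastline/unstudied are forced to that class in the
    output; classification happens only on valid water.
    """
    H, W, C = cube.data.shape
    if H % patch_size or W % patch_size:
        raise ValueError(f"scene {H}x{W} does not tile into {patch_size}-pixel patches")
    if getattr(model, "in_channels", C) not in (None, C):
        raise ValueError(f"channel mismatch: model expects {model.in_channels}, got {C}")
    tiles, origins = [], []
    for r in range(0, H, patch_size):
        for c in range(0, W, patch_size):
            tiles.append(cube.data[r : r + patch_size, c : c + patch_size].transpose(2, 0, 1))
            origins.append((r, c))
    pred_tiles = model.predict_patches(np.stack(tiles).astype(np.float32))
    out = np.zeros((H, W), dtype=np.uint8)
    for (r, c), tile in zip(origins, pred_tiles):
        out[r : r + patch_size, c : c + patch_size] = tile
    invalid = ~np.isin(label_map.labels, VALID_CLASSES)
    out[invalid] = label_map.labels[invalid]
    return LabelMap(labels=out, valid=label_map.valid.copy())
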