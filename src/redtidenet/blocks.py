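"""Building blocks of the improved U-Net.

* ECA — efficient channel attention: global average pooling to a 1x1xC
  channel descriptor, a weight-shared 1-D convolution across channels, a
  sigmoid gate, and per-channel rescaling of the feature map.
* ASPC — atrous spatial pyramid convolution: parallel dilated 3x3
  convolutions whose output widths are fixed fractions of the block width
  (ASPC-3: rates 1/2/3 at 50/25/25%; ASPC-2: rates 1/2 at 50/50%),
  concatenated on the channel axis.
* ASPP — atrous spatial pyramid pooling: 1x1 conv, three depthwise-separable
  dilated 3x3 convs (rates 1/3/5), and a global-average-pool branch, fused
  by a 1x1 convolution.
* receptive_field — side length of the input patch influencing one output
  unit for a stack of dilated convolutions, with an impulse-response oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Parameter, Tensor

__all__ = [
    "ECAConfig",
    "ASPCConfig",
    "ASPC3",
    "ASPC2",
    "ECA",
    "ASPCBlock",
    "ASPPBlock",
    "eca_kernel_size",
    "aspc_branch_widths",
    "eca_apply",
    "aspc_forward",
    "aspp_forward",
    "receptive_field",
    "receptive_field_empirical",
]


@dataclass(frozen=True)
class ECAConfig:
    """Channel-attention settings. kernel_size "adaptive" applies the
    log2(C)-based rule of `eca_kernel_size`; explicit sizes must be odd."""

    kernel_size: int | str = "adaptive"
    gamma: int = 2
    b: int = 1

    def __post_init__(self):
        if isinstance(self.kernel_size, int):
            if self.kernel_size < 1 or self.kernel_size % 2 == 0:
                raise ValueError("explicit ECA kernel size must be odd and >= 1")
        elif self.kernel_size != "adaptive":
            raise ValueError("kernel_size must be an odd int or 'adaptive'")


@dataclass(frozen=True)
class ASPCConfig:
    dilations: tuple[int, ...]
    channel_fractions: tuple[float, ...]
    kernel_size: int = 3

    def __post_init__(self):
        if len(self.dilations) != len(self.channel_fractions):
            raise ValueError("dilations and channel_fractions must align")
        if abs(sum(self.channel_fractions) - 1.0) > 1e-9:
            raise ValueError("channel fractions must sum to 1")


#: Presets: three-rate pyramid (dilations 1/2/3, widths 50/25/25 %) for the
#: first two encoder levels, two-rate pyramid (1/2 at 50/50 %) for the third.
ASPC3 = ASPCConfig(dilations=(1, 2, 3), channel_fractions=(0.5, 0.25, 0.25))
ASPC2 = ASPCConfig(dilations=(1, 2), channel_fractions=(0.5, 0.5))


def eca_kernel_size(C: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel size: nearest odd integer to |log2(C) + b| / gamma.

    t = int(|log2(C)/gamma + b/gamma|); k = t if t is odd else t + 1, min 1.
    """
    if C < 1:
        raise ValueError("channel count must be >= 1")
    t = int(abs(np.log2(C) / gamma + b / gamma))
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


def aspc_branch_widths(fractions: tuple[float, ...], c_out: int) -> tuple[int, ...]:
    """Partition c_out channels by fraction: floor for the non-primary
    branches, remainder to branch 0 (the 50 % branch), so widths always sum
    exactly to c_out."""
    if c_out < len(fractions):
        raise ValueError(f"c_out={c_out} smaller than branch count {len(fractions)}")
    widths = [max(1, int(f * c_out)) for f in fractions]
    widths[0] = c_out - sum(widths[1:])
    if widths[0] < 1:
        raise ValueError("channel partition infeasible for this width")
    return tuple(widths)


class ECA(nn.Module):
    """Efficient channel attention over an (N, C, H, W) feature map."""

    def __init__(self, channels: int, config: ECAConfig = ECAConfig(), rng=None):
        rng = rng or np.random.default_rng(0)
        if config.kernel_size == "adaptive":
            k = eca_kernel_size(channels, config.gamma, config.b)
        else:
            k = int(config.kernel_size)
        self.kernel_size = k
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(k), (k,)))
        self.channels = channels

    def scales(self, x: Tensor) -> Tensor:
        """(N, C) sigmoid channel weights s(c), each strictly in (0, 1)."""
        desc = ag.global_avg_pool(x)
        return ag.sigmoid(ag.conv1d_channels(desc, self.weight))

    def forward(self, x: Tensor) -> Tensor:
        s = self.scales(x)
        N, C = s.data.shape
        return ag.mul(x, ag.reshape(s, (N, C, 1, 1)))


class ASPCBlock(nn.Module):
    """One ASPC convolution stage: parallel dilated 3x3 convolutions whose
    concatenated output has exactly c_out channels, then batch norm + ReLU.

    Branch convolutions are standard (dense) by default; set separable=True
    for depthwise-separable branches.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 config: ASPCConfig = ASPC3, batchnorm: bool = True,
                 separable: bool = False, rng=None):
        rng = rng or np.random.default_rng(0)
        widths = aspc_branch_widths(config.channel_fractions, out_channels)
        self.config = config
        self.branch_widths = widths
        self.branches: list[nn.Module] = []
        for d, w in zip(config.dilations, widths):
            if separable:
                self.branches.append(_SeparableConv(in_channels, w, config.kernel_size, d, rng))
            else:
                self.branches.append(nn.Conv2d(in_channels, w, config.kernel_size, d, rng=rng))
        self.bn = nn.BatchNorm2d(out_channels) if batchnorm else None

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        y = ag.concat([branch(x) for branch in self.branches], axis=1)
        if self.bn is not None:
            y = self.bn(y, train)
        return ag.relu(y)


class _SeparableConv(nn.Module):
    """Depthwise dilated kxk followed by pointwise 1x1."""

    def __init__(self, in_channels, out_channels, kernel_size=3, dilation=1, rng=None):
        self.depthwise = nn.DepthwiseConv2d(in_channels, kernel_size, dilation, rng=rng)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class ASPPBlock(nn.Module):
    """Atrous spatial pyramid pooling with a global-pool branch.

    Five branches — 1x1 conv, three depthwise-separable 3x3 convs at the
    given dilations, and a global average pool broadcast back to H x W —
    concatenated and fused by a 1x1 convolution to out_channels.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 dilations: tuple[int, int, int] = (1, 3, 5), rng=None):
        rng = rng or np.random.default_rng(0)
        if out_channels < 5:
            raise ValueError("ASPP needs out_channels >= 5")
        self.point = nn.Conv2d(in_channels, out_channels, 1, rng=rng)
        self.atrous = [
            _SeparableConv(in_channels, out_channels, 3, d, rng=rng) for d in dilations
        ]
        fused_in = 4 * out_channels + in_channels
        self.fuse = nn.Conv2d(fused_in, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.data.shape
        pooled = ag.expand_hw(ag.global_avg_pool(x), H, W)
        branches = [self.point(x)] + [b(x) for b in self.atrous] + [pooled]
        return self.fuse(ag.concat(branches, axis=1))


def _to_nchw(hwc: np.ndarray) -> Tensor:
    return Tensor(np.transpose(hwc, (2, 0, 1))[None])


def _to_hwc(t: Tensor) -> np.ndarray:
    return np.transpose(t.data[0], (1, 2, 0))


def eca_apply(feature_map: np.ndarray, eca: ECA) -> np.ndarray:
    """Apply channel attention to a single H x W x C feature map."""
    if feature_map.ndim != 3:
        raise ValueError("feature_map must be H x W x C")
    return _to_hwc(eca(_to_nchw(feature_map)))


def aspc_forward(feature_map: np.ndarray, block: ASPCBlock) -> np.ndarray:
    """Run one ASPC stage on a single H x W x C feature map."""
    return _to_hwc(block(_to_nchw(feature_map), train=False))


def aspp_forward(feature_map: np.ndarray, block: ASPPBlock) -> np.ndarray:
    """Run an ASPP stage on a single H x W x C feature map."""
    return _to_hwc(block(_to_nchw(feature_map)))


def receptive_field(dilation_stack: tuple[int, ...] | list[int], kernel: int = 3) -> int:
    """Receptive-field side length of stacked 'same' dilated convolutions.

    RF = 1 + sum_i d_i * (kernel - 1). The empty stack is the identity (RF 1).
    A stack at dilations (1, 2) of 3x3 kernels reaches 7x7; (2, 3) reaches
    11x11.
    """
    if any(d < 1 for d in dilation_stack):
        raise ValueError("dilations must be >= 1")
    return 1 + sum(d * (kernel - 1) for d in dilation_stack)


def receptive_field_empirical(dilation_stack, kernel: int = 3, grid: int = 33) -> int:
    """Impulse-response oracle for `receptive_field`.

    Builds the convolution stack with all-ones kernels, takes the gradient of
    the centered output unit with respect to the input on a grid x grid
    image, and returns the side length of the square support of that
    gradient. Exact as long as grid >= the analytic receptive field.
    """
    x = Parameter(np.zeros((1, 1, grid, grid), dtype=np.float32))
    y: Tensor = x
    for d in dilation_stack:
        w = Tensor(np.ones((1, 1, kernel, kernel), dtype=np.float32))
        y = ag.conv2d(y, w, dilation=int(d))
    c = grid // 2
    seed = np.zeros_like(y.data)
    seed[0, 0, c, c] = 1.0
    y.backward(seed)
    support = np.nonzero(x.grad[0, 0])
    if support[0].size == 0:
        return 1
    rows = support[0].max() - support[0].min() + 1
    cols = support[1].max() - support[1].min() + 1
    if rows != cols:
        raise AssertionError("impulse response support is not square")
    return int(rows)
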