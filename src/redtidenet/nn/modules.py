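"""Layer modules over the autodiff core: parameter containers with He init."""

from __future__ import annotations

import copy
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for mod in self._modules():
            for value in vars(mod).values():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    yield value

    def _modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value._modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item._modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter + batch-norm running-stat arrays, in stable order."""
        arrays = [p.data for p in self.parameters()]
        for mod in self._modules():
            if isinstance(mod, BatchNorm2d):
                arrays.extend([mod.running_mean, mod.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), state, strict=True):
            dst[...] = src

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """'Same' dilated 2-D convolution, He-initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int = 3, dilation: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel_size * kernel_size))
        self.weight = Parameter(rng.normal(0.0, std, (channels, kernel_size, kernel_size)))
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution: exact spatial doubling."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_channels * 4))
        self.weight = Parameter(rng.normal(0.0, std, (in_channels, out_channels, 2, 2)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor, train: bool) -> Tensor:
        return ag.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            train=train, momentum=self.momentum, eps=self.eps,
        )


class ConvUnit(Module):
    """conv -> (batch norm) -> ReLU, the basic encoder/decoder stage."""

    def __init__(self, in_channels, out_channels, kernel_size=3, dilation=1,
                 batchnorm: bool = True, rng=None):
        self.conv = Conv2d(in_channels, out_channels, kernel_size, dilation, rng=rng)
        self.bn = BatchNorm2d(out_channels) if batchnorm else None

    def forward(self, x: Tensor, train: bool) -> Tensor:
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y, train)
        return ag.relu(y)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            if self.lr != 0.0:
                p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clone_module(module: Module) -> Module:
    return copy.deepcopy(module)
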