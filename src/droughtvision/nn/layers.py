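"""Layer/module abstractions over the autograd core.

Conventions follow the detection-network arithmetic this package pins
against its reference architecture table: convolutions carry no bias and
are followed by batch normalisation with learnable scale and shift (2
parameters per channel; running statistics are buffers, not parameters).
"""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock", "Sequential", "SGD"]


class Module:
    """Base class: parameter discovery, train/eval mode, counting."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for v in m.__dict__.values():
                items = v if isinstance(v, (list, tuple)) else (v,)
                for item in items:
                    if (isinstance(item, Tensor) and item.requires_grad
                            and id(item) not in seen):
                        seen.add(id(item))
                        yield item

    def count_parameters(self) -> int:
        """Number of trainable scalars (running stats excluded)."""
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if padding is None:
            padding = k // 2  # same-padding for odd kernels
        rng = rng or np.random.default_rng(0)
        fan_in = (c_in // groups) * k * k
        self.weight = Tensor(
            _kaiming(rng, (c_out, c_in // groups, k, k), fan_in), requires_grad=True
        )
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


_ACTS = {"silu": core.silu, "relu": core.relu, "gelu": core.gelu, None: lambda t: t}


class ConvBlock(Module):
    """Conv (no bias) + BatchNorm + activation — the basic `Conv` unit.

    Parameter count = c_out * (c_in/groups) * k^2 + 2 * c_out.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, act: str | None = "silu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride, padding, groups, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        return _ACTS[self.act](self.bn(self.conv(x)))


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.937,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
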