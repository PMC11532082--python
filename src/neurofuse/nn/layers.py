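"""Neural-network layers over the autodiff Tensor.

Torch-like surface (Module, Linear, Conv2d, BatchNorm, Dropout, Sequential)
kept to the minimum the fusion network requires.  All parameter
initialization draws from an explicit ``numpy.random.Generator`` so model
construction is fully reproducible from a seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, max_pool2d

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm1d",
    "BatchNorm2d",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "ReLU",
    "Dropout",
    "Flatten",
]


class Module:
    """Base class: parameter discovery, train/eval mode, zero_grad."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_all_parameters(self) -> None:
        """Set every learnable parameter (weights, biases, affine terms) to 0.

        Used by algebraic contract checks that exercise the zero-weight limit
        of attention and residual modules.
        """
        for p in self.parameters():
            p.data[...] = 0.0


class ModuleList(Module):
    def __init__(self, items: list[Module]):
        super().__init__()
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = math.sqrt(2.0 / in_dim)  # He initialization
        self.weight = Tensor(rng.normal(0.0, bound, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out if self.bias is None else out + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
    ):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        bound = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, bound, (out_ch, in_ch, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class _BatchNorm(Module):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def _normalize(self, x: Tensor, axes: tuple[int, ...], shape) -> Tensor:
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            m = 1.0 / max(1, int(np.prod([x.shape[a] for a in axes])) - 1)
            unbiased = var.data * int(np.prod([x.shape[a] for a in axes])) * m
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * unbiased.reshape(-1)
            )
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class BatchNorm1d(_BatchNorm):
    """Normalizes each feature over the batch dimension of an (N, D) input."""

    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0,), (1, x.shape[1]))


class BatchNorm2d(_BatchNorm):
    """Normalizes each channel over batch and spatial dims of an NCHW input."""

    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0, 2, 3), (1, x.shape[1], 1, 1))


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    """NCHW -> (N, C) mean over the spatial dimensions."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
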