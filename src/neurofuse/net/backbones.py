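"""CNN backbones exposing four feature-extraction stages.

Each backbone provides ``stem`` (pre-stage layers), ``stages`` (four
modules) and ``channels`` (the channel count after each stage), which is
what the fusion network needs to pair FCN blocks with CNN blocks and to
attach fusion modules after stages 2-4.

``tiny`` is a four-stage desk-scale convnet (channels 16/32/64/128, 32x32
input) for CPU experiments and tests; the ResNet and VGG families follow
their standard layouts.
"""

from __future__ import annotations

import numpy as np

from ..nn import (
    BatchNorm2d,
    Conv2d,
    MaxPool2d,
    Module,
    ModuleList,
    ReLU,
    Sequential,
)
from ..nn.tensor import Tensor

__all__ = ["build_backbone", "Backbone"]


class Backbone(Module):
    def __init__(self, stem: Module, stages: list[Module], channels: list[int]):
        super().__init__()
        self.stem = stem
        self.stages = ModuleList(stages)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:  # plain forward, no hooks
        x = self.stem(x)
        for stage in self.stages:
            x = stage(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _conv_bn_relu(in_ch, out_ch, k, rng, stride=1, padding=0):
    return Sequential(
        Conv2d(in_ch, out_ch, k, rng, stride=stride, padding=padding, bias=False),
        BatchNorm2d(out_ch),
        ReLU(),
    )


def _tiny(rng) -> Backbone:
    channels = [16, 32, 64, 128]
    stages = []
    in_ch = 3
    for out_ch in channels:
        stages.append(_conv_bn_relu(in_ch, out_ch, 3, rng, stride=2, padding=1))
        in_ch = out_ch
    return Backbone(Identity(), stages, channels)


class _BasicBlock(Module):
    expansion = 1

    def __init__(self, in_ch, planes, rng, stride=1):
        super().__init__()
        self.conv1 = Conv2d(in_ch, planes, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, rng, stride=1, padding=1, bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.down = None
        if stride != 1 or in_ch != planes:
            self.down = Sequential(
                Conv2d(in_ch, planes, 1, rng, stride=stride, bias=False),
                BatchNorm2d(planes),
            )

    def forward(self, x):
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = x if self.down is None else self.down(x)
        return (out + shortcut).relu()


class _Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch, planes, rng, stride=1):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = Conv2d(in_ch, planes, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, rng, stride=stride, padding=1, bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, out_ch, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(out_ch)
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(
                Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
                BatchNorm2d(out_ch),
            )

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = x if self.down is None else self.down(x)
        return (out + shortcut).relu()


def _resnet(block, layout, rng) -> Backbone:
    stem = Sequential(
        Conv2d(3, 64, 7, rng, stride=2, padding=3, bias=False),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, stride=2, padding=1),
    )
    stages = []
    channels = []
    in_ch = 64
    for i, (planes, n_blocks) in enumerate(zip([64, 128, 256, 512], layout)):
        blocks = []
        for j in range(n_blocks):
            stride = 2 if (i > 0 and j == 0) else 1
            blocks.append(block(in_ch, planes, rng, stride=stride))
            in_ch = planes * block.expansion
        stages.append(Sequential(*blocks))
        channels.append(in_ch)
    return Backbone(stem, stages, channels)


def _vgg(conv_layout, rng) -> Backbone:
    # first conv block acts as the stem; the remaining four are the stages
    plans = list(zip([64, 128, 256, 512, 512], conv_layout))
    in_ch = 3

    def block(out_ch, n_convs):
        nonlocal in_ch
        layers = []
        for _ in range(n_convs):
            layers += [
                Conv2d(in_ch, out_ch, 3, rng, padding=1),
                BatchNorm2d(out_ch),
                ReLU(),
            ]
            in_ch = out_ch
        layers.append(MaxPool2d(2))
        return Sequential(*layers)

    stem = block(*plans[0])
    stages = [block(out, n) for out, n in plans[1:]]
    return Backbone(stem, stages, [p[0] for p in plans[1:]])


_BUILDERS = {
    "tiny": _tiny,
    "resnet18": lambda rng: _resnet(_BasicBlock, [2, 2, 2, 2], rng),
    "resnet34": lambda rng: _resnet(_BasicBlock, [3, 4, 6, 3], rng),
    "resnet50": lambda rng: _resnet(_Bottleneck, [3, 4, 6, 3], rng),
    "resnet101": lambda rng: _resnet(_Bottleneck, [3, 4, 23, 3], rng),
    "vgg16": lambda rng: _vgg([2, 2, 3, 3, 3], rng),
    "vgg19": lambda rng: _vgg([2, 2, 4, 4, 4], rng),
}


def build_backbone(name: str, rng: np.random.Generator) -> Backbone:
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}") from None
    return builder(rng)
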