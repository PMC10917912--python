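"""Convolutional backbones exposing a three-level feature hierarchy.

The fusion neck consumes the deepest three scales of a trunk network:
``B4`` at stride 16, ``B5`` at stride 32 and ``B6`` at stride 64.  A
standard five-stage trunk (ResNeXt-style) ends at stride 32, so ``B6``
is synthesised with an extra stride-2 3x3 convolution on ``B5`` — the
same construction RetinaNet uses for its P6 level.

Any module that maps an ``N x 3 x H x W`` batch to such a hierarchy and
reports its per-level channel counts is a valid backbone; the neck and
heads only rely on this contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from . import nn
from .nn.tensor import Tensor

LEVELS: Tuple[int, int, int] = (4, 5, 6)
STRIDES: Dict[int, int] = {4: 16, 5: 32, 6: 64}


@dataclass
class FeatureMap:
    """One activation grid tagged with its pyramid level and stride."""

    tensor: Tensor
    level: int
    stride: int

    @property
    def channels(self) -> int:
        return self.tensor.shape[1]

    @property
    def spatial(self) -> Tuple[int, int]:
        return self.tensor.shape[2], self.tensor.shape[3]


@dataclass
class FeatureHierarchy:
    """The ordered multi-scale maps {B4, B5, B6} emitted by a backbone."""

    maps: Dict[int, FeatureMap]
    channels: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        levels = sorted(self.maps)
        if len(levels) != 3:
            raise ValueError(f"expected exactly 3 pyramid levels, got {levels}")
        if not self.channels:
            self.channels = {n: self.maps[n].channels for n in levels}
        prev = None
        for n in levels:
            fm = self.maps[n]
            if prev is not None:
                if fm.stride <= prev.stride:
                    raise ValueError("strides must be strictly increasing with level")
                ph, pw = prev.spatial
                h, w = fm.spatial
                if h > ph or w > pw:
                    raise ValueError("spatial resolution must not grow with level")
            prev = fm

    def __getitem__(self, level: int) -> FeatureMap:
        return self.maps[level]

    @property
    def levels(self) -> Sequence[int]:
        return sorted(self.maps)


def _validate_batch(x: Tensor) -> None:
    if x.ndim != 4:
        raise ValueError(f"expected an N x 3 x H x W batch, got shape {x.shape}")
    n, c, h, w = x.shape
    if n == 0:
        raise ValueError("empty batch")
    if c != 3:
        raise ValueError(f"expected 3 input channels, got {c}")
    if h % 32 or w % 32:
        raise ValueError(f"spatial size {h}x{w} must be divisible by 32")


class Backbone(nn.Module):
    """Contract: `extract_hierarchy` returns {B4, B5, B6}; `out_channels` reports widths."""

    out_channels: Dict[int, int]

    def extract_hierarchy(self, x: Tensor) -> FeatureHierarchy:
        _validate_batch(x)
        return self._extract(x)

    def _extract(self, x: Tensor) -> FeatureHierarchy:
        raise NotImplementedError

    def forward(self, x: Tensor) -> FeatureHierarchy:
        return self.extract_hierarchy(x)


class _Bottleneck(nn.Module):
    """ResNeXt bottleneck: 1x1 reduce, grouped 3x3, 1x1 expand, residual add."""

    def __init__(self, in_ch: int, planes: int, out_ch: int, stride: int, cardinality: int, base_width: int):
        super().__init__()
        width = int(planes * base_width / 64.0) * cardinality
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1, groups=cardinality, bias=False)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch),
            )
        else:
            self.down = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + self.down(x)).relu()


class ResNeXtBackbone(Backbone):
    """ResNeXt-50 (32x4d by default) trunk with a synthesised stride-64 level.

    Native stage outputs at strides 16 and 32 carry 1024 and 2048
    channels; the extra B6 reduction emits ``b6_channels`` (default 512).
    """

    def __init__(
        self,
        layers: Sequence[int] = (3, 4, 6, 3),
        cardinality: int = 32,
        base_width: int = 4,
        b6_channels: int = 512,
    ):
        super().__init__()
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(64)
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)

        def stage(in_ch, planes, blocks, stride):
            mods = [_Bottleneck(in_ch, planes, planes * 4, stride, cardinality, base_width)]
            for _ in range(blocks - 1):
                mods.append(_Bottleneck(planes * 4, planes, planes * 4, 1, cardinality, base_width))
            return nn.Sequential(*mods)

        self.layer1 = stage(64, 64, layers[0], 1)     # stride 4
        self.layer2 = stage(256, 128, layers[1], 2)   # stride 8
        self.layer3 = stage(512, 256, layers[2], 2)   # stride 16 -> B4
        self.layer4 = stage(1024, 512, layers[3], 2)  # stride 32 -> B5
        self.b6_conv = nn.Conv2d(2048, b6_channels, 3, stride=2, padding=1)
        self.out_channels = {4: 1024, 5: 2048, 6: b6_channels}

    def _extract(self, x: Tensor) -> FeatureHierarchy:
        out = self.stem_bn(self.stem_conv(x)).relu()
        out = self.pool(out)
        out = self.layer1(out)
        out = self.layer2(out)
        b4 = self.layer3(out)
        b5 = self.layer4(b4)
        b6 = self.b6_conv(b5)
        return FeatureHierarchy(
            {
                4: FeatureMap(b4, 4, STRIDES[4]),
                5: FeatureMap(b5, 5, STRIDES[5]),
                6: FeatureMap(b6, 6, STRIDES[6]),
            }
        )

    def load_pretrained(self, path: str) -> None:
        """Optionally load trunk weights from an ``.npz`` state dict."""
        state = dict(np.load(path))
        self.load_state_dict(state)


class TinyBackbone(Backbone):
    """A small plain-conv trunk with the same hierarchy contract.

    Intended for fast experiments: five stride-2 stages reach stride 32,
    plus the stride-64 reduction.  Channel widths are (w4, w5, w6).
    """

    def __init__(self, widths: Sequence[int] = (16, 32, 32)):
        super().__init__()
        w4, w5, w6 = widths

        def block(cin, cout, stride):
            return nn.Sequential(
                nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False),
                nn.BatchNorm2d(cout),
                nn.ReLU(),
            )

        self.stage1 = block(3, w4 // 2, 2)       # stride 2
        self.stage2 = block(w4 // 2, w4 // 2, 2)  # 4
        self.stage3 = block(w4 // 2, w4 // 2, 2)  # 8
        self.stage4 = block(w4 // 2, w4, 2)       # 16 -> B4
        self.stage5 = block(w4, w5, 2)            # 32 -> B5
        self.b6_conv = nn.Conv2d(w5, w6, 3, stride=2, padding=1)
        self.out_channels = {4: w4, 5: w5, 6: w6}

    def _extract(self, x: Tensor) -> FeatureHierarchy:
        out = self.stage3(self.stage2(self.stage1(x)))
        b4 = self.stage4(out)
        b5 = self.stage5(b4)
        b6 = self.b6_conv(b5)
        return FeatureHierarchy(
            {
                4: FeatureMap(b4, 4, STRIDES[4]),
                5: FeatureMap(b5, 5, STRIDES[5]),
                6: FeatureMap(b6, 6, STRIDES[6]),
            }
        )


_BACKBONES = {
    "resnext50_32x4d": ResNeXtBackbone,
    "tiny": TinyBackbone,
}


def build_backbone(name: str = "resnext50_32x4d", **kwargs) -> Backbone:
    try:
        cls = _BACKBONES[name]
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; choices: {sorted(_BACKBONES)}") from None
    return cls(**kwargs)
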