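"""Convolutional block attention (CBAM): channel gating then spatial gating.

Channel attention pools each feature map globally over space (average
and max), pushes both descriptors through one shared two-layer MLP and
gates channels with the sigmoid of their sum:

    M_c(F) = sigma( MLP(AvgPool(F)) + MLP(MaxPool(F)) ),   F' = M_c(F) * F

Spatial attention pools across the channel axis instead, stacks the two
H x W maps and reads a single-channel gate off a 7x7 convolution:

    M_s(F') = sigma( f_{7x7}([AvgPool(F'); MaxPool(F')]) ),  F'' = M_s(F') * F'

Both gates lie strictly inside (0, 1), so the refined map never exceeds
the input in element-wise magnitude.
"""

from __future__ import annotations

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concatenate


class ChannelAttention(nn.Module):
    """Shared-MLP channel gate with reduction ratio ``reduction``."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels ({channels}) must be divisible by reduction ({reduction})")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, channels, bias=False)

    def attention_map(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = F.global_avg_pool2d(x).reshape(n, c)
        mx = F.global_max_pool2d(x).reshape(n, c)
        a = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return a.sigmoid().reshape(n, c, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x)


class SpatialAttention(nn.Module):
    """Single-channel spatial gate from channel-pooled statistics."""

    def __init__(self, kernel_size: int = 7):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.conv = nn.Conv2d(2, 1, kernel_size, padding=kernel_size // 2, bias=False)

    def attention_map(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concatenate([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x)


class CBAM(nn.Module):
    """Channel attention followed by spatial attention; shape preserving."""

    def __init__(self, channels: int, reduction: int = 16, kernel_size: int = 7):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction)
        self.spatial = SpatialAttention(kernel_size)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


def channel_attention(x: Tensor, block: CBAM) -> Tensor:
    """Apply only the channel-gating half of ``block``."""
    return block.channel(x)


def spatial_attention(x: Tensor, block: CBAM) -> Tensor:
    """Apply only the spatial-gating half of ``block``."""
    return block.spatial(x)


def apply_cbam(x: Tensor, block: CBAM) -> Tensor:
    """Channel then spatial attention — the refined output feature."""
    return block(x)
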