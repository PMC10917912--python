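"""Weighted dual-pathway feature fusion (the wFPN neck).

Every fusion site combines two same-shape maps with *fast-normalised*
weights: with non-negative learnable scalars w_i and a small epsilon,

    O = sum_i  w_i / (sum_j w_j + eps) * I_i .

The coefficients are each in [0, 1), sum to sum(w)/(sum(w)+eps) < 1, and
cost no exponentials (unlike softmax weighting).  The neck runs

* a top-down pathway: F6 from globally pooled B6, then
  F_n = Conv3x3( fuse( Conv1x1(B_n), Upsample(F_{n+1}) ) );
* per-level CBAM refinement F_n -> F''_n;
* a bottom-up pathway: P4 = F''4, then
  P_n = Conv3x3( fuse( F''_n, Downsample(P_{n-1}) ) )  (no 1x1
  projection — everything is already 256 channels).

Because F6 is produced by global pooling it is spatially 1x1; its
upsampling is a spatial broadcast, so the level-6 branch carries global
context down the pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import nn
from .attention import CBAM
from .backbone import FeatureHierarchy
from .nn import functional as F
from .nn.tensor import Tensor

EPSILON_DEFAULT = 1e-4


class FusionNode(nn.Module):
    """One fusion site: learnable weights + smoothing/projection convs.

    Raw weights start at 1 and are rectified (ReLU) before normalising,
    which keeps every effective weight non-negative.
    """

    def __init__(
        self,
        num_inputs: int = 2,
        channels: int = 256,
        epsilon: float = EPSILON_DEFAULT,
        in_channels: Optional[int] = None,
        smoothing: bool = True,
    ):
        super().__init__()
        if num_inputs < 1:
            raise ValueError("a fusion node needs at least one input")
        if epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        # epsilon = 0 is permitted for exact arithmetic, but then the
        # rectified weights must not all vanish
        self.num_inputs = num_inputs
        self.epsilon = epsilon
        self.raw_weights = nn.Parameter(np.ones(num_inputs))
        self.projection_conv = (
            nn.Conv2d(in_channels, channels, 1) if in_channels is not None else None
        )
        self.smoothing_conv = nn.Conv2d(channels, channels, 3, padding=1) if smoothing else nn.Identity()

    def fusion_coefficients(self) -> Tensor:
        """Normalised per-input coefficients w_i / (sum_j w_j + eps)."""
        w = self.raw_weights.relu()
        return w / (w.sum() + self.epsilon)

    def project(self, x: Tensor) -> Tensor:
        return self.projection_conv(x) if self.projection_conv is not None else x

    def smooth(self, x: Tensor) -> Tensor:
        return self.smoothing_conv(x)


def fast_normalized_fusion(inputs: Sequence[Tensor], node: FusionNode) -> Tensor:
    """Weighted sum of same-shape maps with fast-normalised coefficients."""
    if len(inputs) != node.num_inputs:
        raise ValueError(f"node expects {node.num_inputs} inputs, got {len(inputs)}")
    shapes = {tuple(t.shape) for t in inputs}
    if len(shapes) != 1:
        raise ValueError(f"fusion inputs must share a shape, got {sorted(shapes)}")
    coeffs = node.fusion_coefficients()
    out = coeffs[0] * inputs[0]
    for i in range(1, len(inputs)):
        out = out + coeffs[i] * inputs[i]
    return out


def top_down_step(b_n: Tensor, f_above: Tensor, node: FusionNode) -> Tensor:
    """F_n = Conv3( fuse( Conv1(B_n), Upsample(F_{n+1}) ) )."""
    projected = node.project(b_n)
    target = projected.shape[2:]
    if f_above.shape[2] > target[0] or f_above.shape[3] > target[1]:
        raise ValueError("top-down input must be at coarser or equal resolution")
    resized = F.upsample_nearest(f_above, target)
    return node.smooth(fast_normalized_fusion([projected, resized], node))


class TopNode(nn.Module):
    """F6 = Conv1( GlobalAvgPool(B6) + GlobalMaxPool(B6) ): a 1x1 seed map."""

    def __init__(self, in_channels: int, channels: int = 256):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, channels, 1)

    def forward(self, b6: Tensor) -> Tensor:
        pooled = F.global_avg_pool2d(b6) + F.global_max_pool2d(b6)
        return self.conv(pooled)


def top_node_init(b6: Tensor, node: TopNode) -> Tensor:
    return node(b6)


def bottom_up_step(f_refined: Tensor, p_below: Tensor, node: FusionNode) -> Tensor:
    """P_n = Conv3( fuse( F''_n, Downsample(P_{n-1}) ) ); channels stay 256."""
    target = f_refined.shape[2:]
    if p_below.shape[2] < target[0] or p_below.shape[3] < target[1]:
        raise ValueError("bottom-up input must be at finer or equal resolution")
    resized = F.adaptive_avg_pool2d(p_below, target)
    return node.smooth(fast_normalized_fusion([f_refined, resized], node))


@dataclass
class NeckOutput:
    """All maps the neck emits, keyed by pyramid level (4, 5, 6)."""

    top_down: Dict[int, Tensor]
    refined: Dict[int, Tensor]
    bottom_up: Dict[int, Tensor]

    def all_maps(self) -> Dict[str, Tensor]:
        out = {}
        for n, t in self.top_down.items():
            out[f"F{n}"] = t
        for n, t in self.bottom_up.items():
            out[f"P{n}"] = t
        return out


class WeightedPyramidNeck(nn.Module):
    """Top-down + CBAM + bottom-up weighted fusion over levels {4, 5, 6}."""

    def __init__(
        self,
        in_channels: Dict[int, int],
        channels: int = 256,
        epsilon: float = EPSILON_DEFAULT,
        reduction: int = 16,
    ):
        super().__init__()
        self.levels: List[int] = sorted(in_channels)
        if len(self.levels) < 2:
            raise ValueError("the neck needs at least two pyramid levels")
        self.channels = channels
        self.epsilon = epsilon
        top = self.levels[-1]
        self.top_node = TopNode(in_channels[top], channels)
        # one top-down fusion node per non-top level, each with a 1x1 projection
        self.td_nodes = {
            n: FusionNode(2, channels, epsilon, in_channels=in_channels[n])
            for n in self.levels[:-1]
        }
        # independent CBAM parameters per level
        self.cbam = {n: CBAM(channels, reduction) for n in self.levels}
        # one bottom-up fusion node per non-bottom level; no projection
        self.bu_nodes = {n: FusionNode(2, channels, epsilon) for n in self.levels[1:]}

    def forward(self, hierarchy: FeatureHierarchy) -> NeckOutput:
        levels = self.levels
        top_down: Dict[int, Tensor] = {}
        top_down[levels[-1]] = self.top_node(hierarchy[levels[-1]].tensor)
        for n in reversed(levels[:-1]):
            top_down[n] = top_down_step(hierarchy[n].tensor, top_down[n + 1], self.td_nodes[n])
        refined = {n: self.cbam[n](top_down[n]) for n in levels}
        bottom_up: Dict[int, Tensor] = {levels[0]: refined[levels[0]]}
        for n in levels[1:]:
            bottom_up[n] = bottom_up_step(refined[n], bottom_up[n - 1], self.bu_nodes[n])
        return NeckOutput(top_down=top_down, refined=refined, bottom_up=bottom_up)
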