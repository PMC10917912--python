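"""The assembled classifier: backbone trunk -> weighted pyramid neck -> ensemble head."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

from . import nn
from .backbone import Backbone, FeatureHierarchy, build_backbone
from .heads import EnsembleHead
from .neck import NeckOutput, WeightedPyramidNeck
from .nn.tensor import Tensor


@dataclass
class ForwardDetail:
    """Everything one forward pass produces, for inspection and tests."""

    hierarchy: FeatureHierarchy
    neck: NeckOutput
    level_scores: Dict[int, Tensor]
    logits: Tensor


class WFPNClassifier(nn.Module):
    """Weighted feature-pyramid classifier for K-way fine-grained images."""

    def __init__(
        self,
        backbone: Backbone,
        num_classes: int = 4,
        channels: int = 256,
        epsilon: float = 1e-4,
        reduction: int = 16,
        hidden: int = 256,
    ):
        super().__init__()
        self.backbone = backbone
        self.num_classes = num_classes
        self.neck = WeightedPyramidNeck(
            dict(backbone.out_channels), channels=channels, epsilon=epsilon, reduction=reduction
        )
        self.head = EnsembleHead(
            levels=self.neck.levels,
            in_channels=channels,
            hidden=hidden,
            num_classes=num_classes,
            epsilon=epsilon,
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_detailed(x).logits

    def forward_detailed(self, x: Tensor) -> ForwardDetail:
        hierarchy = self.backbone(x)
        neck_out = self.neck(hierarchy)
        logits, level_scores = self.head(neck_out.bottom_up)
        return ForwardDetail(hierarchy, neck_out, level_scores, logits)


def build_model(config: Optional[Dict[str, Any]] = None) -> WFPNClassifier:
    """Build a classifier from a nested config dict.

    Recognised keys (all optional)::

        backbone: name (default "resnext50_32x4d") or {name: ..., kwargs...}
        neck:     {channels: 256, epsilon: 1e-4}
        cbam:     {reduction: 16}
        head:     {num_classes: 4, hidden: 256}
    """
    cfg = config or {}
    bb_cfg = cfg.get("backbone", "resnext50_32x4d")
    if isinstance(bb_cfg, str):
        backbone = build_backbone(bb_cfg)
    else:
        bb_cfg = dict(bb_cfg)
        backbone = build_backbone(bb_cfg.pop("name"), **bb_cfg)
    neck_cfg = cfg.get("neck", {})
    head_cfg = cfg.get("head", {})
    return WFPNClassifier(
        backbone,
        num_classes=head_cfg.get("num_classes", 4),
        channels=neck_cfg.get("channels", 256),
        epsilon=neck_cfg.get("epsilon", 1e-4),
        reduction=cfg.get("cbam", {}).get("reduction", 16),
        hidden=head_cfg.get("hidden", 256),
    )
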