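"""Per-level classifiers and their weighted ensemble.

Each pyramid level gets its own classifier: global average pooling over
the fused map, then two fully connected layers producing K raw class
scores (logits).  The final prediction is a fast-normalised weighted
average of the three score vectors,

    pred = sum_k w_k * out_k / (eps + sum_k w_k),

with non-negative learnable w_k.  Note the epsilon here is added once to
the summed denominator — a slightly different placement from the fusion
nodes in the neck — and the ensembled quantities are logits, not
probabilities; the training loss is cross-entropy on ``pred`` alone.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


class LevelClassifier(nn.Module):
    """GAP -> FC -> ReLU -> FC, emitting one K-vector of logits per image."""

    def __init__(self, in_channels: int = 256, hidden: int = 256, num_classes: int = 4):
        super().__init__()
        self.in_channels = in_channels
        self.fc1 = nn.Linear(in_channels, hidden)
        self.fc2 = nn.Linear(hidden, num_classes)

    def forward(self, p: Tensor) -> Tensor:
        if p.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {p.shape[1]}")
        n, c = p.shape[0], p.shape[1]
        pooled = F.global_avg_pool2d(p).reshape(n, c)
        return self.fc2(self.fc1(pooled).relu())


class EnsembleHead(nn.Module):
    """Three level classifiers plus learnable non-negative ensemble weights."""

    def __init__(
        self,
        levels: Sequence[int] = (4, 5, 6),
        in_channels: int = 256,
        hidden: int = 256,
        num_classes: int = 4,
        epsilon: float = 1e-4,
    ):
        super().__init__()
        self.levels: List[int] = sorted(levels)
        self.num_classes = num_classes
        self.epsilon = epsilon
        self.classifiers = {n: LevelClassifier(in_channels, hidden, num_classes) for n in self.levels}
        self.ensemble_raw_weights = nn.Parameter(np.ones(len(self.levels)))

    def classify_level(self, level: int, p: Tensor) -> Tensor:
        return self.classifiers[level](p)

    def ensemble(self, outs: Sequence[Tensor]) -> Tensor:
        if len(outs) != len(self.levels):
            raise ValueError(f"expected {len(self.levels)} score vectors, got {len(outs)}")
        w = self.ensemble_raw_weights.relu()
        num = w[0] * outs[0]
        for i in range(1, len(outs)):
            num = num + w[i] * outs[i]
        return num / (self.epsilon + w.sum())

    def forward(self, bottom_up: Dict[int, Tensor]) -> Tuple[Tensor, Dict[int, Tensor]]:
        outs = {n: self.classify_level(n, bottom_up[n]) for n in self.levels}
        pred = self.ensemble([outs[n] for n in self.levels])
        return pred, outs


def predicted_labels(scores: Tensor | np.ndarray) -> np.ndarray:
    """Argmax class per row; ties resolve to the lowest class index."""
    arr = scores.data if isinstance(scores, Tensor) else np.asarray(scores)
    return arr.argmax(axis=1)
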