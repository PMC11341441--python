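"""BiFormerAF: gated attention fusion of SRP5 with P3.

Two branches of identical shape are combined without increasing the
channel count:

    Y      = C2f(P3)
    X0     = BiFormer(C2f(SRP5))
    X1     = sigmoid(BatchNorm(X0))        (element-wise gate in (0, 1))
    NewP3  = Y + X0 * X1

The batch-norm buffer keeps the attention output in a range where the
sigmoid is informative; the gate re-weights the reconstructed features
before they are added onto the shallow branch.  The two C2f branches do
not share weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .bra import AttentionConfig, BiFormerBlock
from .nn import Tensor

__all__ = ["FusionConfig", "C2f", "WeightGate", "BiFormerAF"]


@dataclass
class FusionConfig:
    c2f_depth: int = 1
    attn: AttentionConfig = field(default_factory=AttentionConfig)


class Bottleneck(nn.Module):
    def __init__(self, ch: int, shortcut: bool = True):
        super().__init__()
        self.cv1 = nn.ConvBNSiLU(ch, ch, 3)
        self.cv2 = nn.ConvBNSiLU(ch, ch, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(nn.Module):
    """CSP split-transform-concat block (faster two-convolution variant).

    An initial 1x1 conv produces two half-width chunks; ``depth``
    bottlenecks each consume the newest chunk and append their output; all
    chunks are concatenated and re-projected.
    """

    def __init__(self, in_ch: int, out_ch: int, depth: int = 1, shortcut: bool = True):
        super().__init__()
        if depth < 0:
            raise ValueError("depth must be >= 0")
        self.hidden = max(out_ch // 2, 4)
        self.cv1 = nn.ConvBNSiLU(in_ch, 2 * self.hidden, 1)
        self.blocks = nn.ModuleList([Bottleneck(self.hidden, shortcut) for _ in range(depth)])
        self.cv2 = nn.ConvBNSiLU((2 + depth) * self.hidden, out_ch, 1)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.hidden]
        b = y[:, self.hidden :]
        chunks = [a, b]
        for blk in self.blocks:
            chunks.append(blk(chunks[-1]))
        return self.cv2(nn.concat(chunks, axis=1))


class WeightGate(nn.Module):
    """Element-wise gate: sigmoid(BatchNorm(x)), every entry in (0, 1)."""

    def __init__(self, ch: int):
        super().__init__()
        self.bn = nn.BatchNorm2d(ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(x).sigmoid()


class BiFormerAF(nn.Module):
    """Fuse the reconstructed SRP5 map with P3 into NewP3."""

    def __init__(self, ch: int, cfg: FusionConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or FusionConfig()
        self.branch_p3 = C2f(ch, ch, self.cfg.c2f_depth)
        self.branch_sr = C2f(ch, ch, self.cfg.c2f_depth)
        self.biformer = BiFormerBlock(ch, self.cfg.attn, rng)
        self.gate = WeightGate(ch)

    def forward(self, p3: Tensor, srp5: Tensor) -> Tensor:
        if p3.shape != srp5.shape:
            raise ValueError(
                f"P3 {p3.shape} and SRP5 {srp5.shape} must agree in (C, H, W)"
            )
        y = self.branch_p3(p3)
        x0 = self.biformer(self.branch_sr(srp5))
        return y + x0 * self.gate(x0)

    def branch_outputs(self, p3: Tensor, srp5: Tensor):
        """Return (Y, X0, X1) for diagnostic/algebraic checks."""
        y = self.branch_p3(p3)
        x0 = self.biformer(self.branch_sr(srp5))
        return y, x0, self.gate(x0)
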