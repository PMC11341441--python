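"""Bi-Level Routing Attention (BRA) and the BiFormer block.

BRA is a sparse attention mechanism that works in two stages.  The feature
map is first split into ``S x S`` non-overlapping regions.  A coarse
region-to-region affinity graph (the mean query of each region against the
mean key of every region) selects, for each region, the ``k`` most related
regions.  Fine-grained token-to-token attention is then computed only over
the key/value tokens gathered from those routed regions, plus a local
context enhancement (LCE) term: a depth-wise convolution applied to the
value tensor in its spatial layout.

All feature maps are channel-first ``(B, C, H, W)``; region tensors are
``(B, S^2, HW/S^2, C)`` with tokens in row-major spatial order inside each
region and regions numbered row-major over the ``S x S`` grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, functional as F

__all__ = [
    "AttentionConfig", "ProjectionWeights", "RoutingTables",
    "region_partition", "region_merge", "project_qkv", "region_routing",
    "gather_kv", "token_attention", "bra_forward", "BiFormerBlock",
]


@dataclass
class AttentionConfig:
    """Hyperparameters of one BRA stage.

    S: regions per image side (the map is split into S^2 regions).
    k: number of routed regions each region attends to (1 <= k <= S^2).
    num_heads: attention heads; must divide the channel count.
    lce_kernel: depth-wise convolution size of the local-context term.
    """

    S: int = 8
    k: int = 4
    num_heads: int = 4
    lce_kernel: int = 5

    def validate(self, C: int | None = None):
        if self.k < 1 or self.k > self.S * self.S:
            raise ValueError(f"k={self.k} must lie in [1, S^2={self.S * self.S}]")
        if self.lce_kernel % 2 != 1:
            raise ValueError("lce_kernel must be odd")
        if C is not None and C % self.num_heads:
            raise ValueError(f"num_heads={self.num_heads} must divide C={C}")


@dataclass
class ProjectionWeights:
    """Square C x C query/key/value projections, shared across regions."""

    Wq: Tensor
    Wk: Tensor
    Wv: Tensor

    @classmethod
    def random(cls, C: int, rng: np.random.Generator, trainable: bool = True):
        def make():
            w = (rng.standard_normal((C, C)) / np.sqrt(C)).astype(np.float32)
            return Tensor(w, requires_grad=trainable)

        return cls(make(), make(), make())

    @classmethod
    def identity(cls, C: int):
        eye = np.eye(C, dtype=np.float32)
        return cls(Tensor(eye.copy()), Tensor(eye.copy()), Tensor(eye.copy()))


@dataclass
class RoutingTables:
    """Region affinity matrix and top-k routed indices.

    Ar: (B, S^2, S^2) affinities; Ir: (B, S^2, k) integer indices, row i
    listing the k regions with largest affinity to region i in
    non-increasing order.
    """

    Ar: np.ndarray
    Ir: np.ndarray


def region_partition(x: Tensor, S: int) -> Tensor:
    """Split a (B, C, H, W) map into (B, S^2, HW/S^2, C) region tokens."""
    B, C, H, W = x.shape
    if H % S or W % S:
        raise ValueError(f"S={S} must divide H={H} and W={W} (no implicit padding)")
    h, w = H // S, W // S
    return (
        x.reshape(B, C, S, h, S, w)
        .transpose(0, 2, 4, 3, 5, 1)
        .reshape(B, S * S, h * w, C)
    )


def region_merge(xr: Tensor, S: int, H: int, W: int) -> Tensor:
    """Inverse of :func:`region_partition` (bit-exact round trip)."""
    B, S2, T, C = xr.shape
    if S2 != S * S or T != (H // S) * (W // S):
        raise ValueError("region tensor inconsistent with S, H, W")
    h, w = H // S, W // S
    return (
        xr.reshape(B, S, S, h, w, C)
        .transpose(0, 5, 1, 3, 2, 4)
        .reshape(B, C, H, W)
    )


def project_qkv(xr: Tensor, w: ProjectionWeights):
    """Linear per-token projections Q = Xr Wq, K = Xr Wk, V = Xr Wv."""
    C = xr.shape[-1]
    for name, W in (("Wq", w.Wq), ("Wk", w.Wk), ("Wv", w.Wv)):
        if W.shape != (C, C):
            raise ValueError(f"{name} has shape {W.shape}, expected ({C}, {C})")
    return xr @ w.Wq, xr @ w.Wk, xr @ w.Wv


def region_routing(Q: Tensor, K: Tensor, k: int) -> RoutingTables:
    """Coarse routing: affinities of region-mean queries vs keys, top-k rows.

    Qr and Kr are the per-region token means; Ar = Qr Kr^T.  Row i of Ir
    holds the indices of the k largest entries of Ar[i], best first.
    """
    B, S2, T, C = Q.shape
    if k < 1 or k > S2:
        raise ValueError(f"k={k} out of range [1, {S2}]")
    Qr = Q.data.mean(axis=2)  # (B, S2, C)
    Kr = K.data.mean(axis=2)
    Ar = np.matmul(Qr, Kr.transpose(0, 2, 1))  # (B, S2, S2)
    order = np.argsort(-Ar, axis=-1, kind="stable")
    Ir = order[..., :k]
    return RoutingTables(Ar=Ar, Ir=Ir)


def gather_kv(K: Tensor, V: Tensor, Ir: np.ndarray):
    """Concatenate, per region, the tokens of its routed regions (Ir order)."""
    B, S2, T, C = K.shape
    if Ir.min() < 0 or Ir.max() >= S2:
        raise IndexError(f"routing index outside [0, {S2})")
    k = Ir.shape[-1]
    bidx = np.arange(B)[:, None, None]
    Kg = K[bidx, Ir].reshape(B, S2, k * T, C)
    Vg = V[bidx, Ir].reshape(B, S2, k * T, C)
    return Kg, Vg


def _split_heads(t: Tensor, h: int) -> Tensor:
    B, S2, T, C = t.shape
    return t.reshape(B, S2, T, h, C // h).transpose(0, 1, 3, 2, 4)


def token_attention(Q: Tensor, Kg: Tensor, Vg: Tensor, V: Tensor,
                    cfg: AttentionConfig, hw: tuple[int, int],
                    lce_weight: Tensor | None = None) -> Tensor:
    """Scaled-dot-product attention over gathered tokens, plus LCE(V).

    ``hw`` is the spatial size of the underlying map (needed to restore the
    (B, C, H, W) layout and to run the depth-wise LCE convolution).  When
    ``lce_weight`` is None the LCE term is omitted.
    """
    B, S2, T, C = Q.shape
    cfg.validate(C)
    H, W = hw
    h = cfg.num_heads
    scale = 1.0 / np.sqrt(C / h)
    q = _split_heads(Q, h)            # (B, S2, h, T, C/h)
    kk = _split_heads(Kg, h)
    vv = _split_heads(Vg, h)
    logits = (q @ kk.transpose(0, 1, 2, 4, 3)) * scale
    attn = logits.softmax(axis=-1)
    out = attn @ vv                   # (B, S2, h, T, C/h)
    out = out.transpose(0, 1, 3, 2, 4).reshape(B, S2, T, C)
    out_map = region_merge(out, cfg.S, H, W)
    if lce_weight is not None:
        v_map = region_merge(V, cfg.S, H, W)
        pad = cfg.lce_kernel // 2
        out_map = out_map + F.conv2d(v_map, lce_weight, None, 1, pad, groups=C)
    return out_map


def bra_forward(x: Tensor, w: ProjectionWeights, cfg: AttentionConfig,
                lce_weight: Tensor | None = None) -> Tensor:
    """Full BRA: partition -> project -> route -> gather -> attend (+ LCE)."""
    B, C, H, W = x.shape
    cfg.validate(C)
    xr = region_partition(x, cfg.S)
    Q, K, V = project_qkv(xr, w)
    tables = region_routing(Q, K, cfg.k)
    Kg, Vg = gather_kv(K, V, tables.Ir)
    return token_attention(Q, Kg, Vg, V, cfg, (H, W), lce_weight)


class BRALayer(nn.Module):
    """BRA with learnable projections, LCE kernel and output projection."""

    def __init__(self, C: int, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        cfg.validate(C)
        self.w = ProjectionWeights.random(C, rng)
        self.Wq, self.Wk, self.Wv = self.w.Wq, self.w.Wk, self.w.Wv
        lce = (rng.standard_normal((C, 1, cfg.lce_kernel, cfg.lce_kernel))
               / cfg.lce_kernel).astype(np.float32)
        self.lce_weight = Tensor(lce, requires_grad=True)
        self.out_proj = nn.Conv2d(C, C, 1, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return self.out_proj(bra_forward(x, self.w, self.cfg, self.lce_weight))


class _MLP(nn.Module):
    def __init__(self, C: int, expansion: int = 3):
        super().__init__()
        self.fc1 = nn.Conv2d(C, C * expansion, 1)
        self.fc2 = nn.Conv2d(C * expansion, C, 1, zero_init=True)

    def forward(self, x):
        return self.fc2(self.fc1(x).silu())


class BiFormerBlock(nn.Module):
    """Depth-wise positional stage, then pre-norm residual BRA and MLP.

    Layout: ``x += DWConv3x3(x); x += BRA(LN(x)); x += MLP(LN(x))``.
    The BRA output projection and the MLP second layer are zero-initialised
    so a freshly built block starts close to the identity (plus the
    positional term), which stabilises training of the fusion stage.
    """

    def __init__(self, C: int, cfg: AttentionConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg or AttentionConfig()
        rng = rng or np.random.default_rng(0)
        self.pos = nn.Conv2d(C, C, 3, padding=1, groups=C)
        self.norm1 = nn.LayerNorm2d(C)
        self.attn = BRALayer(C, self.cfg, rng)
        self.norm2 = nn.LayerNorm2d(C)
        self.mlp = _MLP(C)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.pos(x)
        x = x + self.attn(self.norm1(x))
        x = x + self.mlp(self.norm2(x))
        return x
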