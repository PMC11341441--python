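"""FM-SR: feature-map super-resolution of the deepest pyramid level.

The deepest backbone map (P5, stride 32) is reconstructed to the spatial
size of the shallow map (P3, stride 8), i.e. magnified exactly fourfold:

    SRP5 = upsample_x4( body(sppcspc(P5)) + sppcspc(P5) )

* SPPCSPC front-end: a cross-stage-partial block whose inner branch pools
  the map with parallel stride-1 max-pools (kernels 1/5/9/13 by default,
  four receptive fields), concatenates and re-projects.
* Residual body: SRResNet-style blocks (conv-BN-PReLU-conv-BN + identity),
  five by default.
* A skip connection adds the body's input back onto its output before
  upsampling, so zeroing the body never zeroes the module.
* Upsampler: two sub-pixel (depth-to-space) x2 stages; a final 1x1
  projection sets the channel count to match P3 for element-wise fusion.

Training is end to end from the detection loss; FM-SR has no separate
super-resolution objective or pretraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .nn import Tensor, functional as F

__all__ = ["SPPCSPCConfig", "FMSRConfig", "SPPCSPC", "ResidualBlock",
           "ResidualBody", "UpsampleX4", "FMSR"]


@dataclass
class SPPCSPCConfig:
    pool_sizes: tuple = (1, 5, 9, 13)
    hidden_channels: int = 0  # 0 -> half the input channels

    def validate(self):
        if any(k % 2 == 0 for k in self.pool_sizes):
            raise ValueError("pool kernels must be odd (same-size stride-1 pooling)")


@dataclass
class FMSRConfig:
    n_res_blocks: int = 5
    upscale: int = 4
    out_channels: int = 64
    body_channels: int = 0  # 0 -> hidden width of the SPPCSPC front-end
    spp: SPPCSPCConfig = field(default_factory=SPPCSPCConfig)

    def validate(self):
        if self.upscale != 4:
            raise ValueError("the reconstruction factor is fixed at 4 (two x2 stages)")
        if self.n_res_blocks < 1:
            raise ValueError("need at least one residual block")


class SPPCSPC(nn.Module):
    """Spatial-pyramid-pooling block with a cross-stage-partial bypass."""

    def __init__(self, in_ch: int, out_ch: int, cfg: SPPCSPCConfig | None = None):
        super().__init__()
        self.cfg = cfg or SPPCSPCConfig()
        self.cfg.validate()
        c_ = self.cfg.hidden_channels or max(in_ch // 2, 8)
        self.pool_sizes = tuple(self.cfg.pool_sizes)
        # CSP bypass branch: plain conv stack
        self.cv_bypass = nn.ConvBNSiLU(in_ch, c_, 1)
        # SPP branch
        self.cv1 = nn.ConvBNSiLU(in_ch, c_, 1)
        self.cv3 = nn.ConvBNSiLU(c_, c_, 3)
        self.cv_pool = nn.ConvBNSiLU(c_ * len(self.pool_sizes), c_, 1)
        self.cv4 = nn.ConvBNSiLU(c_, c_, 3)
        self.cv_out = nn.ConvBNSiLU(2 * c_, out_ch, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv3(self.cv1(x))
        pools = [F.max_pool2d(y, k) for k in self.pool_sizes]
        y = self.cv4(self.cv_pool(nn.concat(pools, axis=1)))
        return self.cv_out(nn.concat([y, self.cv_bypass(x)], axis=1))


class ResidualBlock(nn.Module):
    """conv-BN-PReLU-conv-BN plus identity (SRResNet unit)."""

    def __init__(self, ch: int):
        super().__init__()
        self.conv1 = nn.Conv2d(ch, ch, 3, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(ch)
        self.act = nn.PReLU()
        self.conv2 = nn.Conv2d(ch, ch, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.act(self.bn1(self.conv1(x)))))
        return x + y


class ResidualBody(nn.Module):
    def __init__(self, ch: int, n_blocks: int):
        super().__init__()
        self.blocks = nn.ModuleList([ResidualBlock(ch) for _ in range(n_blocks)])

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class _SubPixelStage(nn.Module):
    """conv to 4x channels -> depth-to-space x2 -> PReLU."""

    def __init__(self, ch: int):
        super().__init__()
        self.conv = nn.Conv2d(ch, ch * 4, 3, padding=1)
        self.act = nn.PReLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(F.pixel_shuffle(self.conv(x), 2))


class UpsampleX4(nn.Module):
    def __init__(self, ch: int):
        super().__init__()
        self.s1 = _SubPixelStage(ch)
        self.s2 = _SubPixelStage(ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.s2(self.s1(x))


class FMSR(nn.Module):
    """Full FM-SR module: SPPCSPC -> residual body + skip -> x4 sub-pixel."""

    def __init__(self, in_ch: int, cfg: FMSRConfig | None = None):
        super().__init__()
        self.cfg = cfg or FMSRConfig()
        self.cfg.validate()
        body_ch = self.cfg.body_channels or max(in_ch // 2, 8)
        self.front = SPPCSPC(in_ch, body_ch, self.cfg.spp)
        self.body = ResidualBody(body_ch, self.cfg.n_res_blocks)
        self.body_tail = nn.Conv2d(body_ch, body_ch, 3, padding=1, bias=False)
        self.body_tail_bn = nn.BatchNorm2d(body_ch)
        self.up = UpsampleX4(body_ch)
        self.project = nn.Conv2d(body_ch, self.cfg.out_channels, 1)

    def forward(self, p5: Tensor) -> Tensor:
        feat = self.front(p5)
        # SRResNet layout: trailing conv-BN after the block stack, then the
        # long skip adds the body input back before upsampling, so a zeroed
        # body leaves the front-end features to pass through unchanged.
        delta = self.body_tail_bn(self.body_tail(self.body(feat)))
        return self.project(self.up(feat + delta))
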