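"""Cross-stage interactive feature fusion (CSIF).

Replaces identity/concatenation skip connections with a top-down cascade
over the four encoder features E1..E4 (scales 1/4..1/32, channels C..8C):

    D4 = MPM(proj(down2(E3)) + E4)
    D3 = MIA(proj(down2(E2)), E3, proj(up2(D4)))
    D2 = MIA(proj(down2(E1)), proj(up2(D3)), E2)
    D1 = MIA(proj(up2(D2)), E1)

All cross-scale alignments are bilinear/area resizes followed by pointwise
channel projections.  MPM (mixed pooling) adds a lightweight pyramid-pooling
path (bins 1/2/4) and a horizontal/vertical strip-pooling path to the
input, connecting distant regions along rows and columns.  MIA sums its
parts and gates them with three collaborative attention branches — over
channel, height and width — each built from average+std squeezing, a
kernel-3 1-D convolution along its axis and a sigmoid, averaged and passed
through conv + batch-norm + ReLU.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import (BatchNorm2d, Conv2d, Linear, Module, Parameter,
                       Tensor, avg_pool2d, conv1d_k3, resize_bilinear)

__all__ = ["MPM", "MIA", "CSIF"]


class MPM(Module):
    """Mixed pooling module: input + pyramid-pooling path + strip path."""

    def __init__(self, c: int, rng: np.random.Generator, bins=(1, 2, 4)):
        super().__init__()
        self.bins = tuple(bins)
        self.bin_proj = ad.ModuleList([Linear(c, c, rng) for _ in self.bins])
        self.conv_short = Conv2d(c, c, 3, rng)
        self.strip_h_kernel = Parameter(np.array([0.25, 0.5, 0.25], dtype=ad.DTYPE))
        self.strip_w_kernel = Parameter(np.array([0.25, 0.5, 0.25], dtype=ad.DTYPE))
        self.strip_h_proj = Linear(c, c, rng)
        self.strip_w_proj = Linear(c, c, rng)
        self.conv_long = Conv2d(c, c, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        pyr = None
        for k, proj in zip(self.bins, self.bin_proj):
            p = resize_bilinear(x, min(k, h), min(k, w))
            p = resize_bilinear(proj(p), h, w)
            pyr = p if pyr is None else pyr + p
        short = self.conv_short(pyr.relu())
        # horizontal strip: pool across the width, keep rows
        sh = x.mean(axis=2, keepdims=True)                      # (B,H,1,C)
        sh = self.strip_h_proj(conv1d_k3(sh, self.strip_h_kernel, axis=1))
        sv = x.mean(axis=1, keepdims=True)                      # (B,1,W,C)
        sv = self.strip_w_proj(conv1d_k3(sv, self.strip_w_kernel, axis=2))
        long = self.conv_long((sh + sv).relu())                 # broadcast H×W
        return x + short + long


class _AxisGate(Module):
    """One collaborative-attention branch: squeeze the two complementary
    axes by average and standard deviation, mix with learnable weights,
    run a kernel-3 1-D conv along the kept axis, sigmoid-gate."""

    def __init__(self, axis: int):
        super().__init__()
        self.axis = axis                        # 1=H, 2=W, 3=C (NHWC)
        self.kernel = Parameter(np.array([0.0, 1.0, 0.0], dtype=ad.DTYPE))
        self.mix = Parameter(np.array([0.5, 0.5], dtype=ad.DTYPE))
        self.bias = Parameter(np.zeros(1, dtype=ad.DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(a for a in (1, 2, 3) if a != self.axis)
        mu = x.mean(axis=axes, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
        z = self.mix[0] * mu + self.mix[1] * (var + 1e-8).sqrt()
        gate = (conv1d_k3(z, self.kernel, axis=self.axis) + self.bias).sigmoid()
        return x * gate


class MIA(Module):
    """Multidimensional interaction aggregation: sum the (shape-aligned)
    parts, gate along H, W and channel axes, average the three, then
    conv + BN + ReLU."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.gate_h = _AxisGate(1)
        self.gate_w = _AxisGate(2)
        self.gate_c = _AxisGate(3)
        self.conv = Conv2d(c, c, 3, rng)
        self.bn = BatchNorm2d(c)

    def forward(self, parts: list[Tensor]) -> Tensor:
        shape = parts[0].shape
        for p in parts[1:]:
            if p.shape != shape:
                raise ValueError(f"part shapes differ: {p.shape} vs {shape}")
        x = parts[0]
        for p in parts[1:]:
            x = x + p
        g = (self.gate_h(x) + self.gate_w(x) + self.gate_c(x)) * (1.0 / 3.0)
        return self.bn(self.conv(g)).relu()


class CSIF(Module):
    """Top-down fused pyramid over the four encoder levels.

    ``c`` is the stage-1 channel count C; levels carry C, 2C, 4C, 8C."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.proj_e3_down = Linear(4 * c, 8 * c, rng)
        self.mpm = MPM(8 * c, rng)
        self.proj_e2_down = Linear(2 * c, 4 * c, rng)
        self.proj_d4_up = Linear(8 * c, 4 * c, rng)
        self.mia3 = MIA(4 * c, rng)
        self.proj_e1_down = Linear(c, 2 * c, rng)
        self.proj_d3_up = Linear(4 * c, 2 * c, rng)
        self.mia2 = MIA(2 * c, rng)
        self.proj_d2_up = Linear(2 * c, c, rng)
        self.mia1 = MIA(c, rng)

    @staticmethod
    def _up2(x: Tensor) -> Tensor:
        b, h, w, _ = x.shape
        return resize_bilinear(x, 2 * h, 2 * w)

    def forward(self, e1: Tensor, e2: Tensor, e3: Tensor, e4: Tensor):
        for i, (a, b) in enumerate(zip((e1, e2, e3), (e2, e3, e4))):
            if (a.shape[1] != 2 * b.shape[1] or a.shape[2] != 2 * b.shape[2]
                    or 2 * a.shape[3] != b.shape[3]):
                raise ValueError(
                    f"encoder pyramid malformed between levels {i + 1} and {i + 2}: "
                    f"{a.shape} vs {b.shape}")
        d4 = self.mpm(self.proj_e3_down(avg_pool2d(e3, 2)) + e4)
        d3 = self.mia3([self.proj_e2_down(avg_pool2d(e2, 2)), e3,
                        self.proj_d4_up(self._up2(d4))])
        d2 = self.mia2([self.proj_e1_down(avg_pool2d(e1, 2)),
                        self.proj_d3_up(self._up2(d3)), e2])
        d1 = self.mia1([self.proj_d2_up(self._up2(d2)), e1])
        return d1, d2, d3, d4
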