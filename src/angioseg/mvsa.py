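"""Multiscale vessel structure-aware (MVSA) fusion block.

Injects a classical-geometry prior into the learned feature stream: Frangi
vesselness maps are computed from the raw frame at three spatial scales
(1×, 0.5×, 0.25×), fused into a single quarter-scale map

    V4 = down2(V1 + V2) + V3,

and combined with the embedded features X′ through channel attention:

    V_mvsa = ReLU(LN(Conv(CAM([V4, X′])))).

The vessel pyramid is weight-free (it depends only on the frame, not on any
parameter) and is therefore computed once per frame and cached by the
caller; only the Conv/LN/CAM parameters train.  Vessel maps stay
single-channel; the final convolution maps (C+1) → C after concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Conv2d, LayerNorm, Linear, Module, Tensor
from .vesselness import default_sigmas, multiscale_vesselness

__all__ = ["VesselPyramid", "ChannelAttention", "downsample2",
           "compute_frangi_pyramid", "MVSABlock"]


def downsample2(x):
    """2× area (anti-aliased bilinear) reduction; numpy array or Tensor."""
    if isinstance(x, Tensor):
        return ad.avg_pool2d(x, 2)
    x = np.asarray(x)
    h, w = x.shape[-2:]
    if h % 2 or w % 2:
        raise ValueError(f"odd spatial dims {x.shape[-2:]}")
    return 0.25 * (x[..., 0::2, 0::2] + x[..., 0::2, 1::2]
                   + x[..., 1::2, 0::2] + x[..., 1::2, 1::2])


@dataclass
class VesselPyramid:
    """Raw single-channel vesselness maps: ``v1`` (downsampled full-scale
    response) and ``f_half`` / ``f_quarter`` (responses of the half- and
    quarter-scale images); all numpy, batch-first."""
    v1: np.ndarray        # (B, H/2, W/2)
    f_half: np.ndarray    # (B, H/2, W/2)
    f_quarter: np.ndarray  # (B, H/4, W/4)


def compute_frangi_pyramid(images: np.ndarray, sigmas=None, beta: float = 0.5,
                           c: float = 15.0) -> VesselPyramid:
    """Three-scale Frangi maps for a batch of frames (B, H, W).

    The same σ schedule is used at every pyramid level; the pyramid itself
    provides the scale diversity."""
    if sigmas is None:
        sigmas = default_sigmas()
    v1, fh, fq = [], [], []
    for img in images:
        full = multiscale_vesselness(img, sigmas=sigmas, beta=beta, c=c).response
        v1.append(downsample2(full))
        xh = downsample2(img)
        fh.append(multiscale_vesselness(xh, sigmas=sigmas, beta=beta, c=c).response)
        xq = downsample2(xh)
        fq.append(multiscale_vesselness(xq, sigmas=sigmas, beta=beta, c=c).response)
    return VesselPyramid(v1=np.stack(v1), f_half=np.stack(fh),
                         f_quarter=np.stack(fq))


class ChannelAttention(Module):
    """Squeeze-and-excitation channel gating: global average pool →
    bottleneck MLP (reduction 4) → sigmoid gates in (0, 1)."""

    def __init__(self, c: int, rng: np.random.Generator, reduction: int = 4):
        super().__init__()
        hidden = max(c // reduction, 1)
        self.fc1 = Linear(c, hidden, rng)
        self.fc2 = Linear(hidden, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(1, 2), keepdims=True)           # (B,1,1,C)
        gate = self.fc2(self.fc1(s).relu()).sigmoid()
        return x * gate


class MapNorm(Module):
    """Per-sample normalisation over all non-batch axes with a learnable
    affine pair.  Channel-wise layer normalisation is degenerate on the
    single-channel vessel maps (it returns a constant), so those maps are
    normalised over their full spatial extent instead."""

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.weight = ad.Parameter(np.ones(1, dtype=ad.DTYPE))
        self.bias = ad.Parameter(np.zeros(1, dtype=ad.DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.weight + self.bias


class MVSABlock(Module):
    """Fuse the cached vessel pyramid with embedded features at 1/4 scale."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        # no conv bias: the following map normalisation is invariant to it
        self.conv_v2 = Conv2d(1, 1, 3, rng, bias=False)
        self.ln_v2 = MapNorm()
        self.conv_v3 = Conv2d(1, 1, 3, rng, bias=False)
        self.ln_v3 = MapNorm()
        self.cam = ChannelAttention(c + 1, rng)
        self.conv_out = Conv2d(c + 1, c, 3, rng)
        self.ln_out = LayerNorm(c)

    def forward(self, pyramid: VesselPyramid, embedded: Tensor) -> Tensor:
        b, h, w, c = embedded.shape
        if pyramid.f_quarter.shape[1:] != (h, w):
            raise ValueError(
                f"pyramid quarter scale {pyramid.f_quarter.shape[1:]} does not "
                f"match embedded features {(h, w)}")
        dt = embedded.dtype
        v1 = Tensor(pyramid.v1[..., None].astype(dt))
        v2 = self.ln_v2(self.conv_v2(Tensor(pyramid.f_half[..., None].astype(dt)))).relu()
        v3 = self.ln_v3(self.conv_v3(Tensor(pyramid.f_quarter[..., None].astype(dt)))).relu()
        v4 = downsample2(v1 + v2) + v3
        fused = self.cam(ad.concat([v4, embedded], axis=-1))
        return self.ln_out(self.conv_out(fused)).relu()

    @staticmethod
    def raw_fused_map(pyramid: VesselPyramid) -> np.ndarray:
        """Weight-free fusion of the pyramid (no Conv/LN transforms):
        down2(V1 + F_half) + F_quarter, at quarter scale."""
        return downsample2(pyramid.v1 + pyramid.f_half) + pyramid.f_quarter
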