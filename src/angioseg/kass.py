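"""Kolmogorov–Arnold state-space (KASS) block.

A two-branch visual-state-space unit followed by a Kolmogorov–Arnold
feed-forward layer:

    F1 = CAM(LN(SS2D(SiLU(DWConv(Linear(LN(x)))))))          # global branch
    F2 = LocalAttention(SiLU(Linear(LN(x))))                 # gating branch
    F3 = x + Linear(F1 ⊙ F2)
    F_kass = FasterKAN(LN(F3)) + F3

SS2D is the four-direction 2-D selective scan of visual state-space models:
the feature map is unfolded into row-major, reversed row-major,
column-major and reversed column-major sequences, an input-dependent linear
state-space recurrence runs along each, and the four outputs are folded
back and summed.  The feed-forward replaces an MLP with a FasterKAN layer:
each (normalised) scalar feature is expanded through reflectional-switch
basis functions φ(h) = 1 − tanh²((h−g)/p) on a fixed grid and linearly
recombined.

A config switch ``branch1_tail`` selects between the channel-attention tail
(``cam_ln``, the default) and a plain linear tail (``linear``); switches
``use_ffn`` / ``use_local_attention`` reduce the block to a vanilla
visual-state-space block for ablation arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import (DepthwiseConv2d, LayerNorm, Linear, Module, Parameter,
                       Tensor, concat, linear_scan)
from .mvsa import ChannelAttention

__all__ = ["RswafGrid", "rswaf_basis", "FasterKANLayer", "SS2D",
           "LocalAttention", "KassConfig", "KASSBlock"]


# ---------------------------------------------------------------------------
# RSWAF basis / FasterKAN
# ---------------------------------------------------------------------------

@dataclass
class RswafGrid:
    """Fixed grid of reflectional-switch basis centers."""
    grid_min: float = -2.0
    grid_max: float = 2.0
    grid_count: int = 8
    denominator: float = 0.33
    centers: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.denominator <= 0:
            raise ValueError("denominator must be > 0")
        if self.grid_count < 1 or self.grid_max <= self.grid_min:
            raise ValueError("invalid grid")
        self.centers = np.linspace(self.grid_min, self.grid_max, self.grid_count)


def rswaf_basis(h: np.ndarray, grid: RswafGrid) -> np.ndarray:
    """Basis activations φ_g(h) = 1 − tanh²((h − g)/p), shape (*h.shape, G).

    Each φ peaks at 1 on its center and decays to 0 as |h − g| grows."""
    h = np.asarray(h, dtype=float)
    u = (h[..., None] - grid.centers) / grid.denominator
    return 1.0 - np.tanh(u) ** 2


class FasterKANLayer(Module):
    """Kolmogorov–Arnold feed-forward: per-scalar RSWAF basis expansion
    followed by a linear combination back to the channel width.

    Input normalisation is expected from the caller (the block applies LN
    before the layer); the grid on [−2, 2] assumes roughly standardised
    inputs."""

    def __init__(self, c: int, rng: np.random.Generator,
                 grid: RswafGrid | None = None, zero_init: bool = False,
                 init_scale: float = 1.0):
        super().__init__()
        self.grid = grid or RswafGrid()
        g = self.grid.grid_count
        self.proj = Linear(c * g, c, rng, zero_init=zero_init,
                           init_scale=init_scale)
        self._centers = self.grid.centers.astype(ad.DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        *lead, c = x.shape
        u = (x.reshape(*lead, c, 1) - self._centers) * \
            (1.0 / self.grid.denominator)
        phi = 1.0 - u.tanh().pow(2.0)
        return self.proj(phi.reshape(*lead, c * self.grid.grid_count))


# ---------------------------------------------------------------------------
# 2-D selective scan
# ---------------------------------------------------------------------------

class SS2D(Module):
    """Four-direction selective scan over an NHWC feature map.

    Per direction k, with learned input-dependent parameters:

        Δ_t = softplus(W_dt · (W_x x_t) + b_dt)        (per channel)
        a_t = exp(−Δ_t · exp(A_log))                    state decay in (0,1)
        h_t = a_t ⊙ h_{t-1} + Δ_t B_t x_t               linear recurrence
        y_t = C_t · h_t + D ⊙ x_t

    The recurrence runs as a vectorised time loop (the sequential/associative
    scan contract; no hardware scan kernels)."""

    def __init__(self, d: int, rng: np.random.Generator, state_dim: int = 16,
                 dt_rank: int | None = None):
        super().__init__()
        if state_dim < 1:
            raise ValueError("state_dim must be >= 1")
        self.d = d
        self.n = state_dim
        self.dt_rank = dt_rank or max(d // 16, 1)
        self.x_proj = ad.ModuleList([
            Linear(d, self.dt_rank + 2 * state_dim, rng, bias=False)
            for _ in range(4)])
        self.dt_proj = ad.ModuleList([])
        self.a_log = []
        self.d_skip = []
        for k in range(4):
            dt = Linear(self.dt_rank, d, rng)
            # softplus(bias) ≈ Δ init in [1e-3, 1e-1]
            dt_init = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), d))
            dt.bias.data = np.log(np.expm1(dt_init)).astype(ad.DTYPE)
            self.dt_proj.append(dt)
            a = np.tile(np.arange(1, state_dim + 1, dtype=np.float64), (d, 1))
            self.a_log.append(Parameter(np.log(a).astype(ad.DTYPE)))
            self.d_skip.append(Parameter(np.ones(d, dtype=ad.DTYPE)))

    def _scan_inputs(self, seq: Tensor, k: int):
        """Projection of one directional sequence (B, L, D) into recurrence
        coefficients a, bx and readout C."""
        b, l, d = seq.shape
        proj = self.x_proj[k](seq)
        r, n = self.dt_rank, self.n
        dt = proj[:, :, :r]
        bmat = proj[:, :, r:r + n]
        cmat = proj[:, :, r + n:r + 2 * n]
        delta = self.dt_proj[k](dt).softplus()              # (B, L, D)
        a_neg = -self.a_log[k].exp()                        # (D, N)
        a = (delta.reshape(b, l, d, 1) * a_neg).exp()       # (B, L, D, N)
        bx = delta.reshape(b, l, d, 1) * bmat.reshape(b, l, 1, n) * \
            seq.reshape(b, l, d, 1)
        return a, bx, cmat

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        l = h * w
        seqs = [
            x.reshape(b, l, d),                                   # row-major
            x.reshape(b, l, d).flip(1),                           # reversed
            x.transpose(0, 2, 1, 3).reshape(b, l, d),             # col-major
            x.transpose(0, 2, 1, 3).reshape(b, l, d).flip(1),     # reversed
        ]
        a_all, bx_all, c_all = [], [], []
        for k, seq in enumerate(seqs):
            a, bx, cmat = self._scan_inputs(seq, k)
            a_all.append(a)
            bx_all.append(bx)
            c_all.append(cmat)
        # one fused recurrence over the stacked directions
        hid = linear_scan(concat(a_all, axis=0), concat(bx_all, axis=0))
        outs = []
        for k, seq in enumerate(seqs):
            hk = hid[k * b:(k + 1) * b]
            y = (hk * c_all[k].reshape(b, l, 1, self.n)).sum(axis=-1)
            outs.append(y + seq * self.d_skip[k])
        y = outs[0] + outs[1].flip(1)
        yt = outs[2] + outs[3].flip(1)
        return y.reshape(b, h, w, d) + \
            yt.reshape(b, w, h, d).transpose(0, 2, 1, 3)

    def scan_reference(self, x: np.ndarray) -> np.ndarray:
        """Naive per-element sequential-loop oracle of the same recurrence
        (scalar python loops; used to validate the vectorised scan)."""
        with ad.no_grad():
            xt = Tensor(x)
            b, h, w, d = xt.shape
            l = h * w
            seqs = [
                xt.reshape(b, l, d),
                xt.reshape(b, l, d).flip(1),
                xt.transpose(0, 2, 1, 3).reshape(b, l, d),
                xt.transpose(0, 2, 1, 3).reshape(b, l, d).flip(1),
            ]
            outs = []
            for k, seq in enumerate(seqs):
                a, bx, cmat = self._scan_inputs(seq, k)
                a, bx, cmat = a.data, bx.data, cmat.data
                y = np.zeros((b, l, d))
                for bi in range(b):
                    for di in range(d):
                        hstate = np.zeros(self.n)
                        for t in range(l):
                            for ni in range(self.n):
                                hstate[ni] = a[bi, t, di, ni] * hstate[ni] \
                                    + bx[bi, t, di, ni]
                            y[bi, t, di] = float(cmat[bi, t] @ hstate) \
                                + self.d_skip[k].data[di] * seq.data[bi, t, di]
                outs.append(y)
            y = outs[0] + outs[1][:, ::-1]
            yt = outs[2] + outs[3][:, ::-1]
            return y.reshape(b, h, w, d) + \
                yt.reshape(b, w, h, d).transpose(0, 2, 1, 3)


class LocalAttention(Module):
    """Spatial gating from a small neighbourhood: 3×3 depthwise conv →
    pointwise conv → sigmoid gate in (0, 1), multiplied onto the branch."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.dw = DepthwiseConv2d(c, 3, rng)
        self.pw = Linear(c, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.pw(self.dw(x)).sigmoid()


# ---------------------------------------------------------------------------
# the block
# ---------------------------------------------------------------------------

@dataclass
class KassConfig:
    state_dim: int = 16
    expand: int = 2
    conv_kernel: int = 3
    grid_min: float = -2.0
    grid_max: float = 2.0
    grid_count: int = 8
    denominator: float = 0.33
    branch1_tail: str = "cam_ln"        # "cam_ln" | "linear"
    use_ffn: bool = True                # FasterKAN feed-forward
    use_local_attention: bool = True    # gating on branch 2

    def grid(self) -> RswafGrid:
        return RswafGrid(self.grid_min, self.grid_max, self.grid_count,
                         self.denominator)


class KASSBlock(Module):
    """Shape-preserving KASS block; optionally owns the stage-closing
    2× downsample / channel-expand tail (patch merging)."""

    def __init__(self, c: int, rng: np.random.Generator,
                 cfg: KassConfig | None = None, downsample: bool = False):
        super().__init__()
        cfg = cfg or KassConfig()
        if cfg.branch1_tail not in ("cam_ln", "linear"):
            raise ValueError(f"unknown branch1_tail {cfg.branch1_tail!r}")
        self.cfg = cfg
        d = cfg.expand * c
        self.ln_in = LayerNorm(c)
        self.in_proj1 = Linear(c, d, rng)
        self.dwconv = DepthwiseConv2d(d, cfg.conv_kernel, rng)
        self.ss2d = SS2D(d, rng, state_dim=cfg.state_dim)
        if cfg.branch1_tail == "cam_ln":
            self.ln_b1 = LayerNorm(d)
            self.cam = ChannelAttention(d, rng)
        else:
            self.tail_linear = Linear(d, d, rng)
        self.in_proj2 = Linear(c, d, rng)
        if cfg.use_local_attention:
            self.local_attn = LocalAttention(d, rng)
        # residual-branch outputs start small so a fresh stack is
        # near-identity and trains stably from scratch
        self.out_proj = Linear(d, c, rng, init_scale=0.1)
        if cfg.use_ffn:
            self.ln_ffn = LayerNorm(c)
            self.ffn = FasterKANLayer(c, rng, cfg.grid(), init_scale=0.1)
        if downsample:
            from .network import PatchMerge   # deferred: network imports us
            self.merge = PatchMerge(c, rng)
        else:
            self.merge = None

    def zero_output_init(self) -> None:
        """Zero the output projections so the block is a pure residual
        identity (used to verify the residual paths)."""
        self.out_proj.weight.data[...] = 0.0
        self.out_proj.bias.data[...] = 0.0
        if self.cfg.use_ffn:
            self.ffn.proj.weight.data[...] = 0.0
            self.ffn.proj.bias.data[...] = 0.0

    def forward(self, x: Tensor, close_stage: bool = False):
        xn = self.ln_in(x)
        b1 = self.ss2d(self.dwconv(self.in_proj1(xn)).silu())
        if self.cfg.branch1_tail == "cam_ln":
            b1 = self.cam(self.ln_b1(b1))
        else:
            b1 = self.tail_linear(b1)
        b2 = self.in_proj2(xn).silu()
        if self.cfg.use_local_attention:
            b2 = self.local_attn(b2)
        f3 = x + self.out_proj(b1 * b2)
        if self.cfg.use_ffn:
            f_kass = self.ffn(self.ln_ffn(f3)) + f3
        else:
            f_kass = f3
        if close_stage:
            if self.merge is None:
                raise ValueError("block was built without a downsample tail")
            return f_kass, self.merge(f_kass)
        return f_kass
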