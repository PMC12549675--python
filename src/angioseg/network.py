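"""U-shaped vessel-structure-aware state-space segmentation network.

Assembly, for a grayscale frame with sides divisible by 32:

* progressive patch embedding (two stride-2 convs) to 1/4 scale, C channels;
* four encoder stages — stage 1 uses VSASS blocks (a vesselness-prior MVSA
  module feeding a KASS block), stages 2–4 plain KASS blocks — with patch
  merging between stages, giving the pyramid E1..E4 at channels C..8C;
* a cross-stage fusion module (CSIF) producing D1..D4 from E1..E4
  (identity skips when disabled);
* a mirrored decoder with patch expanding and [2,2,2,1] KASS blocks
  (deepest to shallowest), each stage receiving its D level by elementwise
  addition, then a 4× patch expansion and a 1×1 convolution to a sigmoid
  foreground probability;
* a combined binary-cross-entropy + soft-Dice training loss, optimised with
  AdamW under cosine learning-rate annealing.

Everything is seeded: weight initialisation, data order and augmentation
derive from one integer, and evaluation-mode forward passes are
deterministic bit-for-bit.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from . import metrics as seg_metrics
from .autodiff import (AdamW, Conv2d, CosineAnnealingLR, LayerNorm, Linear,
                       Module, Tensor)
from .csif import CSIF
from .kass import KASSBlock, KassConfig
from .mvsa import MVSABlock, compute_frangi_pyramid, downsample2
from .vesselness import default_sigmas

__all__ = [
    "NetworkConfig", "TrainConfig", "SegmentationResult", "PatchEmbed",
    "PatchMerge", "PatchExpand", "VesselSegNet", "combined_loss",
    "train_model", "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    embed_dim: int = 96
    encoder_depths: tuple = (2, 2, 2, 2)
    decoder_depths: tuple = (2, 2, 2, 1)      # deepest (8C) → shallowest (C)
    mvsa_stages: tuple = (1,)                 # stages carrying the MVSA prior
    mvsa_enabled: bool = True
    kass_enabled: bool = True                 # False → vanilla VSS blocks
    csif_enabled: bool = True
    num_classes: int = 1
    # state-space / KAN settings
    state_dim: int = 16
    expand: int = 2
    grid_count: int = 8
    grid_min: float = -2.0
    grid_max: float = 2.0
    denominator: float = 0.33
    branch1_tail: str = "cam_ln"
    # Frangi prior settings
    sigma_min: float = 0.5
    sigma_max: float = 5.0
    n_scales: int = 5
    frangi_beta: float = 0.5
    frangi_c: float = 15.0

    def validate(self) -> None:
        if self.embed_dim % 4:
            raise ValueError("embed_dim must be divisible by 4")
        if len(self.encoder_depths) != 4 or len(self.decoder_depths) != 4:
            raise ValueError("depth lists must have four stages")
        if any(d < 1 for d in self.encoder_depths + self.decoder_depths):
            raise ValueError("depths must be positive")
        if not set(self.mvsa_stages) <= {1, 2, 3, 4}:
            raise ValueError("mvsa_stages must be within {1,2,3,4}")

    def kass_config(self) -> KassConfig:
        return KassConfig(
            state_dim=self.state_dim, expand=self.expand,
            grid_count=self.grid_count, grid_min=self.grid_min,
            grid_max=self.grid_max, denominator=self.denominator,
            branch1_tail=self.branch1_tail,
            use_ffn=self.kass_enabled,
            use_local_attention=self.kass_enabled)

    def sigmas(self):
        return default_sigmas(self.sigma_min, self.sigma_max, self.n_scales)


@dataclass
class SegmentationResult:
    prob: np.ndarray      # (H, W) or (B, H, W) in [0, 1]
    mask: np.ndarray      # same shape, {0, 1}, threshold 0.5


# ---------------------------------------------------------------------------
# patch resampling layers
# ---------------------------------------------------------------------------

class PatchEmbed(Module):
    """Progressive embedding: two stride-2 3×3 convolutions
    (1 → C/2 → C), each normalised and activated, then a final LN."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(1, c // 2, 3, rng, stride=2, padding=1)
        self.ln1 = LayerNorm(c // 2)
        self.conv2 = Conv2d(c // 2, c, 3, rng, stride=2, padding=1)
        self.ln2 = LayerNorm(c)
        self.ln_out = LayerNorm(c)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise ValueError(f"spatial dims {x.shape[1:3]} not divisible by 4")
        x = self.ln1(self.conv1(x)).gelu()
        x = self.ln2(self.conv2(x)).gelu()
        return self.ln_out(x)


class PatchMerge(Module):
    """2×2 neighbourhood concatenation (4C) → linear to 2C → LN."""

    def __init__(self, c: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = Linear(4 * c, 2 * c, rng, bias=False)
        self.norm = LayerNorm(2 * c)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"odd spatial dims {(h, w)}")
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.norm(self.reduce(x))


class PatchExpand(Module):
    """Linear channel expansion + pixel rearrangement: ×2 doubles the
    spatial dims and halves the channels; ×4 (final projection variant)
    quadruples the dims and maps C → C/4."""

    def __init__(self, c: int, rng: np.random.Generator, factor: int = 2):
        super().__init__()
        if c % factor:
            raise ValueError(f"channels {c} not divisible by factor {factor}")
        self.factor = factor
        self.c_out = c // factor
        self.expand = Linear(c, factor * factor * self.c_out, rng, bias=False)
        self.norm = LayerNorm(self.c_out)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, _ = x.shape
        r, co = self.factor, self.c_out
        x = self.expand(x).reshape(b, h, w, r, r, co)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h * r, w * r, co)
        return self.norm(x)


class VSASSBlock(KASSBlock):
    """Vessel structure-aware state-space block: MVSA prior + KASS.

    Subclasses the KASS block so that, relative to a plain block, enabling
    the prior adds exactly the ``mvsa.*`` parameters and nothing else."""

    def __init__(self, c: int, rng: np.random.Generator, cfg: KassConfig):
        super().__init__(c, rng, cfg)
        self.mvsa = MVSABlock(c, rng)

    def forward(self, pyramid, x: Tensor) -> Tensor:   # type: ignore[override]
        return super().forward(self.mvsa(pyramid, x))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class VesselSegNet(Module):
    """Full segmentation network (see module docstring)."""

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = cfg or NetworkConfig()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.embed_dim
        kcfg = cfg.kass_config()
        self.patch_embed = PatchEmbed(c, rng)

        mvsa_stages = set(cfg.mvsa_stages) if cfg.mvsa_enabled else set()
        self._mvsa_stages = mvsa_stages
        self.enc_stages = []
        self.merges = []
        for s in range(1, 5):
            cs = c * 2 ** (s - 1)
            blocks = []
            for _ in range(cfg.encoder_depths[s - 1]):
                if s in mvsa_stages:
                    blocks.append(VSASSBlock(cs, rng, kcfg))
                else:
                    blocks.append(KASSBlock(cs, rng, kcfg))
            self.enc_stages.append(ad.ModuleList(blocks))
            if s < 4:
                self.merges.append(PatchMerge(cs, rng))
        self.enc_stages = ad.ModuleList(self.enc_stages)
        self.merges = ad.ModuleList(self.merges)

        self.csif = CSIF(c, rng) if cfg.csif_enabled else None

        self.dec_stages = []
        self.expands = []
        for i, s in enumerate((4, 3, 2, 1)):       # deepest → shallowest
            cs = c * 2 ** (s - 1)
            self.dec_stages.append(ad.ModuleList(
                [KASSBlock(cs, rng, kcfg) for _ in range(cfg.decoder_depths[i])]))
            if s > 1:
                self.expands.append(PatchExpand(cs, rng, factor=2))
        self.dec_stages = ad.ModuleList(self.dec_stages)
        self.expands = ad.ModuleList(self.expands)

        self.final_expand = PatchExpand(c, rng, factor=4)
        self.head = Linear(c // 4, cfg.num_classes, rng)
        # vessels are a rare foreground class: start the sigmoid near the
        # low prior rather than at 0.5
        self.head.bias.data[...] = -2.0

    # -- plumbing ----------------------------------------------------------
    @staticmethod
    def _normalise(images: np.ndarray) -> np.ndarray:
        return ((images.astype(np.float64) / 255.0) - 0.5) * 2.0

    def _pyramids(self, images: np.ndarray) -> dict:
        """Weight-free Frangi pyramids for every MVSA-carrying stage, keyed
        by stage; stage s sees the frame area-downsampled by 2^(s-1)."""
        out = {}
        cfg = self.cfg
        for s in sorted(self._mvsa_stages):
            img = images.astype(np.float64)
            for _ in range(s - 1):
                img = downsample2(img)
            out[s] = compute_frangi_pyramid(
                img, sigmas=cfg.sigmas(), beta=cfg.frangi_beta, c=cfg.frangi_c)
        return out

    # -- forward -----------------------------------------------------------
    def forward_probs(self, images: np.ndarray) -> Tensor:
        """Probability map tensor (B, H, W, 1) for a batch of frames given
        as (B, H, W) arrays on the [0, 255] intensity scale."""
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        b, h, w = images.shape
        if h % 32 or w % 32:
            raise ValueError(f"spatial dims {(h, w)} must be divisible by 32")
        pyramids = self._pyramids(images)
        x = Tensor(self._normalise(images)[..., None].astype(ad.DTYPE))
        x = self.patch_embed(x)

        enc = []
        for s in range(1, 5):
            for block in self.enc_stages[s - 1]:
                if isinstance(block, VSASSBlock):
                    x = block(pyramids[s], x)
                else:
                    x = block(x)
            enc.append(x)
            if s < 4:
                x = self.merges[s - 1](x)
        e1, e2, e3, e4 = enc

        if self.csif is not None:
            d1, d2, d3, d4 = self.csif(e1, e2, e3, e4)
        else:
            d1, d2, d3, d4 = e1, e2, e3, e4

        x = e4 + d4
        skips = (None, d3, d2, d1)
        for i in range(4):
            for block in self.dec_stages[i]:
                x = block(x)
            if i < 3:
                x = self.expands[i](x)
                x = x + skips[i + 1]
        x = self.final_expand(x)
        return self.head(x).sigmoid()

    def forward(self, images: np.ndarray, threshold: float = 0.5) -> SegmentationResult:
        """Evaluation-mode segmentation of one frame or a batch."""
        squeeze = np.asarray(images).ndim == 2
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                prob = self.forward_probs(images).data[..., 0]
        finally:
            self.train(was_training)
        if squeeze:
            prob = prob[0]
        return SegmentationResult(prob=prob.astype(np.float64),
                                  mask=(prob >= threshold).astype(np.uint8))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def combined_loss(prob: Tensor, target: np.ndarray, w1: float = 1.0,
                  w2: float = 1.0, eps: float = 1.0) -> Tensor:
    """w1 · BCE + w2 · (1 − soft Dice with smoothing eps).

    ``prob`` is the sigmoid output (B, H, W, 1); ``target`` a binary array
    broadcastable to it."""
    t = np.asarray(target, dtype=prob.dtype.type)
    if t.ndim == prob.ndim - 1:
        t = t[..., None]
    if t.shape != prob.shape:
        raise ValueError(f"target shape {t.shape} != prob shape {prob.shape}")
    p = prob.clamp(1e-7, 1.0 - 1e-7)
    tt = Tensor(t)
    bce = -(tt * p.log() + (1.0 - tt) * (1.0 - p).log()).mean()
    inter = (p * tt).sum()
    dice = 1.0 - (2.0 * inter + eps) / (p.sum() + tt.sum() + eps)
    return w1 * bce + w2 * dice


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, net: VesselSegNet, extra: dict | None = None) -> None:
    """Single-file weight archive with the network config embedded."""
    payload = {f"param/{k}": v for k, v in net.state_dict().items()}
    meta = {"config": asdict(net.cfg), "extra": extra or {}}
    np.savez(str(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **payload)


def load_checkpoint(path: str | Path) -> tuple[VesselSegNet, dict]:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cfg_d = meta["config"]
    for key in ("encoder_depths", "decoder_depths", "mvsa_stages"):
        cfg_d[key] = tuple(cfg_d[key])
    net = VesselSegNet(NetworkConfig(**cfg_d))
    net.load_state_dict(state)
    return net, meta.get("extra", {})


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 1000
    batch_size: int = 4
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    weight_decay: float = 1e-2
    t_max: int = 50
    lr_min: float = 1e-5
    w1: float = 1.0                 # BCE weight
    w2: float = 1.0                 # Dice weight
    augment: bool = True
    seed: int = 0
    patience: int = 100             # early stop on validation DSC
    out_dir: str = "runs/train"


def _augment(rng: np.random.Generator, img: np.ndarray, mask: np.ndarray):
    """Random 90°-multiple rotation, ±15° free rotation and flips, p=0.5."""
    k = int(rng.integers(0, 4))
    if k:
        img, mask = np.rot90(img, k), np.rot90(mask, k)
    if rng.uniform() < 0.5:
        ang = rng.uniform(-15.0, 15.0)
        img = ndimage.rotate(img, ang, reshape=False, order=1, mode="reflect")
        mask = ndimage.rotate(mask.astype(float), ang, reshape=False,
                              order=0, mode="constant") >= 0.5
    if rng.uniform() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.uniform() < 0.5:
        img, mask = img[::-1], mask[::-1]
    return np.ascontiguousarray(img), np.ascontiguousarray(mask.astype(np.uint8))


@dataclass
class TrainResult:
    checkpoint: Path
    log_path: Path
    history: list = field(default_factory=list)
    best_dsc: float = float("nan")


def _evaluate(net: VesselSegNet, data: list) -> dict:
    per_image = []
    for img, mask in data:
        res = net.forward(img)
        per_image.append(seg_metrics.evaluate_pair(res.mask, mask))
    return seg_metrics.aggregate(per_image)


def train_model(train_set: list, cfg: TrainConfig,
                val_set: list | None = None,
                net: VesselSegNet | None = None,
                net_cfg: NetworkConfig | None = None) -> TrainResult:
    """Seeded training loop: AdamW + cosine annealing, per-epoch validation
    metrics, best-DSC checkpointing, line-oriented text log."""
    if not train_set:
        raise ValueError("empty training dataset")
    val_set = val_set if val_set else train_set
    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = VesselSegNet(net_cfg or NetworkConfig(), seed=cfg.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ck_path = out / "best.npz"
    log_path = out / "train.log"
    opt = AdamW(net.parameters(), lr=cfg.lr, betas=(cfg.beta1, cfg.beta2),
                eps=cfg.adam_eps, weight_decay=cfg.weight_decay)
    sched = CosineAnnealingLR(opt, t_max=cfg.t_max, lr_min=cfg.lr_min)
    history = []
    best_dsc, best_epoch = -1.0, -1
    log = io.StringIO()
    n = len(train_set)
    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, masks = [], []
            for i in idx:
                img, mask = train_set[i]
                if cfg.augment:
                    img, mask = _augment(rng, img, mask)
                imgs.append(img)
                masks.append(mask)
            prob = net.forward_probs(np.stack(imgs).astype(np.float64))
            loss = combined_loss(prob, np.stack(masks), cfg.w1, cfg.w2)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        sched.step()
        net.eval()
        summary = _evaluate(net, val_set)
        rec = {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses)),
               **summary}
        history.append(rec)
        line = (f"epoch {epoch} lr {opt.lr:.8g} loss {rec['loss']:.6f} "
                f"dsc {rec['mdsc']:.6f} iou {rec['miou']:.6f} "
                f"sen {rec['msen']:.6f} hd95 {rec['mhd95']:.6f}")
        log.write(line + "\n")
        if rec["mdsc"] > best_dsc:
            best_dsc, best_epoch = rec["mdsc"], epoch
            save_checkpoint(ck_path, net, extra={"epoch": epoch,
                                                 "dsc": best_dsc})
        if epoch - best_epoch >= cfg.patience:
            log.write(f"early stop at epoch {epoch} (best {best_epoch})\n")
            break
    log_path.write_text(log.getvalue())
    if not ck_path.exists():
        save_checkpoint(ck_path, net, extra={"epoch": -1})
    return TrainResult(checkpoint=ck_path, log_path=log_path,
                       history=history, best_dsc=best_dsc)
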