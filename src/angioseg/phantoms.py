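"""Synthetic angiogram phantoms with exact ground truth.

Generates the kind of frame an X-ray coronary angiogram produces — a bright,
slowly varying, noisy background crossed by a dark branching vessel tree —
together with the binary vessel mask, so that every training and evaluation
path in the package can run without clinical data.  Four regimes emulate the
standard difficulty axes of angiographic segmentation:

``easy``
    well-filled tree, good contrast, mild noise.
``low_contrast``
    weak vessel-to-background intensity difference, higher noise (poor
    contrast filling, low-dose imaging).
``complex``
    deeper branching, projected crossings, catheter-like dark distractor.
``fuzzy``
    strong blur (motion / partial-volume boundary smearing).

Trees are random recursive bifurcating structures with quadratic-Bézier
centerlines, generation-wise radius decay, and swept-disk rasterisation with
anti-aliased edges (re-binarised at 0.5 for the mask).  Everything is a pure
function of the integer seed and the stated parameters, so a manifest row
regenerates its sample byte-for-byte.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "TreeParams", "VesselTree", "PhantomSample",
    "generate_tree", "render_angiogram", "make_sample", "make_dataset",
    "tube_phantom", "REGIMES",
]

BACKGROUND_LEVEL = 200.0


@dataclass
class TreeParams:
    depth: int = 4                 # max generations of bifurcation
    branch_prob: float = 0.85      # probability an edge bifurcates
    radius_decay: float = 0.7      # child radius / parent radius
    root_radius: float = 4.5       # trunk radius, px (at frame 256; scaled)
    n_roots: int = 1               # extra roots produce projected crossings

    def validate(self) -> None:
        if self.depth < 1 or not (0.0 < self.radius_decay < 1.0) \
                or not (0.0 <= self.branch_prob <= 1.0) \
                or self.root_radius <= 0 or self.n_roots < 1:
            raise ValueError("invalid tree parameters")


@dataclass
class Edge:
    p0: np.ndarray          # start point (x, y)
    pc: np.ndarray          # Bézier control point
    p1: np.ndarray          # end point
    r0: float               # radius at start, px
    r1: float               # radius at end, px
    generation: int


@dataclass
class VesselTree:
    frame_size: int
    edges: list[Edge] = field(default_factory=list)
    params: TreeParams = field(default_factory=TreeParams)


def _clip_point(p: np.ndarray, frame: int, margin: float = 3.0) -> np.ndarray:
    return np.clip(p, margin, frame - 1 - margin)


def _grow(rng: np.random.Generator, tree: VesselTree, pos: np.ndarray,
          direction: np.ndarray, gen: int, params: TreeParams) -> None:
    if gen >= params.depth:
        return
    frame = tree.frame_size
    scale = frame / 256.0
    length = frame * rng.uniform(0.16, 0.28) * (0.85 ** gen)
    ang = math.atan2(direction[1], direction[0]) + rng.uniform(-0.25, 0.25)
    d = np.array([math.cos(ang), math.sin(ang)])
    end = _clip_point(pos + d * length, frame)
    mid = 0.5 * (pos + end)
    perp = np.array([-d[1], d[0]])
    ctrl = _clip_point(mid + perp * length * rng.uniform(-0.25, 0.25), frame)
    r_parent = params.root_radius * scale * params.radius_decay ** gen
    r_child = r_parent * params.radius_decay
    tree.edges.append(Edge(p0=pos.copy(), pc=ctrl, p1=end,
                           r0=r_parent, r1=r_child, generation=gen))
    new_dir = end - pos
    nrm = np.linalg.norm(new_dir)
    new_dir = new_dir / nrm if nrm > 0 else d
    if gen + 1 >= params.depth:
        return
    if rng.uniform() < params.branch_prob:
        for sign in (1.0, -1.0):
            split = math.radians(rng.uniform(15.0, 40.0))
            rot = _rotate(new_dir, sign * split)
            _grow(rng, tree, end, rot, gen + 1, params)
    else:
        _grow(rng, tree, end, new_dir, gen + 1, params)


def _rotate(v: np.ndarray, a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_tree(seed: int, frame_size: int = 256,
                  params: TreeParams | None = None) -> VesselTree:
    """Random recursive vessel tree with smooth centerlines.

    Roots start on the frame border pointing inward; ``params.n_roots > 1``
    projects additional sub-trees onto the same plane, producing crossings.
    """
    if frame_size < 64:
        raise ValueError("frame_size must be >= 64")
    params = params or TreeParams()
    params.validate()
    rng = np.random.default_rng(seed)
    tree = VesselTree(frame_size=frame_size, params=params)
    for _ in range(params.n_roots):
        side = rng.integers(0, 4)
        t = rng.uniform(0.2, 0.8) * (frame_size - 1)
        if side == 0:
            pos, d = np.array([t, 3.0]), np.array([0.0, 1.0])
        elif side == 1:
            pos, d = np.array([t, frame_size - 4.0]), np.array([0.0, -1.0])
        elif side == 2:
            pos, d = np.array([3.0, t]), np.array([1.0, 0.0])
        else:
            pos, d = np.array([frame_size - 4.0, t]), np.array([-1.0, 0.0])
        ang = rng.uniform(-0.5, 0.5)
        _grow(rng, tree, pos, _rotate(d, ang), 0, params)
    return tree


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _bezier_points(e: Edge) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled centerline points and per-point radii of one edge."""
    chord = np.linalg.norm(e.p1 - e.p0) + np.linalg.norm(e.pc - 0.5 * (e.p0 + e.p1))
    n = max(int(chord * 2), 8)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * e.p0 + 2 * (1 - t) * t * e.pc + t ** 2 * e.p1
    radii = e.r0 + (e.r1 - e.r0) * t[:, 0]
    return pts, radii


def _sweep_disks(canvas: np.ndarray, pts: np.ndarray, radii: np.ndarray) -> None:
    """Max-combine anti-aliased disk coverage into ``canvas`` in place."""
    h, w = canvas.shape
    for (x, y), r in zip(pts, radii):
        e = int(math.ceil(r + 1.0))
        x0, x1 = max(int(x) - e, 0), min(int(x) + e + 1, w)
        y0, y1 = max(int(y) - e, 0), min(int(y) + e + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
        cov = np.clip(r + 0.5 - d, 0.0, 1.0)
        np.maximum(canvas[y0:y1, x0:x1], cov, out=canvas[y0:y1, x0:x1])


def rasterize_tree(tree: VesselTree) -> np.ndarray:
    """Anti-aliased swept-disk coverage map of the tree in [0, 1]."""
    canvas = np.zeros((tree.frame_size, tree.frame_size))
    for e in tree.edges:
        pts, radii = _bezier_points(e)
        _sweep_disks(canvas, pts, radii)
    return canvas


@dataclass
class PhantomSample:
    image: np.ndarray       # uint8 grayscale, dark vessels on bright bg
    mask: np.ndarray        # uint8 {0, 1}
    meta: dict


def render_angiogram(tree: VesselTree, contrast_depth: float = 80.0,
                     blur_sigma: float = 0.8, noise_sigma: float = 5.0,
                     distractors: bool = False, seed: int = 0) -> PhantomSample:
    """Render a tree to an 8-bit angiogram-like frame plus ground truth.

    The image is a smooth bright background (level ≈ 200/255 with a gradient
    and blurred blob shadows) minus ``contrast_depth`` inside the vessels,
    Gaussian-blurred by ``blur_sigma`` and corrupted by additive Gaussian
    noise of ``noise_sigma``; an optional catheter-like dark curve is drawn
    but excluded from the mask.
    """
    rng = np.random.default_rng(seed)
    n = tree.frame_size
    soft = rasterize_tree(tree)
    mask = (soft >= 0.5).astype(np.uint8)

    yy, xx = np.mgrid[0:n, 0:n] / (n - 1)
    gdir = rng.uniform(0.0, 2 * math.pi)
    bg = BACKGROUND_LEVEL + 15.0 * ((xx - 0.5) * math.cos(gdir) +
                                    (yy - 0.5) * math.sin(gdir))
    blobs = ndimage.gaussian_filter(rng.standard_normal((n, n)), n / 10.0)
    std = blobs.std()
    if std > 0:
        bg = bg + 10.0 * blobs / std

    img = bg - contrast_depth * soft
    if distractors:
        cath = _catheter_curve(rng, n)
        img = img - 0.8 * contrast_depth * cath
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    if noise_sigma > 0:
        img = img + rng.standard_normal((n, n)) * noise_sigma
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    meta = {
        "seed": int(seed), "frame_size": int(n),
        "contrast_depth": float(contrast_depth),
        "blur_sigma": float(blur_sigma), "noise_sigma": float(noise_sigma),
        "distractors": bool(distractors),
        "n_edges": len(tree.edges),
    }
    return PhantomSample(image=img, mask=mask, meta=meta)


def _catheter_curve(rng: np.random.Generator, n: int) -> np.ndarray:
    """Coverage map of a long thin constant-radius curve (not a vessel)."""
    canvas = np.zeros((n, n))
    p0 = np.array([rng.uniform(0, n - 1), 0.0])
    p1 = np.array([rng.uniform(0, n - 1), float(n - 1)])
    pc = np.array([rng.uniform(0, n - 1), rng.uniform(0, n - 1)])
    e = Edge(p0=p0, pc=pc, p1=p1, r0=2.2 * n / 256, r1=2.2 * n / 256, generation=0)
    pts, radii = _bezier_points(e)
    _sweep_disks(canvas, pts, radii)
    return canvas


# ---------------------------------------------------------------------------
# regimes and datasets
# ---------------------------------------------------------------------------

REGIMES = {
    # (contrast range, noise range, blur range, depth, n_roots, distractors)
    "easy": dict(contrast=(60, 110), noise=(3, 6), blur=(0.6, 1.0),
                 depth=4, n_roots=1, distractors=False),
    "low_contrast": dict(contrast=(18, 35), noise=(6, 10), blur=(0.8, 1.4),
                         depth=4, n_roots=1, distractors=False),
    "complex": dict(contrast=(50, 100), noise=(4, 8), blur=(0.6, 1.2),
                    depth=5, n_roots=2, distractors=True),
    "fuzzy": dict(contrast=(45, 90), noise=(4, 8), blur=(2.0, 3.5),
                  depth=4, n_roots=1, distractors=False),
}


def make_sample(seed: int, frame_size: int = 256,
                regime: str = "easy") -> PhantomSample:
    """One seeded sample: regime ranges are drawn deterministically from
    ``seed``, then the tree and rendering reuse the same seed."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    spec = REGIMES[regime]
    rr = np.random.default_rng(seed)
    contrast = rr.uniform(*spec["contrast"])
    noise = rr.uniform(*spec["noise"])
    blur = rr.uniform(*spec["blur"])
    params = TreeParams(depth=spec["depth"], n_roots=spec["n_roots"])
    tree = generate_tree(seed, frame_size, params)
    sample = render_angiogram(tree, contrast_depth=contrast, blur_sigma=blur,
                              noise_sigma=noise,
                              distractors=spec["distractors"], seed=seed)
    sample.meta["regime"] = regime
    return sample


MANIFEST_FIELDS = ["stem", "seed", "regime", "frame_size", "contrast_depth",
                   "blur_sigma", "noise_sigma", "distractors", "n_edges"]


def make_dataset(n: int, seed: int, regime: str, out_dir: str | Path,
                 frame_size: int = 256) -> Path:
    """Write ``n`` seeded image/mask PNG pairs plus a TSV manifest.

    Returns the manifest path.  Per-sample seeds are spawned from ``seed``
    and recorded, so the manifest alone regenerates every file
    byte-identically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    manifest = out / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=MANIFEST_FIELDS, delimiter="\t")
        wr.writeheader()
        for i, s in enumerate(child_seeds):
            sample = make_sample(int(s), frame_size=frame_size, regime=regime)
            stem = f"{i:04d}"
            Image.fromarray(sample.image).save(out / "images" / f"{stem}.png")
            Image.fromarray(sample.mask * 255).save(out / "masks" / f"{stem}.png")
            row = {"stem": stem, **{k: sample.meta[k] for k in MANIFEST_FIELDS
                                    if k in sample.meta}}
            wr.writerow(row)
    return manifest


def tube_phantom(seed: int, frame_size: int = 128, half_width: float = 2.0,
                 contrast_depth: float = 80.0, noise_sigma: float = 3.0,
                 blur_sigma: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
    """A single smoothly curving near-vertical dark tube with a known
    centerline; returns (image, centerline column per row).

    Used for centerline-accuracy checks of the vesselness filter."""
    rng = np.random.default_rng(seed)
    n = frame_size
    rows = np.arange(n)
    amp = rng.uniform(4.0, 10.0)
    period = rng.uniform(1.2, 2.5) * n
    phase = rng.uniform(0, 2 * math.pi)
    center = n / 2 + rng.uniform(-n / 8, n / 8) + \
        amp * np.sin(2 * math.pi * rows / period + phase)
    cols = np.arange(n)[None, :]
    d = np.abs(cols - center[:, None])
    cov = np.clip(half_width + 0.5 - d, 0.0, 1.0)
    img = BACKGROUND_LEVEL - contrast_depth * cov
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    if noise_sigma > 0:
        img = img + rng.standard_normal((n, n)) * noise_sigma
    return np.clip(img, 0, 255), center
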