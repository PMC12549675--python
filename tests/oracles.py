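"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they validate: the vesselness
oracle uses a general symmetric eigensolver and direct response arithmetic
instead of the closed-form pipeline; the HD95 oracle computes all pairwise
boundary distances explicitly instead of KD-tree queries.
"""

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist


def _oracle_kernels(sigma):
    """Sampled Gaussian-derivative kernels with polynomial-moment
    normalisation (independent construction of the same discrete operator:
    zeroth moments vanish, first/second moments equal 1/2)."""
    r = max(int(4.0 * sigma + 0.5), 1)
    x = np.arange(2 * r + 1, dtype=float) - r
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g = g / g.sum()
    d1 = -x / sigma ** 2 * g
    d1 = d1 - d1.sum() * g
    d1 = d1 / (d1 * x).sum()
    d2 = (x ** 2 / sigma ** 2 - 1.0) / sigma ** 2 * g
    d2 = d2 - d2.sum() * g
    d2 = d2 * (2.0 / (d2 * x ** 2).sum())
    return g, d1, d2


def frangi_oracle(image: np.ndarray, sigmas, beta: float, c: float,
                  bright_vessels: bool = False) -> np.ndarray:
    """Max-over-scales vesselness via np.linalg.eigvalsh per pixel."""
    image = np.asarray(image, dtype=float)
    work = image if bright_vessels else -image
    best = np.zeros_like(work)
    for s in sigmas:
        s2 = s * s
        g, d1, d2 = _oracle_kernels(s)

        def both(img, ky, kx):
            out = ndimage.correlate1d(img, ky, axis=0, mode="reflect")
            return ndimage.correlate1d(out, kx, axis=1, mode="reflect")

        ixx = both(work, g, d2) * s2
        iyy = both(work, d2, g) * s2
        ixy = both(work, d1, d1) * s2
        hmat = np.stack([np.stack([ixx, ixy], -1),
                         np.stack([ixy, iyy], -1)], -2)   # (H, W, 2, 2)
        vals = np.linalg.eigvalsh(hmat)                    # ascending
        lo, hi = vals[..., 0], vals[..., 1]
        swap = np.abs(lo) > np.abs(hi)
        lam2 = np.where(swap, lo, hi)
        lam1 = np.where(swap, hi, lo)
        resp = np.zeros_like(work)
        ok = lam2 < 0
        rb2 = np.zeros_like(work)
        rb2[ok] = (lam1[ok] / lam2[ok]) ** 2
        s2n = lam1 ** 2 + lam2 ** 2
        resp[ok] = np.exp(-rb2[ok] / (2 * beta ** 2)) * \
            (1.0 - np.exp(-s2n[ok] / (2 * c ** 2)))
        best = np.maximum(best, resp)
    return best


def boundary_oracle(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    er = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(m & ~er)


def hd95_oracle(pred: np.ndarray, gt: np.ndarray) -> float:
    """95th percentile of pooled directed distances via the full distance
    matrix."""
    bp = boundary_oracle(pred).astype(float)
    bg = boundary_oracle(gt).astype(float)
    d = cdist(bp, bg)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))
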