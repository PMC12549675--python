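"""Image and dataset I/O.

Frames are 8- or 16-bit grayscale PNGs (RGB accepted and converted by
luminance); every loader returns float arrays on a common [0, 255] scale.
Datasets are directories ``images/*.png`` + ``masks/*.png`` with matching
stems; masks are 0/255 PNGs binarised at half range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["load_image", "load_mask", "save_mask", "load_dataset"]

_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path: str | Path) -> np.ndarray:
    """Grayscale float image scaled to [0, 255] regardless of bit depth."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
        return arr
    arr = arr.astype(np.float64)
    if arr.max() > 255.0:        # 16-bit input: map full range onto [0, 255]
        arr = arr * (255.0 / 65535.0)
    return arr


def load_mask(path: str | Path) -> np.ndarray:
    """Binary {0,1} mask from a 0/255 PNG (threshold at half range)."""
    return (load_image(path) >= 127.5).astype(np.uint8)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG."""
    m = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(m).save(Path(path))


def load_dataset(root: str | Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """(image, mask) pairs from ``root/images`` + ``root/masks`` by stem."""
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise IOError(f"{root} must contain images/ and masks/ directories")
    pairs = []
    for img_path in sorted(img_dir.glob("*.png")):
        mask_path = mask_dir / img_path.name
        if not mask_path.exists():
            raise IOError(f"missing mask for {img_path.name}")
        pairs.append((load_image(img_path), load_mask(mask_path)))
    if not pairs:
        raise IOError(f"no PNG pairs found under {root}")
    return pairs
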