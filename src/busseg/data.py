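"""Dataset I/O: paired image/mask loading, saving and resizing.

Mask convention: ``<stem>_mask.png`` next to ``<stem>.png`` (PNG/BMP/TIFF),
lesion = 255; loaders also accept 0/1 masks.  Images are 8-bit grayscale,
normalized to [0, 1] on load.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .phantom import SamplePair

__all__ = [
    "IMAGE_EXTENSIONS",
    "load_pair",
    "load_directory",
    "save_pair",
    "save_dataset",
    "resize_pair",
]

IMAGE_EXTENSIONS = (".png", ".bmp", ".tif", ".tiff")


def _read_gray(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"unreadable image file {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr, dtype=np.float64)


def load_pair(image_path) -> SamplePair:
    """Load one image and its ``<stem>_mask`` companion."""
    image_path = Path(image_path)
    mask_path = None
    for ext in IMAGE_EXTENSIONS:
        candidate = image_path.with_name(image_path.stem + "_mask" + ext)
        if candidate.exists():
            mask_path = candidate
            break
    if mask_path is None:
        raise FileNotFoundError(f"no mask found for image {image_path} "
                                f"(expected {image_path.stem}_mask.*)")
    img = _read_gray(image_path) / 255.0
    raw_mask = _read_gray(mask_path)
    mask = (raw_mask > raw_mask.max() / 2 if raw_mask.max() > 0
            else raw_mask > 0).astype(np.uint8)
    if img.shape != mask.shape:
        raise ValueError(
            f"image/mask shape mismatch for {image_path}: {img.shape} vs "
            f"{mask.shape}")
    return SamplePair(image=img.astype(np.float32), mask=mask,
                      provenance=str(image_path))


def load_directory(directory) -> list:
    """Load all image/mask pairs in a directory (sorted by filename)."""
    directory = Path(directory)
    pairs = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        if path.stem.endswith("_mask"):
            continue
        pairs.append(load_pair(path))
    if not pairs:
        raise FileNotFoundError(f"no image/mask pairs found in {directory}")
    return pairs


def save_pair(sample: SamplePair, directory, stem: str):
    """Write ``<stem>.png`` and ``<stem>_mask.png`` as 8-bit PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.asarray(sample.image) * 255.0, 0, 255).astype(np.uint8)
    mask8 = (np.asarray(sample.mask) > 0).astype(np.uint8) * 255
    iio.imwrite(directory / f"{stem}.png", img8)
    iio.imwrite(directory / f"{stem}_mask.png", mask8)


def save_dataset(samples, directory, prefix: str = "phantom"):
    width = max(4, len(str(len(samples))))
    for i, s in enumerate(samples):
        save_pair(s, directory, f"{prefix}_{i:0{width}d}")


def resize_pair(sample: SamplePair, side: int) -> SamplePair:
    """Bilinear resize for the image, nearest for the mask (stays binary)."""
    if sample.image.shape == (side, side):
        return sample
    img = _sk_resize(sample.image, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(sample.mask.astype(np.float32), (side, side), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return SamplePair(image=np.clip(img, 0, 1).astype(np.float32),
                      mask=(msk > 0.5).astype(np.uint8),
                      provenance=sample.provenance)
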