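"""Reading and writing of images, masks and probability maps.

Images are 8-bit RGB (PNG/TIFF/JPEG); masks are single-channel PNG with
values {0, 255} on disk and {0, 1} in memory; probability maps are stored
as 16-bit PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def read_image(path) -> np.ndarray:
    """Load an image as uint8 RGB (H, W, 3); grayscale is replicated,
    alpha channels are dropped."""
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    """Load a binary mask as uint8 {0, 1}."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_probability(path, pmap: np.ndarray) -> None:
    """Store a [0, 1] probability map as 16-bit PNG."""
    arr = np.clip(np.asarray(pmap, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def read_probability(path) -> np.ndarray:
    arr = iio.imread(path)
    return arr.astype(np.float64) / 65535.0
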