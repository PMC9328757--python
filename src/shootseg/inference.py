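"""Full-image segmentation: pad, tile, predict, reassemble, threshold,
clean, colorize.

Prediction normalizes intensities to [0, 1] exactly as in training, runs
each 256 x 256 tile through the network, stitches the per-tile probability
maps back together and crops to the source size.  The probability map is
binarized at T = 0.6 by default (probability >= T is plant), optionally
cleaned by removing small connected components, and can be rendered as an
RGB overlay in which background pixels are black.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .tiling import extract_patches, pad_to_tile_multiple, reassemble

DEFAULT_THRESHOLD = 0.6
CONNECTIVITY = 2  # 8-connectivity: diagonal stems/leaves stay connected


def predict_probability(model, image: np.ndarray, batch_size: int = 4) -> np.ndarray:
    """Per-pixel plant probability for an RGB image of any size >= 256."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    x = image.astype(np.float32) / 255.0
    padded, (pb, pr) = pad_to_tile_multiple(x, model.config.patch_size)
    grid = extract_patches(padded, pb, pr, model.config.patch_size)
    probs = model.predict(grid.patches, batch_size=batch_size)
    grid.patches = probs[..., 0]
    pmap = reassemble(grid)
    return np.clip(pmap, 0.0, 1.0)


def threshold_probability(pmap: np.ndarray, threshold: float = DEFAULT_THRESHOLD):
    """Binarize a probability map: plant where probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (np.asarray(pmap) >= threshold).astype(np.uint8)


def remove_small_clusters(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop 8-connected plant components smaller than ``min_size`` pixels."""
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    if min_size <= 1 or not mask.any():
        return mask
    labels = measure.label(mask, connectivity=CONNECTIVITY)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels].astype(np.uint8)


def colorize(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    """RGB rendering of a segmentation: plant pixels keep their original
    color, background is black."""
    mask = np.asarray(mask)
    image = np.asarray(image)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask and image sizes differ")
    return image * (mask > 0)[..., None].astype(image.dtype)


def segment_image(
    model,
    image: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_cluster_size: int = 0,
    roi: tuple[int, int, int, int] | None = None,
):
    """Probability map + cleaned binary mask for one image.

    ``roi`` = (r0, c0, r1, c1) restricts the returned mask to a rectangle
    (pixels outside are background).  Returns ``(pmap, mask)``.
    """
    pmap = predict_probability(model, image)
    mask = threshold_probability(pmap, threshold)
    if roi is not None:
        r0, c0, r1, c1 = roi
        keep = np.zeros_like(mask)
        keep[r0:r1, c0:c1] = mask[r0:r1, c0:c1]
        mask = keep
    mask = remove_small_clusters(mask, min_cluster_size)
    return pmap, mask
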