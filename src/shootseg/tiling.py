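"""Lossless conversion between full-size images and 256 x 256 patch grids.

Full-resolution greenhouse images are zero-padded on the bottom and right
edges to the next multiple of the tile size, cut into non-overlapping
tiles in row-major order, and later reassembled bit-exactly.  Anchoring
the original content at the top-left keeps pixel coordinates unchanged,
which the trait geometry relies on.  The same operations apply to
3-channel images, single-channel masks and probability maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_TILE = 256


def pad_to_tile_multiple(image: np.ndarray, tile: int = DEFAULT_TILE):
    """Zero-pad ``image`` so both spatial dimensions are multiples of ``tile``.

    Returns ``(padded, (pad_bottom, pad_right))``.  Works on (H, W) and
    (H, W, C) arrays; added pixels are zero in all channels.
    """
    if tile <= 0:
        raise ValueError(f"tile size must be positive, got {tile}")
    if image.ndim not in (2, 3) or image.size == 0:
        raise ValueError("image must be a non-empty 2-D or 3-D array")
    h, w = image.shape[:2]
    if h < tile or w < tile:
        warnings.warn(
            f"image {h}x{w} is smaller than the documented {tile}x{tile} "
            "minimum; padding up",
            stacklevel=2,
        )
    pad_bottom = (-h) % tile
    pad_right = (-w) % tile
    pads = [(0, pad_bottom), (0, pad_right)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pads), (pad_bottom, pad_right)


@dataclass
class PatchGrid:
    """Row-major grid of tiles plus the geometry needed to invert tiling."""

    patches: np.ndarray  # (n, tile, tile[, C])
    grid_rows: int
    grid_cols: int
    original_height: int
    original_width: int
    pad_bottom: int
    pad_right: int
    tile: int = DEFAULT_TILE

    def validate(self) -> None:
        t = self.tile
        if self.grid_rows * t != self.original_height + self.pad_bottom:
            raise ValueError("grid rows inconsistent with padded height")
        if self.grid_cols * t != self.original_width + self.pad_right:
            raise ValueError("grid cols inconsistent with padded width")
        if len(self.patches) != self.grid_rows * self.grid_cols:
            raise ValueError(
                f"expected {self.grid_rows * self.grid_cols} patches, "
                f"got {len(self.patches)}"
            )
        if not (0 <= self.pad_bottom < t and 0 <= self.pad_right < t):
            raise ValueError("padding must lie in [0, tile)")


def extract_patches(
    padded: np.ndarray,
    pad_bottom: int = 0,
    pad_right: int = 0,
    tile: int = DEFAULT_TILE,
) -> PatchGrid:
    """Cut a padded image into a row-major grid of non-overlapping tiles.

    ``pad_bottom``/``pad_right`` record how much of the padded image is
    filler, so the grid can be cropped back to the original size.
    """
    h, w = padded.shape[:2]
    if h % tile or w % tile:
        raise ValueError(f"padded dimensions {h}x{w} not divisible by {tile}")
    rows, cols = h // tile, w // tile
    n = rows * cols
    patches = (
        padded.reshape(rows, tile, cols, tile, *padded.shape[2:])
        .swapaxes(1, 2)
        .reshape(n, tile, tile, *padded.shape[2:])
    )
    return PatchGrid(
        patches=np.ascontiguousarray(patches),
        grid_rows=rows,
        grid_cols=cols,
        original_height=h - pad_bottom,
        original_width=w - pad_right,
        pad_bottom=pad_bottom,
        pad_right=pad_right,
        tile=tile,
    )


def tile_image(image: np.ndarray, tile: int = DEFAULT_TILE) -> PatchGrid:
    """Pad and tile in one step."""
    padded, (pb, pr) = pad_to_tile_multiple(image, tile)
    return extract_patches(padded, pb, pr, tile)


def reassemble(grid: PatchGrid) -> np.ndarray:
    """Invert :func:`extract_patches`, cropping away the padding."""
    grid.validate()
    t = grid.tile
    p = np.asarray(grid.patches)
    full = (
        p.reshape(grid.grid_rows, grid.grid_cols, t, t, *p.shape[3:])
        .swapaxes(1, 2)
        .reshape(grid.grid_rows * t, grid.grid_cols * t, *p.shape[3:])
    )
    return full[: grid.original_height, : grid.original_width]
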