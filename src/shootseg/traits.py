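"""Shoot trait quantification: 35 scalar traits in 4 feature groups.

Traits are computed over the union of all segmented plant components of
one image (whole-shoot phenotyping) and fall into four groups:

* ``area``  (5)  -- projected plant area, hole-filled area, area fraction,
  component count, largest-component area;
* ``bbox``  (8)  -- bounding-box anchor, size, area, aspect ratio, extent
  and diagonal;
* ``hull``  (4)  -- convex-hull area, solidity, hull perimeter and maximum
  hull diameter (Feret-like);
* ``color`` (18) -- mean/SD/median of R, G, B over plant pixels, circular
  mean/SD of hue plus mean/SD of saturation and value, mean excess green
  2G - R - B, mean normalized green G/(R+G+B), and mean brightness
  (R+G+B)/3.

All lengths and areas are in pixels.  For an empty mask the geometric
traits are 0 and the color traits are NaN (no plant pixels to average).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, morphology
from skimage.color import rgb2hsv

TRAIT_GROUPS: dict[str, list[str]] = {
    "area": [
        "plant_area_px",
        "filled_area_px",
        "area_fraction",
        "component_count",
        "largest_component_area_px",
    ],
    "bbox": [
        "min_row",
        "min_col",
        "height_px",
        "width_px",
        "area_px",
        "aspect_ratio",
        "extent",
        "diagonal_px",
    ],
    "hull": [
        "area_px",
        "solidity",
        "perimeter_px",
        "max_diameter_px",
    ],
    "color": [
        "mean_r", "sd_r", "median_r",
        "mean_g", "sd_g", "median_g",
        "mean_b", "sd_b", "median_b",
        "mean_h", "sd_h",
        "mean_s", "sd_s",
        "mean_v", "sd_v",
        "mean_excess_green",
        "mean_normalized_green",
        "mean_brightness",
    ],
}

TRAIT_NAMES: list[str] = [
    f"{group}.{name}" for group, names in TRAIT_GROUPS.items() for name in names
]


def _circular_hue_stats(h_deg: np.ndarray) -> tuple[float, float]:
    """Mean direction and circular SD of hue angles, in degrees."""
    rad = np.deg2rad(h_deg)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    mean = math.degrees(math.atan2(s, c)) % 360.0
    r = min(math.hypot(s, c), 1.0)
    sd = math.degrees(math.sqrt(max(-2.0 * math.log(max(r, 1e-12)), 0.0)))
    return mean, sd


def _hull_metrics(mask: np.ndarray, filled_area: float):
    coords = np.argwhere(mask)
    hull_img = morphology.convex_hull_image(mask)
    hull_area = float(hull_img.sum())
    perimeter = float(measure.perimeter(hull_img))
    try:
        hull = ConvexHull(coords)
        verts = coords[hull.vertices].astype(np.float64)
        diffs = verts[:, None, :] - verts[None, :, :]
        max_diam = float(np.sqrt((diffs**2).sum(-1)).max())
    except (QhullError, ValueError):
        # degenerate (single pixel / collinear) masks
        pts = coords.astype(np.float64)
        if len(pts) == 1:
            max_diam = 0.0
        else:
            diffs = pts[:, None, :] - pts[None, :, :]
            max_diam = float(np.sqrt((diffs**2).sum(-1)).max())
        hull_area = max(hull_area, filled_area)
    return hull_area, perimeter, max_diam


def compute_traits(mask: np.ndarray, image: np.ndarray) -> dict[str, float]:
    """All 35 traits for one (mask, image) pair, keyed ``group.name``."""
    mask = np.asarray(mask)
    image = np.asarray(image)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask and image sizes differ")
    m = mask > 0
    out = dict.fromkeys(TRAIT_NAMES, 0.0)
    if not m.any():
        for name in TRAIT_GROUPS["color"]:
            out[f"color.{name}"] = float("nan")
        return out

    area = float(m.sum())
    filled = ndimage.binary_fill_holes(m)
    labels = measure.label(m, connectivity=2)
    counts = np.bincount(labels.ravel())[1:]
    out["area.plant_area_px"] = area
    out["area.filled_area_px"] = float(filled.sum())
    out["area.area_fraction"] = area / m.size
    out["area.component_count"] = float(len(counts))
    out["area.largest_component_area_px"] = float(counts.max())

    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    bh, bw = float(r1 - r0 + 1), float(c1 - c0 + 1)
    out["bbox.min_row"] = float(r0)
    out["bbox.min_col"] = float(c0)
    out["bbox.height_px"] = bh
    out["bbox.width_px"] = bw
    out["bbox.area_px"] = bh * bw
    out["bbox.aspect_ratio"] = bh / bw
    out["bbox.extent"] = area / (bh * bw)
    out["bbox.diagonal_px"] = math.hypot(bh, bw)

    hull_area, hull_perim, hull_diam = _hull_metrics(m, out["area.filled_area_px"])
    out["hull.area_px"] = hull_area
    out["hull.solidity"] = area / hull_area if hull_area else 0.0
    out["hull.perimeter_px"] = hull_perim
    out["hull.max_diameter_px"] = hull_diam

    pix = image[m].astype(np.float64)
    r, g, b = pix[:, 0], pix[:, 1], pix[:, 2]
    for chan, vals in zip("rgb", (r, g, b)):
        out[f"color.mean_{chan}"] = float(vals.mean())
        out[f"color.sd_{chan}"] = float(vals.std())
        out[f"color.median_{chan}"] = float(np.median(vals))
    hsv = rgb2hsv(pix[None, :, :] / 255.0)[0]
    mean_h, sd_h = _circular_hue_stats(hsv[:, 0] * 360.0)
    out["color.mean_h"] = mean_h
    out["color.sd_h"] = sd_h
    out["color.mean_s"] = float(hsv[:, 1].mean())
    out["color.sd_s"] = float(hsv[:, 1].std())
    out["color.mean_v"] = float(hsv[:, 2].mean())
    out["color.sd_v"] = float(hsv[:, 2].std())
    out["color.mean_excess_green"] = float((2 * g - r - b).mean())
    total = r + g + b
    out["color.mean_normalized_green"] = float(
        np.where(total > 0, g / np.where(total > 0, total, 1.0), 0.0).mean()
    )
    out["color.mean_brightness"] = float(total.mean() / 3.0)
    return out


def traits_to_table(records, ids=None) -> pd.DataFrame:
    """One row per image, stable group-prefixed column order."""
    records = list(records)
    if ids is None:
        ids = [f"image_{i:04d}" for i in range(len(records))]
    rows = [
        {"id": i, **{name: rec.get(name, float("nan")) for name in TRAIT_NAMES}}
        for i, rec in zip(ids, records)
    ]
    return pd.DataFrame(rows, columns=["id", *TRAIT_NAMES])
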