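"""Segmentation evaluation: Dice coefficient and pixel-averaged binary
cross-entropy.

The Dice coefficient DC = 2|P ∩ G| / (|P| + |G|) scores the overlap
between a predicted mask P and ground truth G; 1 is perfect agreement, 0
total failure.  When both masks are empty the score is defined as 1.0
(perfect agreement on absence; the ratio is otherwise 0/0).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_EPS = 1e-7


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient between two binary masks of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    g = truth.astype(bool)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def binary_cross_entropy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-pixel binary cross-entropy, natural log, probabilities
    clipped to [1e-7, 1 - 1e-7]."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(truth * np.log(p) + (1.0 - truth) * np.log(1.0 - p)))


def evaluate_mask_pairs(pairs, names=None) -> pd.DataFrame:
    """Per-image Dice/CE table with a trailing mean/SD summary row.

    ``pairs`` is an iterable of (predicted probability-or-mask, ground
    truth mask) arrays.
    """
    rows = []
    for i, (p, g) in enumerate(pairs):
        name = names[i] if names is not None else f"image_{i:04d}"
        rows.append(
            {
                "image": name,
                "dice": dice(np.asarray(p) >= 0.5, g),
                "ce_loss": binary_cross_entropy(p, g),
            }
        )
    df = pd.DataFrame(rows, columns=["image", "dice", "ce_loss"])
    if len(df):
        summary = pd.DataFrame(
            [
                {"image": "mean", "dice": df["dice"].mean(), "ce_loss": df["ce_loss"].mean()},
                {"image": "sd", "dice": df["dice"].std(ddof=1), "ce_loss": df["ce_loss"].std(ddof=1)},
            ]
        )
        df = pd.concat([df, summary], ignore_index=True)
    return df


def evaluate_mask_dirs(pred_dir, truth_dir, out_csv=None) -> pd.DataFrame:
    """Match same-named mask files in two directories and score them."""
    from .image_io import read_mask

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    names = sorted(p.name for p in pred_dir.iterdir() if p.is_file())
    pairs = [(read_mask(pred_dir / n), read_mask(truth_dir / n)) for n in names]
    df = evaluate_mask_pairs(pairs, names)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
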