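"""Shallow pixel-classifier baseline.

Each pixel is described by the raw intensities of its 3 x 3 neighborhood
across the red, green and blue channels (27 features, scaled to [0, 1];
image borders use edge replication) and classified plant/background by a
small fully-connected network.  The classifier sees no spatial context
beyond the neighborhood window, which is exactly what makes it a useful
contrast to the U-net on scenes where plant and distractor colors overlap.

The network itself is scikit-learn's MLPClassifier (two hidden layers,
64 and 32 ReLU units, Adam, log-loss), a stand-in configuration for the
original shallow architecture.
"""

from __future__ import annotations

import numpy as np
from sklearn.neural_network import MLPClassifier

FEATURE_LENGTH = 27
HIDDEN_LAYERS = (64, 32)


def extract_pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel 27-vector: 3x3 neighborhood x RGB, row-major neighbor
    order with channels innermost, normalized to [0, 1].

    The center pixel's channels sit at positions 12..14.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    h, w = image.shape[:2]
    if h < 3 or w < 3:
        raise ValueError("image must be at least 3 x 3")
    padded = np.pad(image, ((1, 1), (1, 1), (0, 0)), mode="edge")
    feats = np.empty((h, w, 9, 3), dtype=np.float32)
    for i, (dr, dc) in enumerate(
        (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
    ):
        feats[:, :, i, :] = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w, :]
    return feats.reshape(h * w, FEATURE_LENGTH) / 255.0


def sample_training_pixels(images, masks, n_per_class=20000, seed=0):
    """Balanced seeded sample of plant/background pixel features."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for img, msk in zip(images, masks):
        feats.append(extract_pixel_features(img))
        labels.append((np.asarray(msk).ravel() > 0).astype(np.int8))
    x = np.concatenate(feats)
    y = np.concatenate(labels)
    sel = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        take = min(n_per_class, len(idx))
        sel.append(rng.choice(idx, take, replace=False))
    sel = np.concatenate(sel)
    return x[sel], y[sel]


def train_pixel_nn(features, labels, seed=0, max_iter=60):
    """Fit the shallow classifier on balanced pixel features."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    clf = MLPClassifier(
        hidden_layer_sizes=HIDDEN_LAYERS,
        activation="relu",
        solver="adam",
        batch_size=min(512, len(labels)),
        max_iter=max_iter,
        random_state=seed,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(features, labels)
    return clf


def predict_pixel_nn(clf, image: np.ndarray) -> np.ndarray:
    """Classify every pixel of ``image``; returns a {0, 1} uint8 mask
    (plant probability thresholded at 0.5)."""
    h, w = image.shape[:2]
    feats = extract_pixel_features(image)
    prob = clf.predict_proba(feats)[:, list(clf.classes_).index(1)]
    return (prob >= 0.5).astype(np.uint8).reshape(h, w)
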