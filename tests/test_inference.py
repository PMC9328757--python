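"""Thresholding, cluster cleanup, colorization and tiled prediction."""

import numpy as np
import pytest

from shootseg.inference import (
    colorize,
    predict_probability,
    remove_small_clusters,
    threshold_probability,
)
from shootseg.unet import ModelConfig


def test_threshold_boundary_inclusive():
    pmap = np.array([[0.6, 0.599], [0.0, 1.0]])
    mask = threshold_probability(pmap, 0.6)
    np.testing.assert_array_equal(mask, [[1, 0], [0, 1]])


def test_threshold_counts_and_empty_map():
    rng = np.random.default_rng(0)
    pmap = rng.random((40, 40))
    for t in (0.3, 0.6, 0.9):
        assert threshold_probability(pmap, t).sum() == int((pmap >= t).sum())
    assert threshold_probability(np.zeros((5, 5)), 0.6).sum() == 0


def test_threshold_monotone_in_t():
    rng = np.random.default_rng(1)
    pmap = rng.random((30, 30))
    previous = None
    for t in np.linspace(0.05, 0.95, 10):
        mask = threshold_probability(pmap, float(t))
        if previous is not None:
            assert not np.any(mask & ~previous)  # raising T never adds pixels
        previous = mask


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.3, 1.5])
def test_threshold_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        threshold_probability(np.zeros((2, 2)), bad)


def _flood_fill_components(mask):
    """Brute-force 8-connected component sizes (independent of skimage)."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        stack, pixels = [(r0, c0)], []
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            pixels.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        comps.append(pixels)
    return comps


def test_remove_small_clusters_matches_flood_fill_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        mask = (rng.random((24, 24)) < 0.25).astype(np.uint8)
        min_size = int(rng.integers(1, 8))
        cleaned = remove_small_clusters(mask, min_size)
        expected = np.zeros_like(mask)
        for comp in _flood_fill_components(mask):
            if len(comp) >= min_size:
                for r, c in comp:
                    expected[r, c] = 1
        np.testing.assert_array_equal(cleaned, expected)


def test_remove_small_clusters_examples_and_edge_cases():
    mask = np.zeros((30, 30), dtype=np.uint8)
    mask[1:6, 1] = 1  # 5-pixel component
    mask[10:20, 10:15] = 1  # 50-pixel component
    cleaned = remove_small_clusters(mask, 10)
    assert cleaned.sum() == 50
    assert cleaned[12, 12] == 1 and cleaned[2, 1] == 0
    np.testing.assert_array_equal(remove_small_clusters(mask, 0), mask)
    assert remove_small_clusters(mask, mask.sum() + 1).sum() == 0
    with pytest.raises(ValueError):
        remove_small_clusters(mask, -1)


def test_remove_small_clusters_idempotent():
    rng = np.random.default_rng(9)
    for _ in range(10):
        mask = (rng.random((20, 20)) < 0.3).astype(np.uint8)
        once = remove_small_clusters(mask, 5)
        np.testing.assert_array_equal(remove_small_clusters(once, 5), once)


def test_colorize_examples():
    rng = np.random.default_rng(2)
    img = rng.integers(1, 256, (10, 10, 3), dtype=np.uint8)
    assert colorize(np.zeros((10, 10), np.uint8), img).sum() == 0
    np.testing.assert_array_equal(colorize(np.ones((10, 10), np.uint8), img), img)
    single = np.zeros((10, 10), np.uint8)
    single[4, 7] = 1
    out = colorize(single, img)
    assert (out.sum(axis=2) > 0).sum() == 1
    np.testing.assert_array_equal(out[4, 7], img[4, 7])
    with pytest.raises(ValueError):
        colorize(np.zeros((3, 3)), img)


class _MeanStub:
    """Translation-equivariant stand-in model: per-patch channel mean."""

    def __init__(self, patch_size=64):
        self.config = ModelConfig(
            patch_size=patch_size, depth=1, encoder_filters=[4], bridge_filters=8
        )

    def predict(self, x, batch_size=8):
        x = np.asarray(x, dtype=np.float32)
        out = x.mean(axis=3, keepdims=True)
        return out


def test_predict_probability_matches_blockwise_oracle():
    rng = np.random.default_rng(11)
    img = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
    stub = _MeanStub(64)
    pmap = predict_probability(stub, img)
    assert pmap.shape == (128, 128)
    # oracle: evaluate the stub on each 64x64 block directly
    x = img.astype(np.float32) / 255.0
    for bi in range(2):
        for bj in range(2):
            block = x[64 * bi : 64 * (bi + 1), 64 * bj : 64 * (bj + 1)]
            np.testing.assert_allclose(
                pmap[64 * bi : 64 * (bi + 1), 64 * bj : 64 * (bj + 1)],
                block.mean(axis=2),
                rtol=1e-5,
            )


def test_predict_probability_single_tile_equals_direct_patch():
    rng = np.random.default_rng(12)
    img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
    stub = _MeanStub(64)
    pmap = predict_probability(stub, img)
    direct = stub.predict((img.astype(np.float32) / 255.0)[None])[0, :, :, 0]
    np.testing.assert_allclose(pmap, direct, rtol=1e-6)
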