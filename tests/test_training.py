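"""Patch balancing, splitting, and the training loop itself."""

import numpy as np
import pytest

from shootseg.training import (
    TrainingConfig,
    prepare_balanced_patches,
    split_train_val,
    train,
)
from shootseg.unet import ModelConfig, build_unet

TINY = ModelConfig(
    patch_size=32, kernel_size=3, depth=2, encoder_filters=[4, 8], bridge_filters=16
)


def _image_with_plant_patches(n_plant, n_background, tile=32):
    """One wide image whose tiles are plant/background by construction."""
    total = n_plant + n_background
    img = np.zeros((tile, tile * total, 3), dtype=np.uint8)
    mask = np.zeros((tile, tile * total), dtype=np.uint8)
    img[:, :, 1] = 60
    for i in range(n_plant):
        mask[tile // 2, i * tile + tile // 2] = 1
    return img, mask


def test_balancing_subsamples_majority_class():
    img, mask = _image_with_plant_patches(40, 100)
    x, y = prepare_balanced_patches([img], [mask], seed=0, tile=32)
    n_plant = int(sum(y[i].any() for i in range(len(y))))
    assert len(x) == 80
    assert n_plant == 40


def test_balancing_keeps_already_balanced_data():
    img, mask = _image_with_plant_patches(10, 10)
    x, y = prepare_balanced_patches([img], [mask], seed=0, tile=32)
    assert len(x) == 20


def test_all_plant_mask_yields_no_background_patches():
    img = np.zeros((32, 64, 3), dtype=np.uint8)
    mask = np.ones((32, 64), dtype=np.uint8)
    x, y = prepare_balanced_patches([img], [mask], seed=0, tile=32)
    assert len(x) == 2
    assert all(y[i].any() for i in range(len(y)))


def test_no_plant_patches_is_an_error():
    img, mask = _image_with_plant_patches(0, 4)
    with pytest.raises(ValueError):
        prepare_balanced_patches([img], [mask], seed=0, tile=32)


def test_patch_values_normalized_to_unit_range():
    img, mask = _image_with_plant_patches(2, 2)
    img[:] = 255
    x, y = prepare_balanced_patches([img], [mask], seed=0, tile=32)
    assert x.max() == pytest.approx(1.0)
    assert set(np.unique(y)) <= {0.0, 1.0}


@pytest.mark.parametrize("n,expected_train", [(100, 85), (20, 17)])
def test_split_sizes(n, expected_train):
    tr, va = split_train_val(list(range(n)), 0.85, seed=0)
    assert len(tr) == expected_train
    assert len(va) == n - expected_train
    assert sorted(tr + va) == list(range(n))


def test_split_is_deterministic_and_guards_small_n():
    a = split_train_val(list(range(40)), 0.85, seed=9)
    b = split_train_val(list(range(40)), 0.85, seed=9)
    assert a == b
    with pytest.raises(ValueError):
        split_train_val([1], 0.85, seed=0)


def _tiny_dataset(n, seed=0, tile=32):
    """Green blobs on dark background at 32x32: quick to learn."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n, tile, tile, 3), dtype=np.float32)
    y = np.zeros((n, tile, tile, 1), dtype=np.float32)
    x[..., 2] = 0.3
    for i in range(n):
        r, c = rng.integers(8, 24, 2)
        rr, cc = np.mgrid[0:tile, 0:tile]
        blob = (rr - r) ** 2 + (cc - c) ** 2 < 30
        x[i, blob] = (0.1, 0.8, 0.1)
        y[i, blob, 0] = 1.0
    return x, y


def test_training_reduces_loss_and_is_reproducible():
    x, y = _tiny_dataset(12)
    xv, yv = _tiny_dataset(4, seed=99)
    cfg = TrainingConfig(epochs=4, batch_size=4, seed=7)
    histories = []
    for _ in range(2):
        model, _ = build_unet(TINY, seed=7)
        model, hist = train(model, (x, y), (xv, yv), cfg)
        histories.append(hist)
    h0, h1 = histories
    assert h0.train_loss == h1.train_loss  # bit-reproducible run
    assert h0.val_loss == h1.val_loss
    assert h0.train_loss[-1] < h0.train_loss[0]
    assert len(h0.train_loss) == 4


def test_learning_rate_sequence_follows_plateau_rule():
    x, y = _tiny_dataset(8)
    cfg = TrainingConfig(
        epochs=10, batch_size=4, seed=3, plateau_patience=2, plateau_factor=0.2
    )
    model, _ = build_unet(TINY, seed=3)
    _, hist = train(model, (x, y), (x, y), cfg)
    lrs = hist.learning_rate
    assert lrs[0] == pytest.approx(1e-3)
    for prev, cur in zip(lrs, lrs[1:]):
        assert cur == pytest.approx(prev) or cur == pytest.approx(
            max(prev * 0.2, cfg.min_learning_rate)
        )
    assert all(b <= a * (1 + 1e-9) for a, b in zip(lrs, lrs[1:]))  # non-increasing


def test_plateau_reduction_hits_expected_value():
    """0.001 * 0.2 = 2e-4 after a patience-long stall."""
    assert 0.001 * 0.2 == pytest.approx(2e-4)
    x, y = _tiny_dataset(4)
    # constant validation set of zeros cannot improve forever; with
    # patience 1 the rate must drop at least once over 6 epochs
    cfg = TrainingConfig(epochs=6, batch_size=4, seed=1, plateau_patience=1)
    model, _ = build_unet(TINY, seed=1)
    _, hist = train(model, (x, y), (x, y), cfg)
    assert min(hist.learning_rate) < 1e-3 or hist.val_loss[-1] < hist.val_loss[0]


def test_invalid_training_configs_rejected():
    for bad in (
        dict(split_ratio=0.0),
        dict(split_ratio=1.0),
        dict(plateau_factor=1.5),
        dict(epochs=0),
    ):
        with pytest.raises(ValueError):
            TrainingConfig(**bad).validate()
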