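"""Dataset preparation and the U-net training loop.

Training follows the protocol used for the shoot models: images and masks
are padded and cut into non-overlapping 256 x 256 patches, patch classes
("plant": at least one plant pixel; "background": none) are balanced by
seeded sub-sampling of the majority class, intensities are scaled to
[0, 1], and the network is optimized with Adam on pixel-averaged binary
cross-entropy.  Kernel weights start from N(0, 0.05^2); the learning rate
starts at 1e-3 and is multiplied by 0.2 whenever the validation loss has
not improved for 5 consecutive epochs (floored at 1e-6).

The train/validation split is applied at the image level so patches from
one photograph never leak across the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .metrics import binary_cross_entropy, dice
from .nn import Adam
from .tiling import tile_image
from .unet import ModelConfig, UNet, build_unet

_EPS = 1e-7


@dataclass
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 128
    initial_learning_rate: float = 1e-3
    plateau_factor: float = 0.2
    plateau_patience: int = 5
    min_learning_rate: float = 1e-6
    split_ratio: float = 0.85
    init_sd: float = 0.05
    seed: int = 0
    probability_threshold: float = 0.6
    min_cluster_size: int = 0
    # random-restart guard against unlucky initial draws in short-budget
    # runs: if training Dice is still below ``restart_dice_floor`` after
    # ``restart_patience`` epochs, reinitialize from the next draw of the
    # same weight distribution (optimizer state reset, epoch budget and
    # learning-rate schedule unchanged)
    restart_patience: int = 4
    restart_dice_floor: float = 0.02
    max_restarts: int = 3

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch training curves."""

    train_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_dice": self.train_dice,
                "val_loss": self.val_loss,
                "val_dice": self.val_dice,
                "learning_rate": self.learning_rate,
            }
        )


def prepare_balanced_patches(images, masks, seed=0, tile=256):
    """Tile image/mask pairs and balance plant vs background patches.

    A patch is "plant" when its mask contains at least one plant pixel.
    The majority class is sub-sampled (seeded) to the minority count; when
    one class is absent the other is kept in full (a dataset with no plant
    patches at all is untrainable and raises).  Returns ``(x, y)`` with
    ``x`` in [0, 1] float32 (n, t, t, 3) and ``y`` float32 (n, t, t, 1).
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    plant, background = [], []
    for img, msk in zip(images, masks):
        if img.shape[:2] != msk.shape[:2]:
            raise ValueError("image/mask size mismatch")
        gi = tile_image(np.asarray(img), tile)
        gm = tile_image((np.asarray(msk) > 0).astype(np.uint8), tile)
        for pi, pm in zip(gi.patches, gm.patches):
            (plant if pm.any() else background).append((pi, pm))
    if not plant:
        raise ValueError("no plant patches in the dataset; nothing to learn")
    rng = np.random.default_rng(seed)
    if background:
        n = min(len(plant), len(background))
        plant = [plant[i] for i in rng.choice(len(plant), n, replace=False)]
        background = [background[i] for i in rng.choice(len(background), n, replace=False)]
    chosen = plant + background
    x = np.stack([p[0] for p in chosen]).astype(np.float32) / 255.0
    y = np.stack([p[1] for p in chosen]).astype(np.float32)[..., None]
    return x, y


def split_train_val(items, split_ratio=0.85, seed=0):
    """Seeded disjoint, exhaustive split; train size = round(ratio * N)."""
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    if not 0 < split_ratio < 1:
        raise ValueError("split_ratio must be in (0, 1)")
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(round(split_ratio * n))
    n_train = min(max(n_train, 1), n - 1)  # keep both sides non-empty
    train_idx = sorted(idx[:n_train].tolist())
    val_idx = sorted(idx[n_train:].tolist())
    return [items[i] for i in train_idx], [items[i] for i in val_idx]


def _epoch_metrics(model, x, y, threshold, batch_size=8):
    p = model.predict(x, batch_size=batch_size)
    loss = binary_cross_entropy(p, y)
    dices = [
        dice(p[i, :, :, 0] >= threshold, y[i, :, :, 0] > 0.5) for i in range(len(x))
    ]
    return loss, float(np.mean(dices))


def train(model: UNet, train_set, val_set, config: TrainingConfig):
    """Optimize ``model`` on ``train_set`` = (x, y); returns the model and
    its :class:`TrainingHistory`.  Fully reproducible for a fixed seed."""
    config.validate()
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.trainable_layers(), lr=config.initial_learning_rate)
    history = TrainingHistory()
    lr = config.initial_learning_rate
    best_val = np.inf
    stale = 0
    restarts_left = config.max_restarts
    last_restart_epoch = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        losses, weights = [], []
        inter = 0.0
        sums = 0.0
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            p = model.forward(xb, training=True)
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            loss = float(
                -np.mean(yb * np.log(pc) + (1.0 - yb) * np.log(1.0 - pc))
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "check input scaling and learning rate"
                )
            losses.append(loss)
            weights.append(len(sel))
            pb = p >= config.probability_threshold
            gb = yb > 0.5
            inter += 2.0 * float((pb & gb).sum())
            sums += float(pb.sum()) + float(gb.sum())
            # gradient of mean BCE at the logit level: (p - y) / n_pixels
            model.backward((p - yb) / p.size, from_logits=True)
            opt.lr = lr
            opt.step()
        train_loss = float(np.average(losses, weights=weights))
        train_dice = inter / sums if sums else 1.0
        val_loss, val_dice = _epoch_metrics(
            model, x_va, y_va, config.probability_threshold
        )
        history.train_loss.append(train_loss)
        history.train_dice.append(train_dice)
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        history.learning_rate.append(lr)
        logger.info(
            "epoch=%d train_loss=%.4f train_dice=%.4f val_loss=%.4f "
            "val_dice=%.4f lr=%.2e",
            epoch + 1, train_loss, train_dice, val_loss, val_dice, lr,
        )
        # random restart: with few optimizer steps per run, some initial
        # draws never leave the base-rate regime; reinitialization is the
        # standard remedy and costs no extra epochs
        if (
            restarts_left > 0
            and epoch + 1 - last_restart_epoch >= config.restart_patience
            and train_dice < config.restart_dice_floor
        ):
            model.init_weights(int(rng.integers(0, 2**31 - 1)), sd=config.init_sd)
            opt = Adam(model.trainable_layers(), lr=lr)
            best_val = np.inf
            stale = 0
            restarts_left -= 1
            last_restart_epoch = epoch + 1
            continue
        # reduce-on-plateau schedule driven by validation loss
        if val_loss < best_val - 1e-8:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.plateau_patience:
                lr = max(lr * config.plateau_factor, config.min_learning_rate)
                stale = 0
    return model, history


def run_training(
    images,
    masks,
    model_config: ModelConfig | None = None,
    training_config: TrainingConfig | None = None,
):
    """Image-level split, patch preparation, and training in one call.

    Returns ``(model, history, (val_images, val_masks))`` -- the held-out
    full images are handed back so callers can evaluate whole-image
    predictions against masks the optimizer never saw.
    """
    tcfg = training_config or TrainingConfig()
    tcfg.validate()
    tile = (model_config or ModelConfig()).patch_size
    pairs = list(zip(images, masks))
    train_pairs, val_pairs = split_train_val(pairs, tcfg.split_ratio, tcfg.seed)
    x_tr, y_tr = prepare_balanced_patches(
        [p[0] for p in train_pairs], [p[1] for p in train_pairs], seed=tcfg.seed,
        tile=tile,
    )
    # validation patches are kept unbalanced: they estimate deployment
    # performance rather than the training objective
    x_va, y_va = _all_patches(
        [p[0] for p in val_pairs], [p[1] for p in val_pairs], tile=tile
    )
    model, _ = build_unet(model_config, seed=tcfg.seed)
    model.init_weights(tcfg.seed, sd=tcfg.init_sd)
    model, history = train(model, (x_tr, y_tr), (x_va, y_va), tcfg)
    return model, history, ([p[0] for p in val_pairs], [p[1] for p in val_pairs])


def _all_patches(images, masks, tile=256):
    xs, ys = [], []
    for img, msk in zip(images, masks):
        gi = tile_image(np.asarray(img), tile)
        gm = tile_image((np.asarray(msk) > 0).astype(np.uint8), tile)
        xs.append(gi.patches)
        ys.append(gm.patches)
    x = np.concatenate(xs).astype(np.float32) / 255.0
    y = np.concatenate(ys).astype(np.float32)[..., None]
    return x, y
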