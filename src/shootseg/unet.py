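"""Encoder-decoder U-net for patch-level shoot segmentation.

The network operates on 256 x 256 patches: three encoder blocks (two 7x7
conv -> batch-norm -> ReLU layers each, followed by 2x2 max pooling) with
16/32/64 filters, a 128-filter bridge block without pooling, and a decoder
that mirrors the encoder using 3x3 stride-2 transpose convolutions.  Each
transpose convolution doubles the spatial size and halves the channel
depth; its output is concatenated with the same-resolution encoder output
before two further conv-BN-ReLU layers.  A 1x1 convolution with logistic
activation produces the per-pixel plant probability.  Batch normalization
follows every plain convolution; transpose convolutions and the output
head carry no normalization, and there is no dropout.

With the default configuration the network has exactly 2,484,721 trainable
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .nn import Adam, BatchNorm2D, Conv2D, ConvTranspose2D, MaxPool2D, ReLU, Sigmoid


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``depth`` counts pooling stages (the bridge is separate), so a
    ``patch_size`` input is reduced to ``patch_size / 2**depth`` at the
    bridge -- 32 x 32 with the defaults.
    """

    patch_size: int = 256
    kernel_size: int = 7
    transpose_kernel_size: int = 3
    transpose_stride: int = 2
    depth: int = 3
    encoder_filters: list[int] = field(default_factory=lambda: [16, 32, 64])
    bridge_filters: int = 128
    input_channels: int = 3
    output_channels: int = 1

    def validate(self) -> None:
        if len(self.encoder_filters) != self.depth:
            raise ValueError("encoder_filters length must equal depth")
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError("patch_size must be divisible by 2**depth")
        counts = [
            self.patch_size,
            self.kernel_size,
            self.bridge_filters,
            self.input_channels,
            self.output_channels,
            *self.encoder_filters,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all size/channel counts must be positive")
        if self.transpose_kernel_size != 3 or self.transpose_stride != 2:
            raise ValueError("decoder supports 3x3 stride-2 transpose convolutions")


def _conv_params(k: int, c_in: int, c_out: int) -> int:
    return (k * k * c_in + 1) * c_out


def network_spec(config: ModelConfig) -> list[dict]:
    """Per-layer description (shapes and trainable-parameter counts).

    Derived purely from the configuration by shape arithmetic, independent
    of the array-backed model, so the two can be cross-checked.
    """
    config.validate()
    spec: list[dict] = []
    k = config.kernel_size
    size = config.patch_size
    c = config.input_channels

    def add(name, kind, size, channels, params):
        spec.append(
            {
                "name": name,
                "kind": kind,
                "output_size": [size, size],
                "channels": channels,
                "trainable_params": params,
            }
        )

    def conv_block(prefix, size, c_in, c_out):
        c = c_in
        for j in (1, 2):
            add(f"{prefix}_conv{j}", "conv", size, c_out, _conv_params(k, c, c_out))
            add(f"{prefix}_bn{j}", "batchnorm", size, c_out, 2 * c_out)
            add(f"{prefix}_relu{j}", "relu", size, c_out, 0)
            c = c_out
        return c_out

    for i, f in enumerate(config.encoder_filters, start=1):
        c = conv_block(f"enc{i}", size, c, f)
        size //= 2
        add(f"enc{i}_pool", "maxpool", size, c, 0)
    c = conv_block("bridge", size, c, config.bridge_filters)
    for i in range(config.depth, 0, -1):
        f = config.encoder_filters[i - 1]
        size *= 2
        add(f"dec{i}_up", "conv_transpose", size, f, _conv_params(3, c, f))
        add(f"dec{i}_concat", "concat", size, 2 * f, 0)
        c = conv_block(f"dec{i}", size, 2 * f, f)
    add(
        "head_conv",
        "conv",
        size,
        config.output_channels,
        _conv_params(1, c, config.output_channels),
    )
    add("head_sigmoid", "sigmoid", size, config.output_channels, 0)
    return spec


def count_trainable_parameters(spec: list[dict]) -> int:
    """Sum of per-layer trainable parameters in a network spec."""
    return int(sum(layer["trainable_params"] for layer in spec))


class UNet:
    """Array-backed U-net with explicit forward/backward passes."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        k = config.kernel_size
        c = config.input_channels
        self.encoder: list[list] = []
        self.pools: list[MaxPool2D] = []
        for i, f in enumerate(config.encoder_filters, start=1):
            self.encoder.append(self._conv_block(f"enc{i}", c, f, k))
            self.pools.append(MaxPool2D())
            c = f
        self.bridge = self._conv_block("bridge", c, config.bridge_filters, k)
        c = config.bridge_filters
        self.ups: list[ConvTranspose2D] = []
        self.decoder: list[list] = []
        for i in range(config.depth, 0, -1):
            f = config.encoder_filters[i - 1]
            self.ups.append(ConvTranspose2D(c, f, name=f"dec{i}_up"))
            self.decoder.append(self._conv_block(f"dec{i}", 2 * f, f, k))
            c = f
        self.head = Conv2D(c, config.output_channels, 1, name="head_conv")
        self.sigmoid = Sigmoid()

    @staticmethod
    def _conv_block(prefix, c_in, c_out, k):
        return [
            Conv2D(c_in, c_out, k, name=f"{prefix}_conv1"),
            BatchNorm2D(c_out, name=f"{prefix}_bn1"),
            ReLU(),
            Conv2D(c_out, c_out, k, name=f"{prefix}_conv2"),
            BatchNorm2D(c_out, name=f"{prefix}_bn2"),
            ReLU(),
        ]

    # -- plumbing ---------------------------------------------------------
    def layers(self):
        for block in self.encoder:
            yield from block
        yield from self.pools
        yield from self.bridge
        for up, block in zip(self.ups, self.decoder):
            yield up
            yield from block
        yield self.head
        yield self.sigmoid

    def trainable_layers(self):
        return [l for l in self.layers() if l.params]

    def n_trainable(self) -> int:
        return sum(l.n_trainable() for l in self.trainable_layers())

    def init_weights(self, seed: int, sd: float = 0.05) -> None:
        """Gaussian N(0, sd^2) kernels, zero biases, identity batch-norm."""
        rng = np.random.default_rng(seed)
        for l in self.layers():
            if isinstance(l, (Conv2D, ConvTranspose2D)):
                l.init_weights(rng, sd)
            elif isinstance(l, BatchNorm2D):
                l.params["gamma"][...] = 1.0
                l.params["beta"][...] = 0.0
                l.running_mean[...] = 0.0
                l.running_var[...] = 1.0

    # -- forward / backward ----------------------------------------------
    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for block, pool in zip(self.encoder, self.pools):
            for l in block:
                x = l.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        for l in self.bridge:
            x = l.forward(x, training)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.decoder, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(x.shape[3])
            x = np.concatenate([x, skip], axis=3)
            for l in block:
                x = l.forward(x, training)
        x = self.head.forward(x, training)
        return self.sigmoid.forward(x, training)

    def backward(self, dy, from_logits=False):
        """Backpropagate ``dy``; with ``from_logits`` the final sigmoid is
        skipped (the caller supplies the gradient at the logit level, the
        numerically stable route for cross-entropy training)."""
        if not from_logits:
            dy = self.sigmoid.backward(dy)
        dy = self.head.backward(dy)
        skip_grads = []
        for up, block, c_up in zip(
            reversed(self.ups), reversed(self.decoder), reversed(self._skip_channels)
        ):
            for l in reversed(block):
                dy = l.backward(dy)
            skip_grads.append(dy[..., c_up:])
            dy = up.backward(np.ascontiguousarray(dy[..., :c_up]))
        for l in reversed(self.bridge):
            dy = l.backward(dy)
        for block, pool, dskip in zip(
            reversed(self.encoder), reversed(self.pools), reversed(skip_grads)
        ):
            dy = pool.backward(dy) + dskip
            for l in reversed(block):
                dy = l.backward(dy)
        return dy

    def predict(self, x, batch_size=8):
        """Inference-mode forward pass in memory-bounded chunks."""
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            for i, l in enumerate(self.layers()):
                if not l.params:
                    continue
                g = f.create_group(f"layer_{i:03d}_{l.name or type(l).__name__}")
                for k, v in l.params.items():
                    g.create_dataset(k, data=v)
                if isinstance(l, BatchNorm2D):
                    g.create_dataset("running_mean", data=l.running_mean)
                    g.create_dataset("running_var", data=l.running_var)

    @classmethod
    def load(cls, path) -> "UNet":
        with h5py.File(path, "r") as f:
            cfg = json.loads(f.attrs["config"])
            model = cls(ModelConfig(**cfg))
            groups = sorted(f.keys())
            it = iter(groups)
            for i, l in enumerate(model.layers()):
                if not l.params:
                    continue
                g = f[next(it)]
                for k in l.params:
                    l.params[k] = g[k][()]
                if isinstance(l, BatchNorm2D):
                    l.running_mean = g["running_mean"][()]
                    l.running_var = g["running_var"][()]
        return model


def build_unet(config: ModelConfig | None = None, seed: int = 0):
    """Construct and initialize the U-net; returns ``(model, spec)``."""
    config = config or ModelConfig()
    spec = network_spec(config)
    model = UNet(config)
    model.init_weights(seed)
    assert model.n_trainable() == count_trainable_parameters(spec)
    return model, spec
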