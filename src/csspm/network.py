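"""The reference spectrogram classifier f_theta.

Three convolution blocks — each batch-normalization, convolution with ReLU,
max-pooling — followed by two fully connected layers with dropout, mapping a
``(channels, freq, time)`` magnitude STFT image to a 2-class probability
vector (index 0 interictal, index 1 preictal).

The first block is described in the source architecture as a 3D convolution
with ``16n x 5 x 5`` kernels and stride ``1 x 2 x 2`` where ``n`` is the EEG
channel count: the kernel spans the full channel axis with stride 1, so the
channel axis collapses to length 1 and the block is mathematically a 2D
convolution with ``n`` input channels and ``16n`` feature maps — it is built
as such, and the "reshape to 2D" step becomes the identity.  Blocks 2 and 3
are plain 2D convolutions with 32 and 64 kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    MaxPool2d,
    ReLU,
    Sequential,
    Sigmoid,
    Softmax,
)

__all__ = ["ModelConfig", "build_model", "forward"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference setup: block 1 has ``16 * n_channels``
    5x5 kernels at stride 2x2 with 2x2 pooling; blocks 2-3 have 32 and 64
    3x3 kernels at stride 1 with 2x2 pooling; then FC(256, sigmoid) and
    FC(2, softmax), each with dropout 0.5 on its input.  Convolution padding
    is "same" by default (the source is silent; "same" lets reduced
    desk-scale spectrograms survive three pooling stages) and configurable.
    """

    n_channels: int = 4
    block1_kernels_per_channel: int = 16
    block1_kernel: tuple[int, int] = (5, 5)
    block1_stride: tuple[int, int] = (2, 2)
    block1_pool: tuple[int, int] = (2, 2)
    block2_kernels: int = 32
    block3_kernels: int = 64
    conv23_kernel: tuple[int, int] = (3, 3)
    conv23_stride: tuple[int, int] = (1, 1)
    pool: tuple[int, int] = (2, 2)
    fc1_units: int = 256
    n_classes: int = 2
    dropout_rate: float = 0.5
    padding: str = "same"
    bn_momentum: float = 0.99
    dtype: str = "float64"

    @property
    def block1_kernels(self) -> int:
        return self.block1_kernels_per_channel * self.n_channels


def build_model(
    cfg: ModelConfig,
    input_shape: tuple[int, int, int],
    rng: np.random.Generator | None = None,
) -> Sequential:
    """Build the classifier for inputs of ``(channels, freq, time)`` shape.

    Weights are Glorot-uniform from ``rng``.  Raises ``ValueError`` with the
    offending stage if the input is too small to survive the three
    convolution/pooling stages.
    """
    n_ch, h, w = input_shape
    if n_ch != cfg.n_channels:
        raise ValueError(
            f"input has {n_ch} channels but ModelConfig.n_channels={cfg.n_channels}"
        )
    rng = rng or np.random.default_rng()
    dtype = np.dtype(cfg.dtype).type

    layers: list = []

    def track(conv: Conv2d, pool: MaxPool2d, h: int, w: int, block: int):
        h, w = conv.output_shape(h, w)
        if h < 1 or w < 1:
            raise ValueError(f"block {block}: convolution output collapses to {h}x{w}")
        h, w = pool.output_shape(h, w)
        if h < 1 or w < 1:
            raise ValueError(f"block {block}: pooled output collapses to {h}x{w}")
        return h, w

    conv1 = Conv2d(cfg.n_channels, cfg.block1_kernels, cfg.block1_kernel,
                   cfg.block1_stride, cfg.padding, rng, dtype)
    pool1 = MaxPool2d(cfg.block1_pool)
    h, w = track(conv1, pool1, h, w, 1)
    layers += [BatchNorm(cfg.n_channels, cfg.bn_momentum, dtype=dtype),
               conv1, ReLU(), pool1]

    conv2 = Conv2d(cfg.block1_kernels, cfg.block2_kernels, cfg.conv23_kernel,
                   cfg.conv23_stride, cfg.padding, rng, dtype)
    pool2 = MaxPool2d(cfg.pool)
    h, w = track(conv2, pool2, h, w, 2)
    layers += [BatchNorm(cfg.block1_kernels, cfg.bn_momentum, dtype=dtype),
               conv2, ReLU(), pool2]

    conv3 = Conv2d(cfg.block2_kernels, cfg.block3_kernels, cfg.conv23_kernel,
                   cfg.conv23_stride, cfg.padding, rng, dtype)
    pool3 = MaxPool2d(cfg.pool)
    h, w = track(conv3, pool3, h, w, 3)
    layers += [BatchNorm(cfg.block2_kernels, cfg.bn_momentum, dtype=dtype),
               conv3, ReLU(), pool3]

    flat = cfg.block3_kernels * h * w
    layers += [
        Flatten(),
        Dropout(cfg.dropout_rate),
        Dense(flat, cfg.fc1_units, rng, dtype),
        Sigmoid(),
        Dropout(cfg.dropout_rate),
        Dense(cfg.fc1_units, cfg.n_classes, rng, dtype),
        Softmax(),
    ]
    return Sequential(layers)


def forward(
    net: Sequential,
    x: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Batch of spectrograms -> batch of class-probability 2-vectors z_i.

    Training mode applies dropout from ``rng`` and batch statistics;
    evaluation mode is deterministic.
    """
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    return net.forward(x, training=training, rng=rng)


def make_optimizer(net: Sequential, beta1: float = 0.9, beta2: float = 0.999) -> Adam:
    return Adam(net, beta1=beta1, beta2=beta2)
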