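"""Layers and optimizer for the spectrogram CNN.

Conventions: inputs are ``(N, C, H, W)`` for spatial layers and ``(N, D)``
after flattening.  Every layer exposes ``forward(x, training, rng)`` and
``backward(grad_out) -> grad_in``; trainable arrays live in ``layer.params``
(name -> array) with matching ``layer.grads``.  ``forward`` caches whatever
``backward`` needs; a layer is therefore not reentrant across batches, which
is all the trainer requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "BatchNorm", "Conv2d", "ReLU", "MaxPool2d", "Dropout",
    "Flatten", "Dense", "Sigmoid", "Softmax", "Sequential", "Adam",
]


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training: bool, rng=None):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, spatial) axes.

    Training mode normalizes with biased batch statistics and updates running
    statistics with the given momentum; evaluation mode uses the frozen
    running statistics.
    """

    def __init__(self, n_features: int, momentum: float = 0.99,
                 eps: float = 1e-5, dtype=np.float64) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)

    def _shape(self, x):
        # broadcast shape putting features on axis 1
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training: bool, rng=None):
        axes = (0,) + tuple(range(2, x.ndim))
        s = self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(s)) * inv.reshape(s)
        self._cache = (xhat, inv, axes, s, training)
        return self.params["gamma"].reshape(s) * xhat + self.params["beta"].reshape(s)

    def backward(self, g):
        xhat, inv, axes, s, training = self._cache
        self.grads["gamma"][...] = (g * xhat).sum(axis=axes)
        self.grads["beta"][...] = g.sum(axis=axes)
        gxhat = g * self.params["gamma"].reshape(s)
        if not training:
            return gxhat * inv.reshape(s)
        m = np.prod([xhat.shape[a] for a in axes])
        gx = (gxhat - gxhat.mean(axis=axes).reshape(s)
              - xhat * (gxhat * xhat).mean(axis=axes).reshape(s)) * inv.reshape(s)
        return gx


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


class Conv2d(Layer):
    """2D convolution (cross-correlation) via im2col, with bias.

    ``padding`` is "same" (zero-padded so the output size is ceil(in/stride))
    or "valid".  Glorot-uniform initialization.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 stride: tuple[int, int] = (1, 1), padding: str = "same",
                 rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        self.stride = stride
        self.kernel = kernel
        self.padding = padding
        kh, kw = kernel
        fan_in, fan_out = in_ch * kh * kw, out_ch * kh * kw
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        rng = rng or np.random.default_rng()
        self.params = {
            "W": rng.uniform(-limit, limit, size=(out_ch, in_ch, kh, kw)).astype(dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        sh, sw = self.stride
        if self.padding == "same":
            return -(-h // sh), -(-w // sw)
        return (h - kh) // sh + 1, (w - kw) // sw + 1

    def forward(self, x, training: bool, rng=None):
        kh, kw = self.kernel
        sh, sw = self.stride
        if self.padding == "same":
            ph = _same_pad(x.shape[2], kh, sh)
            pw = _same_pad(x.shape[3], kw, sw)
            xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        else:
            xp = x
        n, c, hp, wp = xp.shape
        oh, ow = (hp - kh) // sh + 1, (wp - kw) // sw + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} too small for kernel {self.kernel}"
            )
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
        # (n, c, oh, ow, kh, kw) -> (n, oh*ow, c*kh*kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
        W = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ W.T + self.params["b"]
        self._cache = (cols, xp.shape, x.shape, oh, ow)
        return out.transpose(0, 2, 1).reshape(n, -1, oh, ow)

    def backward(self, g):
        cols, padded_shape, in_shape, oh, ow = self._cache
        n = g.shape[0]
        oc = g.shape[1]
        kh, kw = self.kernel
        sh, sw = self.stride
        gmat = g.reshape(n, oc, oh * ow).transpose(0, 2, 1)  # (n, P, oc)
        W = self.params["W"].reshape(oc, -1)
        self.grads["W"][...] = np.tensordot(gmat, cols, axes=([0, 1], [0, 1])).reshape(
            self.params["W"].shape
        )
        self.grads["b"][...] = gmat.sum(axis=(0, 1))
        gcols = gmat @ W  # (n, P, c*kh*kw)
        c = padded_shape[1]
        gwin = gcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros(padded_shape, dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += gwin[..., i, j]
        if self.padding == "same":
            ph0 = (padded_shape[2] - in_shape[2])
            pw0 = (padded_shape[3] - in_shape[3])
            top, left = ph0 // 2, pw0 // 2
            gx = gx[:, :, top : top + in_shape[2], left : left + in_shape[3]]
        return gx


class ReLU(Layer):
    def forward(self, x, training: bool, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2d(Layer):
    """Non-overlapping max pooling; trailing rows/cols not filling a window
    are cropped (floor semantics)."""

    def __init__(self, size: tuple[int, int] = (2, 2)) -> None:
        super().__init__()
        self.size = size

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        return h // self.size[0], w // self.size[1]

    def forward(self, x, training: bool, rng=None):
        ph, pw = self.size
        n, c, h, w = x.shape
        oh, ow = h // ph, w // pw
        if oh < 1 or ow < 1:
            raise ValueError(f"input {h}x{w} too small for {ph}x{pw} pooling")
        xc = x[:, :, : oh * ph, : ow * pw]
        tiles = xc.reshape(n, c, oh, ph, ow, pw).transpose(0, 1, 2, 4, 3, 5)
        flat = tiles.reshape(n, c, oh, ow, ph * pw)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        in_shape, idx = self._cache
        ph, pw = self.size
        n, c, oh, ow = g.shape
        gflat = np.zeros((n, c, oh, ow, ph * pw), dtype=g.dtype)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros(in_shape, dtype=g.dtype)
        tiles = gflat.reshape(n, c, oh, ow, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        gx[:, :, : oh * ph, : ow * pw] = tiles.reshape(n, c, oh * ph, ow * pw)
        return gx


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity otherwise."""

    def __init__(self, rate: float = 0.5) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training: bool, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, training: bool, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        rng = rng or np.random.default_rng()
        self.params = {
            "W": rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training: bool, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"][...] = self._x.T @ g
        self.grads["b"][...] = g.sum(axis=0)
        return g @ self.params["W"].T


class Sigmoid(Layer):
    def forward(self, x, training: bool, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Softmax(Layer):
    def forward(self, x, training: bool, rng=None):
        e = np.exp(x - x.max(axis=1, keepdims=True))
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, g):
        y = self._y
        return y * (g - (g * y).sum(axis=1, keepdims=True))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, training: bool, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        """Yield (layer, name, array, grad) for every trainable array."""
        for layer in self.layers:
            for name, arr in layer.params.items():
                yield layer, name, arr, layer.grads[name]

    def param_count(self) -> int:
        return sum(arr.size for _, _, arr, _ in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for name in sorted(layer.params):
                out.append(layer.params[name].copy())
            if isinstance(layer, BatchNorm):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for name in sorted(layer.params):
                layer.params[name][...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)


class Adam:
    """Adam optimizer over a :class:`Sequential`'s parameters."""

    def __init__(self, net: Sequential, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(arr) for _, _, arr, _ in net.parameters()]
        self.v = [np.zeros_like(arr) for _, _, arr, _ in net.parameters()]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (_, _, arr, grad) in enumerate(self.net.parameters()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            arr -= lr * mhat / (np.sqrt(vhat) + self.eps)
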