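"""Minimal numpy neural-network engine for the weighted CNN.

Implements exactly the layers the WCNN needs — valid 2-D convolution, batch
normalization, ReLU, dropout, the parameter-free KWC channel-weighting layer,
flatten and dense — with forward and backward passes, plus Adam with a
staircase exponential learning-rate schedule.  Tensors are NCHW
(batch, channels, height, width); the height axis indexes MFCC dimensions and
the width axis indexes frames.

The KWC layer rescales every channel by its own global average,

    w_c = mean_ij F_c(i, j),        F'_c = w_c * F_c,

so channels with high mean activation are amplified and near-silent channels
are suppressed.  It has no parameters; gradients flow through both factors of
the product (d F'/d F picks up both the w_c term and the 1/(H*W) term from the
pooled mean), which makes the layer a trainable-through attention mechanism
at zero parameter cost.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "KWC",
    "Flatten",
    "Dense",
    "kwc_forward",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "sigmoid_binary_cross_entropy",
]


def kwc_forward(F: np.ndarray) -> np.ndarray:
    """Key-weighting calculation on a single (C, H, W) feature tensor.

    Each channel is multiplied by its global average activation.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3:
        raise ValueError("expected a (C, H, W) tensor")
    w = F.mean(axis=(1, 2), keepdims=True)
    return w * F


class Layer:
    """Base layer: forward caches what backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv2D(Layer):
    """Valid (unpadded) convolution, square stride, NCHW layout."""

    def __init__(self, in_channels: int, out_channels: int, kernel=(2, 2), stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = stride
        rng = rng or np.random.default_rng()
        fan_in = in_channels * self.kernel[0] * self.kernel[1]
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, *self.kernel))
        b = np.zeros(out_channels)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training=False):
        w, b = self.params
        kh, kw = self.kernel
        s = self.stride
        n, c, h, wd = x.shape
        if h < kh or wd < kw:
            raise ValueError("kernel larger than input feature map")
        view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        view = view[:, :, ::s, ::s, :, :]       # (N, Cin, Ho, Wo, kh, kw)
        self._x_shape = x.shape
        self._view = view
        out = np.einsum("nchwij,fcij->nfhw", view, w, optimize=True)
        return out + b[None, :, None, None]

    def backward(self, dout):
        w, _ = self.params
        kh, kw = self.kernel
        s = self.stride
        n, f, ho, wo = dout.shape
        self.grads[0][...] = np.einsum("nfhw,nchwij->fcij", dout, self._view, optimize=True)
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        dx = np.zeros(self._x_shape)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.einsum(
                    "nfhw,fc->nchw", dout, w[:, :, i, j], optimize=True
                )
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics (NCHW)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        gamma = np.ones(channels)
        beta = np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        self._training = training
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        gamma, beta = self.params
        return gamma[None, :, None, None] * self._xhat + beta[None, :, None, None]

    def backward(self, dout):
        gamma, _ = self.params
        axes = (0, 2, 3)
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        inv_std = 1.0 / self._std
        if not self._training:
            return dout * (gamma * inv_std)[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * gamma[None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        )
        return term * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float = 0.3, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class KWC(Layer):
    """Channel weighting by global average pooling; zero parameters."""

    def forward(self, x, training=False):
        self._x = x
        self._w = x.mean(axis=(2, 3), keepdims=True)
        return self._w * x

    def backward(self, dout):
        # product rule: out = w(x) * x with w = mean(x) per channel
        hw = self._x.shape[2] * self._x.shape[3]
        direct = self._w * dout
        pooled = (dout * self._x).sum(axis=(2, 3), keepdims=True) / hw
        return direct + pooled


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_units: int, out_units: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_units), size=(in_units, out_units))
        b = np.zeros(out_units)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training=False):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.maximum(p, 1e-12))) / n
    return loss, (p - onehot) / n


def sigmoid_binary_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on a single sigmoid logit per sample."""
    z = logits.ravel()
    t = targets.ravel()
    p = 1.0 / (1.0 + np.exp(-z))
    loss = -np.mean(t * np.log(np.maximum(p, 1e-12)) + (1 - t) * np.log(np.maximum(1 - p, 1e-12)))
    return loss, ((p - t) / z.size).reshape(logits.shape)


class Network:
    """An ordered layer stack with forward/backward and parameter access."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self, include_batchnorm: bool = False) -> int:
        total = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm) and not include_batchnorm:
                continue
            total += layer.n_params()
        return total

    def activation_and_gradient(self, x: np.ndarray, dlogits: np.ndarray, layer_index: int):
        """Forward activation at ``layer_index`` and the gradient of a scalar
        (encoded by ``dlogits`` at the output) with respect to it.

        Used by Grad-CAM: run in evaluation mode, backpropagate from the
        output logits down to — but not through — the indexed layer.
        """
        act = x
        acts = []
        for layer in self.layers:
            act = layer.forward(act, training=False)
            acts.append(act)
        dout = dlogits
        for layer in reversed(self.layers[layer_index + 1 :]):
            dout = layer.backward(dout)
        return acts[layer_index], dout


class Adam:
    """Adam with a staircase exponential learning-rate schedule.

    The step size at iteration t is
    ``lr * decay_rate ** floor(t / decay_steps)`` — with the defaults, the
    learning rate drops by 5% every 10,000 iterations.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, decay_rate: float = 0.95,
                 decay_steps: int = 10_000, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.decay_rate = decay_rate
        self.decay_steps = decay_steps
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def current_lr(self) -> float:
        return self.lr * self.decay_rate ** (self.t // self.decay_steps)

    def step(self, grads: list[np.ndarray]) -> None:
        lr_t = self.current_lr()
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr_t * mhat / (np.sqrt(vhat) + self.eps)
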