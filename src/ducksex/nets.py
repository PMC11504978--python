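"""Minimal feed-forward/convolutional network engine with manual backprop.

Supports exactly what the three duckling-sex classifiers need: dense
layers, 3x3 same-padding 2-D convolutions (im2col + GEMM), ReLU, inverted
dropout, flatten, a fused softmax cross-entropy loss, and Adam.  All
parameters and activations are float32; every source of randomness
(initialization, batch shuffling, dropout masks) is drawn from a single
seeded Generator, so training is bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map x @ W + b with He-normal initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ShapeError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv2D(Layer):
    """3x3 (or kxk) stride-1 'same' convolution on (B, C, H, W) tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((fan_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k),
                                                           axis=(2, 3))
        # (B, C, H, W, k, k) -> (B*H*W, C*k*k)
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * self.k * self.k)
        return np.ascontiguousarray(cols)

    def forward(self, x, train, rng):
        b, c, h, w = x.shape
        if c != self.c_in:
            raise ShapeError(f"expected {self.c_in} input channels, got {c}")
        self._xshape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.w + self.b
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        b, c, h, w = self._xshape
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(b * h * w, self.c_out)
        self.grads[0][...] = self._cols.T @ g
        self.grads[1][...] = g.sum(axis=0)
        gcols = g @ self.w.T  # (B*H*W, C*k*k)
        gcols = gcols.reshape(b, h, w, c, self.k, self.k)
        p = self.k // 2
        gx = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        # col2im: scatter-add each kernel tap back to its input position.
        for di in range(self.k):
            for dj in range(self.k):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gx[:, :, p:p + h, p:p + w]


class Network:
    """An ordered layer stack with a fused softmax cross-entropy head."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...]) -> None:
        self.layers = layers
        self.input_shape = input_shape  # per-sample shape fed to the first layer

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for layer in self.layers for p in layer.params)

    def _reshape_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        expected = int(np.prod(self.input_shape))
        if x.ndim != 2 or x.shape[1] != expected:
            raise ShapeError(
                f"expected input of shape (n, {expected}), got {x.shape}"
            )
        return x.reshape((x.shape[0], *self.input_shape))

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return class logits for a (n_samples, n_features) batch."""
        rng = rng or np.random.default_rng(0)
        out = self._reshape_input(x)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (loss, gradient w.r.t. logits).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-30)))
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, network: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in network.parameters()]
        self.v = [np.zeros_like(p) for p, _ in network.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self.network.parameters()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
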