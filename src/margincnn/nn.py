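"""Minimal NumPy neural-network layers for the patch classifier.

Float32 throughout; convolutions are stride-1 same-padding implemented via
im2col + GEMM, so the only spatial downsampling comes from the two 2x2/2
max-pool layers. Gradients follow plain backpropagation and are applied by
vanilla SGD (no momentum, no weight decay). All randomness (initialization,
dropout masks) flows through `numpy.random.Generator` instances supplied by
the caller, which makes training bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np


def he_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """Variance-scaled (fan-in) Gaussian initialization."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    params: tuple = ()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sgd_step(self, lr: float) -> None:
        pass


class Conv2D(Layer):
    """3x3 (or k x k) convolution, stride 1, same padding, NHWC layout."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        self.k = kernel
        self.cin = cin
        self.cout = cout
        fan_in = kernel * kernel * cin
        self.W = he_normal(rng, fan_in, (fan_in, cout))  # rows ordered (kh, kw, cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = ("W", "b")

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (n, h, w, c, k, k) -> cols ordered (kh, kw, c) to match W rows
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * c
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        cols = self._im2col(x)
        out = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(n * h * w, self.cout)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for i in range(k):  # scatter-add the k*k shifted views (stride-1 col2im)
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        del self._cols
        return dxp[:, p : p + h, p : p + w, :]

    def sgd_step(self, lr: float) -> None:
        self.W -= lr * self.dW
        self.b -= lr * self.db


class ReLU(Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2, :]
        r = np.ascontiguousarray(
            xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        ).reshape(n, h2, w2, c, 4)
        arg = r.argmax(axis=-1)
        if train:
            self._arg = arg
            self._inshape = x.shape
        return np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._inshape
        h2, w2 = h // 2, w // 2
        d4 = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
        np.put_along_axis(d4, self._arg[..., None], dout[..., None], axis=-1)
        dxc = (
            d4.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * 2, w2 * 2, c)
        )
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, : h2 * 2, : w2 * 2, :] = dxc
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = he_normal(rng, n_in, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = ("W", "b")

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def sgd_step(self, lr):
        self.W -= lr * self.dW
        self.b -= lr * self.db


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            layer.sgd_step(lr)

    def weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append(getattr(layer, name))
        return out

    def set_weights(self, arrays) -> None:
        arrays = list(arrays)
        i = 0
        for layer in self.layers:
            for name in layer.params:
                target = getattr(layer, name)
                if arrays[i].shape != target.shape:
                    raise ValueError(
                        f"weight shape mismatch: {arrays[i].shape} vs {target.shape}"
                    )
                setattr(layer, name, arrays[i].astype(np.float32))
                i += 1
        if i != len(arrays):
            raise ValueError("wrong number of weight arrays for this architecture")
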