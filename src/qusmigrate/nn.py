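"""Minimal numpy neural-network layers with hand-written backprop and Adam.

Only what the reduced patch classifiers need: strided valid/same 2-D
convolution (im2col + BLAS matmul), ReLU, 2x2 average pooling,
global average pooling, a dense head, dense (concatenative) and residual
blocks. All computation is float32 and fully deterministic given the
initialization generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "AvgPool2d", "GlobalAvgPool", "Dense", "DenseBlock", "ResidualBlock", "Adam", "Sequential", "bce_with_logits", "sigmoid"]


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, rng, in_ch, out_ch, kernel=(3, 3), stride=(1, 1), pad="valid"):
        super().__init__()
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        self.W = _uniform_init(rng, (out_ch, in_ch, kh, kw), fan_in)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.stride = stride
        self.pad = pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _pad_amounts(self):
        kh, kw = self.W.shape[2:]
        if self.pad == "valid":
            return (0, 0), (0, 0)
        # 'same' supported for stride 1 only
        ph, pw = kh // 2, kw // 2
        return (ph, kh - 1 - ph), (pw, kw - 1 - pw)

    def _im2col(self, x, Ho, Wo):
        """Tap-ordered column tensor (N, Cin*kh*kw, Ho*Wo), filled by strided
        slice copies so every heavy op downstream is a BLAS matmul."""
        kh, kw = self.W.shape[2:]
        sh, sw = self.stride
        N, Cin = x.shape[:2]
        cols = np.empty((N, Cin, kh, kw, Ho, Wo), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = x[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw]
        return cols.reshape(N, Cin * kh * kw, Ho * Wo)

    def forward(self, x):
        (pt, pb), (pl, pr) = self._pad_amounts()
        if pt or pb or pl or pr:
            x = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        self._x_shape = x.shape
        kh, kw = self.W.shape[2:]
        sh, sw = self.stride
        if x.shape[2] < kh or x.shape[3] < kw:
            raise ValueError("input smaller than the convolution kernel")
        Ho = (x.shape[2] - kh) // sh + 1
        Wo = (x.shape[3] - kw) // sw + 1
        self._cols = self._im2col(x, Ho, Wo)
        Wm = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(Wm, self._cols).reshape(x.shape[0], -1, Ho, Wo)
        return (out + self.b[None, :, None, None]).astype(np.float32)

    def backward(self, dout):
        kh, kw = self.W.shape[2:]
        sh, sw = self.stride
        N, Cin, H, W = self._x_shape
        _, Cout, Ho, Wo = dout.shape
        dflat = dout.reshape(N, Cout, Ho * Wo)
        self.grads[0][...] = np.tensordot(dflat, self._cols, axes=([0, 2], [0, 2])).reshape(
            self.W.shape
        )
        self.grads[1][...] = dout.sum(axis=(0, 2, 3))
        Wm = self.W.reshape(Cout, -1)
        dcols = np.matmul(Wm.T, dflat).reshape(N, Cin, kh, kw, Ho, Wo)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += dcols[:, :, i, j]
        (pt, pb), (pl, pr) = self._pad_amounts()
        if pt or pb or pl or pr:
            dx = dx[:, :, pt : H - pb, pl : W - pr]
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(np.float32)

    def backward(self, dout):
        return dout * self._mask


class AvgPool2d(Layer):
    """2x2 average pooling, stride 2; trailing odd row/column dropped."""

    def forward(self, x):
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        self._in_shape = x.shape
        v = x[:, :, : 2 * Ho, : 2 * Wo].reshape(N, C, Ho, 2, Wo, 2)
        return v.mean(axis=(3, 5)).astype(np.float32)

    def backward(self, dout):
        N, C, H, W = self._in_shape
        Ho, Wo = H // 2, W // 2
        dx = np.zeros(self._in_shape, dtype=np.float32)
        d = (dout / 4.0)[:, :, :, None, :, None]
        dx[:, :, : 2 * Ho, : 2 * Wo] = np.broadcast_to(
            d, (N, C, Ho, 2, Wo, 2)
        ).reshape(N, C, 2 * Ho, 2 * Wo)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dout):
        N, C, H, W = self._in_shape
        return np.broadcast_to(
            (dout / (H * W))[:, :, None, None], self._in_shape
        ).astype(np.float32)


class Dense(Layer):
    """Flattening linear layer."""

    def __init__(self, rng, in_features, out_features):
        super().__init__()
        self.W = _uniform_init(rng, (in_features, out_features), in_features)
        self.b = _uniform_init(rng, (out_features,), in_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._in_shape = x.shape
        self._x = x.reshape(len(x), -1)
        return (self._x @ self.W + self.b).astype(np.float32)

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return (dout @ self.W.T).reshape(self._in_shape)


class DenseBlock(Layer):
    """Dense connection: output = concat(x, relu(conv3x3_same(x)))."""

    def __init__(self, rng, in_ch, growth):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, growth, kernel=(3, 3), stride=(1, 1), pad="same")
        self.relu = ReLU()
        self.in_ch = in_ch
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x):
        y = self.relu.forward(self.conv.forward(x))
        return np.concatenate([x, y], axis=1)

    def backward(self, dout):
        dx_skip = dout[:, : self.in_ch]
        dy = dout[:, self.in_ch :]
        return dx_skip + self.conv.backward(self.relu.backward(dy))


class ResidualBlock(Layer):
    """Pre-activation-free basic block: relu(x + conv(relu(conv(x))))."""

    def __init__(self, rng, channels):
        super().__init__()
        self.conv1 = Conv2d(rng, channels, channels, (3, 3), (1, 1), pad="same")
        self.conv2 = Conv2d(rng, channels, channels, (3, 3), (1, 1), pad="same")
        self.r1, self.r2 = ReLU(), ReLU()
        self.params = self.conv1.params + self.conv2.params
        self.grads = self.conv1.grads + self.conv2.grads

    def forward(self, x):
        y = self.conv2.forward(self.r1.forward(self.conv1.forward(x)))
        return self.r2.forward(x + y)

    def backward(self, dout):
        d = self.r2.backward(dout)
        dy = self.conv1.backward(self.r1.backward(self.conv2.backward(d)))
        return d + dy


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for l in reversed(self.layers):
            dout = l.backward(dout)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Numerically stable per-sample binary cross-entropy and d(loss)/d(logit).

    loss = -[y log yhat + (1-y) log(1-yhat)] with yhat = sigmoid(logit).
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    losses = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = sigmoid(z) - y
    return losses, dz
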