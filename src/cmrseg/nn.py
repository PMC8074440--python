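"""Minimal NumPy neural-network engine for 2D semantic segmentation.

Implements exactly the pieces a 2D U-Net needs — 3x3 same-padding
convolutions, batch normalization, ReLU, 2x2 max-pooling, 2x2 stride-2
transposed convolutions, skip concatenation and an Adam optimizer — with
hand-written backward passes.  Activations are channels-last
``(N, H, W, C)`` float32; convolutions are evaluated as shifted GEMMs so
the heavy lifting stays inside BLAS.

All randomness flows through an explicit ``numpy.random.Generator``, so
initialization and training are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

#: working precision of the engine.  float32 for speed; tests switch to
#: float64 when verifying gradients against finite differences.
DTYPE = np.float32


class Layer:
    """A differentiable layer: ``forward`` caches what ``backward`` needs."""

    def params(self) -> list[tuple[str, np.ndarray]]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k same-padding convolution, stride 1, He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, kernel: int = 3):
        self.cin, self.cout, self.k = cin, cout, kernel
        scale = np.sqrt(2.0 / (cin * kernel * kernel))
        self.W = rng.normal(0.0, scale, (kernel, kernel, cin, cout)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        N, H, W, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.empty((N, H, W, self.cout), dtype=DTYPE)
        yf = y.reshape(-1, self.cout)
        yf[:] = self.b
        for di in range(self.k):
            for dj in range(self.k):
                xs = xp[:, di : di + H, dj : dj + W, :].reshape(-1, self.cin)
                yf += xs @ self.W[di, dj]
        if train:
            self._xp, self._hw = xp, (H, W)
        return y

    def backward(self, dy):
        N, H, W, _ = dy.shape
        p = self.k // 2
        dyf = dy.reshape(-1, self.cout)
        self.gb[:] = dyf.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for di in range(self.k):
            for dj in range(self.k):
                xs = self._xp[:, di : di + H, dj : dj + W, :].reshape(-1, self.cin)
                self.gW[di, dj] = xs.T @ dyf
                dxp[:, di : di + H, dj : dj + W, :] += (dyf @ self.W[di, dj].T).reshape(
                    N, H, W, self.cin
                )
        self._xp = None
        return dxp[:, p : p + H, p : p + W, :] if p else dxp


class BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.run_mean = np.zeros(c, dtype=DTYPE)
        self.run_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def state(self):
        return [("run_mean", self.run_mean), ("run_var", self.run_var)]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        if train:
            self._xhat, self._istd = xhat, istd
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, istd = self._xhat, self._istd
        self.ggamma[:] = (dy * xhat).sum(axis=(0, 1, 2))
        self.gbeta[:] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma
        m1 = dxhat.mean(axis=(0, 1, 2))
        m2 = (dxhat * xhat).mean(axis=(0, 1, 2))
        dx = istd * (dxhat - m1 - xhat * m2)
        self._xhat = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train):
        y = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._pos
        self._pos = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, train):
        N, H, W, C = x.shape
        x6 = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        flat = np.ascontiguousarray(x6).reshape(N, H // 2, W // 2, 4, C)
        idx = flat.argmax(axis=3)
        y = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy):
        N, H, W, C = self._shape
        d4 = np.zeros((N, H // 2, W // 2, 4, C), dtype=DTYPE)
        np.put_along_axis(d4, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = (
            d4.reshape(N, H // 2, W // 2, 2, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(N, H, W, C)
        )
        self._idx = None
        return np.ascontiguousarray(dx)


class ConvTranspose2(Layer):
    """2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.cin, self.cout = cin, cout
        self.W = rng.normal(0.0, scale, (2, 2, cin, cout)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        N, H, W, _ = x.shape
        xf = x.reshape(-1, self.cin)
        y = np.empty((N, 2 * H, 2 * W, self.cout), dtype=DTYPE)
        for di in range(2):
            for dj in range(2):
                y[:, di::2, dj::2, :] = (xf @ self.W[di, dj]).reshape(N, H, W, self.cout)
        y += self.b
        if train:
            self._xf, self._nhw = xf, (N, H, W)
        return y

    def backward(self, dy):
        N, H, W = self._nhw
        self.gb[:] = dy.sum(axis=(0, 1, 2))
        dxf = np.zeros((N * H * W, self.cin), dtype=DTYPE)
        for di in range(2):
            for dj in range(2):
                dys = np.ascontiguousarray(dy[:, di::2, dj::2, :]).reshape(-1, self.cout)
                self.gW[di, dj] = self._xf.T @ dys
                dxf += dys @ self.W[di, dj].T
        dx = dxf.reshape(N, H, W, self.cin)
        self._xf = None
        return dx


class DoubleConv(Layer):
    """(Conv 3x3 -> BN -> ReLU) x 2, the standard U-Net block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.layers = [
            Conv2d(cin, cout, rng),
            BatchNorm(cout),
            ReLU(),
            Conv2d(cout, cout, rng),
            BatchNorm(cout),
            ReLU(),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Symmetric encoder-decoder with skip connections.

    ``depth`` encoder levels (the deepest acting as bottleneck) with
    ``base * 2**i`` channels at level ``i``; 2x2 max-pool downsampling,
    transposed-conv upsampling, concatenated skips, and a final 1x1
    convolution producing per-class logits at input resolution.  Inputs
    whose spatial size is not a multiple of ``2**(depth-1)`` are
    zero-padded internally and the logits cropped back.
    """

    def __init__(self, n_classes: int, depth: int = 4, base: int = 16, in_ch: int = 1, seed: int = 0):
        if depth < 2:
            raise ValueError("U-Net depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.n_classes, self.depth, self.base, self.in_ch = n_classes, depth, base, in_ch
        ch = [base * 2**i for i in range(depth)]
        self.enc = [DoubleConv(in_ch if i == 0 else ch[i - 1], ch[i], rng) for i in range(depth)]
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = [ConvTranspose2(ch[i + 1], ch[i], rng) for i in reversed(range(depth - 1))]
        self.dec = [DoubleConv(2 * ch[i], ch[i], rng) for i in reversed(range(depth - 1))]
        self.head = Conv2d(ch[0], n_classes, rng, kernel=1)

    # -- parameter plumbing -------------------------------------------------

    def _modules(self):
        return [*self.enc, *self.ups, *self.dec, self.head]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def _bn_layers(self):
        out = []
        for blk in [*self.enc, *self.dec]:
            out.extend(l for l in blk.layers if isinstance(l, BatchNorm))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {}
        for i, (_, p) in enumerate(self.params()):
            d[f"p{i}"] = p
        for i, bn in enumerate(self._bn_layers()):
            d[f"bn{i}_mean"] = bn.run_mean
            d[f"bn{i}_var"] = bn.run_var
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for i, (_, p) in enumerate(self.params()):
            p[...] = d[f"p{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.run_mean = np.asarray(d[f"bn{i}_mean"], dtype=DTYPE)
            bn.run_var = np.asarray(d[f"bn{i}_var"], dtype=DTYPE)

    # -- forward / backward -------------------------------------------------

    def _pad(self, x):
        m = 2 ** (self.depth - 1)
        N, H, W, C = x.shape
        ph, pw = (-H) % m, (-W) % m
        self._crop = (H, W)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)))
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits ``(N, H, W, n_classes)`` for inputs ``(N, H, W, in_ch)``."""
        x = np.ascontiguousarray(x, dtype=DTYPE)
        x = self._pad(x)
        skips = []
        for i in range(self.depth - 1):
            x = self.enc[i].forward(x, train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        x = self.enc[-1].forward(x, train)
        self._skip_ch = []
        for j in range(self.depth - 1):
            x = self.ups[j].forward(x, train)
            skip = skips[-(j + 1)]
            x = np.concatenate([skip, x], axis=-1)
            self._skip_ch.append(skip.shape[-1])
            x = self.dec[j].forward(x, train)
        logits = self.head.forward(x, train)
        H, W = self._crop
        return logits[:, :H, :W, :]

    def backward(self, dlogits: np.ndarray) -> None:
        m = 2 ** (self.depth - 1)
        N, H, W, C = dlogits.shape
        ph, pw = (-H) % m, (-W) % m
        if ph or pw:
            dlogits = np.pad(dlogits, ((0, 0), (0, ph), (0, pw), (0, 0)))
        dy = self.head.backward(dlogits)
        dskips = []
        for j in reversed(range(self.depth - 1)):
            dy = self.dec[j].backward(dy)
            c = self._skip_ch[j]
            dskips.append(dy[..., :c])
            dy = self.ups[j].backward(np.ascontiguousarray(dy[..., c:]))
        dy = self.enc[-1].backward(dy)
        for i in reversed(range(self.depth - 1)):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)


class Adam:
    """Adam optimizer over a model's parameter/grad pairs."""

    def __init__(self, model, lr: float = 0.01, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p in model.params()]
        self.v = [np.zeros_like(p) for _, p in model.params()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (_, p), g, m, v in zip(self.model.params(), self.model.grads(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
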