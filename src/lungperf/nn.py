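"""Minimal numpy convolutional-network engine.

No deep-learning framework is available in the target environment, so the
blind-spot network is built on this small hand-written engine: dilated 2D
convolutions (optionally centre-masked), ReLU, residual blocks and Adam.
Forward passes cache what the matching backward pass needs; layers are used
for a single in-flight forward/backward pair at a time.

Convolutions use zero padding. This keeps the blind-spot argument exact at
image borders: zero padding never aliases an outside tap back onto the centre
pixel, whereas reflective padding can re-route the 5x5/dilation-3 branch onto
its own centre near an edge.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "Sequential", "Residual", "Concat2", "Adam"]


class Conv2d:
    """2D convolution over (N, C, H, W) with 'same' zero padding.

    ``mask_center=True`` zeroes the central tap of the kernel, structurally
    removing the identity path (the blind spot).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int = 1,
                 mask_center: bool = False, rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.W = rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.mask = np.ones_like(self.W)
        if mask_center:
            self.mask[:, :, kernel // 2, kernel // 2] = 0.0
        self.kernel = kernel
        self.dilation = dilation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._win = None
        self._in_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, d = self.kernel, self.dilation
        p = d * (k // 2)
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        ke = d * (k - 1) + 1
        win = sliding_window_view(xp, (ke, ke), axis=(2, 3))[..., ::d, ::d]
        Wm = self.W * self.mask
        out = np.tensordot(win, Wm, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,O)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        out += self.b[None, :, None, None]
        self._win = win
        self._in_shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, d = self.kernel, self.dilation
        p = d * (k // 2)
        N, C, H, W = self._in_shape
        self.dW = np.tensordot(g, self._win, axes=([0, 2, 3], [0, 2, 3]))
        self.dW *= self.mask
        self.db = g.sum(axis=(0, 2, 3))
        Wm = self.W * self.mask
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                w_ij = Wm[:, :, i, j]  # (O, C)
                contrib = np.tensordot(g, w_ij, axes=([1], [0]))  # (N,H,W,C)
                dxp[:, :, i * d:i * d + H, j * d:j * d + W] += contrib.transpose(0, 3, 1, 2)
        self._win = None
        return dxp[:, :, p:p + H, p:p + W] if p else dxp

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self):
        return [self.W, self.b]

    def load_state(self, arrays):
        self.W[...] = arrays[0]
        self.b[...] = arrays[1]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        out = np.where(self._mask, g, 0.0)
        self._mask = None
        return out

    def params(self):
        return []

    def state(self):
        return []

    def load_state(self, arrays):
        pass


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state(self):
        out = []
        for layer in self.layers:
            out.extend(layer.state())
        return out

    def load_state(self, arrays):
        i = 0
        for layer in self.layers:
            n = len(layer.state())
            layer.load_state(arrays[i:i + n])
            i += n


class Residual:
    """y = x + inner(x); channel counts must match."""

    def __init__(self, inner: Sequential):
        self.inner = inner

    def forward(self, x):
        return x + self.inner.forward(x)

    def backward(self, g):
        return g + self.inner.backward(g)

    def params(self):
        return self.inner.params()

    def state(self):
        return self.inner.state()

    def load_state(self, arrays):
        self.inner.load_state(arrays)


class Concat2:
    """Run two branches on the same input and concatenate along channels."""

    def __init__(self, branch_a: Sequential, branch_b: Sequential):
        self.a = branch_a
        self.b = branch_b
        self._split = None

    def forward(self, x):
        ya = self.a.forward(x)
        yb = self.b.forward(x)
        self._split = ya.shape[1]
        return np.concatenate([ya, yb], axis=1)

    def backward(self, g):
        s = self._split
        return self.a.backward(g[:, :s]) + self.b.backward(g[:, s:])

    def params(self):
        return self.a.params() + self.b.params()

    def state(self):
        return self.a.state() + self.b.state()

    def load_state(self, arrays):
        na = len(self.a.state())
        self.a.load_state(arrays[:na])
        self.b.load_state(arrays[na:])


class Adam:
    def __init__(self, net, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.net.params()):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
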