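"""Minimal NumPy convolutional layers with hand-derived gradients.

Just enough machinery for the habituation autoencoder: a same-padded
convolution, ReLU, concatenated max+average pooling, and a transposed
convolution (implemented as zero-dilation followed by convolution), plus
Adam.  All operations are deterministic; weights are initialized from an
explicit Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "DualPool2", "ConvTranspose2x", "Sequential", "Adam", "mse_loss"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H-k+1, W-k+1, C*k*k) valid-window columns."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (B, C, Ho, Wo, k, k) -> (B, Ho, Wo, C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        x.shape[0], x.shape[2] - k + 1, x.shape[3] - k + 1, -1)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add columns back to (B, C, H, W)."""
    B, C, H, W = x_shape
    Ho, Wo = H - k + 1, W - k + 1
    x = np.zeros(x_shape)
    cols = cols.reshape(B, Ho, Wo, C, k, k)
    for dy in range(k):
        for dx in range(k):
            x[:, :, dy:dy + Ho, dx:dx + Wo] += cols[:, :, :, :, dy, dx].transpose(0, 3, 1, 2)
    return x


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded stride-1 convolution (cross-correlation) with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 pad: int | None = None):
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_in * k * k, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._x_shape = xp.shape
        self._cols = _im2col(xp, self.k)
        out = self._cols @ self.W + self.b
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout):
        d = dout.transpose(0, 2, 3, 1)
        self.grads[0][...] = np.tensordot(self._cols, d, axes=([0, 1, 2], [0, 1, 2]))
        self.grads[1][...] = d.sum(axis=(0, 1, 2))
        dcols = d @ self.W.T
        dxp = _col2im(dcols, self._x_shape, self.k)
        p = self.pad
        return dxp[:, :, p:-p or None, p:-p or None] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class DualPool2(Layer):
    """Concatenated 2x2 max- and average-pooling (stride 2), doubling channels."""

    def forward(self, x):
        B, C, H, W = x.shape
        self._x_shape = x.shape
        v = x.reshape(B, C, H // 2, 2, W // 2, 2)
        self._v = v
        mx = v.max(axis=(3, 5))
        av = v.mean(axis=(3, 5))
        self._argmask = v == mx[:, :, :, None, :, None]
        return np.concatenate([mx, av], axis=1)

    def backward(self, dout):
        B, C, H, W = self._x_shape
        dmx, dav = dout[:, :C], dout[:, C:]
        # route max grad to (first) argmax; ties split evenly is acceptable here
        nsel = self._argmask.sum(axis=(3, 5), keepdims=True)
        dv = self._argmask * (dmx[:, :, :, None, :, None] / nsel)
        dv = dv + dav[:, :, :, None, :, None] / 4.0
        return dv.reshape(B, C, H, W)


class ConvTranspose2x(Layer):
    """Stride-2 transposed convolution with a 4x4 kernel: exact 2x upsampling.

    Realized as zero-dilation of the input followed by a valid convolution
    with padding k-1-p = 2 (p = 1), giving output size 2H x 2W.
    """

    K = 4
    PAD = 2

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2D(c_in, c_out, self.K, rng, pad=self.PAD)
        self.params = self.conv.params
        self.grads = self.conv.grads

    @staticmethod
    def _dilate(x):
        B, C, H, W = x.shape
        out = np.zeros((B, C, 2 * H - 1, 2 * W - 1))
        out[:, :, ::2, ::2] = x
        return out

    def forward(self, x):
        self._in_shape = x.shape
        return self.conv.forward(self._dilate(x))
        # dilated (2H-1) + 2*2 pad - 4 + 1 = 2H

    def backward(self, dout):
        dxd = self.conv.backward(dout)
        return dxd[:, :, ::2, ::2]


class GlobalDualPool(Layer):
    """Concatenated global max- and average-pooling: (B,C,H,W) -> (B,2C,1,1).

    Collapses the feature map to a vector code, the autoencoder's
    low-dimensional bottleneck.
    """

    def forward(self, x):
        self._x_shape = x.shape
        B, C, H, W = x.shape
        flat = x.reshape(B, C, -1)
        self._argmax = flat.argmax(axis=2)
        mx = flat.max(axis=2)
        av = flat.mean(axis=2)
        return np.concatenate([mx, av], axis=1)[:, :, None, None]

    def backward(self, dout):
        B, C, H, W = self._x_shape
        d = dout[:, :, 0, 0]
        dx = np.zeros((B, C, H * W))
        bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        dx[bi, ci, self._argmax] = d[:, :C]
        dx += (d[:, C:] / (H * W))[:, :, None]
        return dx.reshape(B, C, H, W)


class FullFrameDeconv(Layer):
    """Single transposed convolution from a (B, C, 1, 1) code to a full
    (B, 1, H, W) image: the kernel spans the whole output frame, so the
    reconstruction is a learned combination of C template images."""

    def __init__(self, c_in: int, out_hw: tuple, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.out_hw = c_in, out_hw
        n_out = out_hw[0] * out_hw[1]
        self.W = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(c_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._z = x[:, :, 0, 0]
        out = self._z @ self.W + self.b
        return out.reshape(x.shape[0], 1, *self.out_hw)

    def backward(self, dout):
        d = dout.reshape(dout.shape[0], -1)
        self.grads[0][...] = self._z.T @ d
        self.grads[1][...] = d.sum(axis=0)
        return (d @ self.W.T)[:, :, None, None]


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
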