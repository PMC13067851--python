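"""Minimal CPU neural-network layers with explicit backprop.

Just enough machinery for the shallow spiral-core network: a valid-in-time /
same-in-space 3D convolution, max pooling, a 1x3x3 (2D) convolution, stride-2
transposed convolutions, bilinear resizing and sigmoid/ReLU, plus Adam.
Everything is float32 and deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

F32 = np.float32


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Layer:
    params: list  # [(name, array, grad array), ...]

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, valid in time, same (zero-pad) in space, stride 1.

    Implemented as shift-and-matmul accumulation over the 27 kernel taps so
    all heavy lifting happens in contiguous BLAS calls.
    """

    def __init__(self, rng, c_in, c_out, k=(3, 3, 3)):
        self.k = k
        fan_in = c_in * k[0] * k[1] * k[2]
        self.W = he_init(rng, (c_out, c_in) + k, fan_in)
        self.b = np.zeros(c_out, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def _im2col(self, xp, To, Ho, Wo):
        kt, kh, kw = self.k
        B, Ci, T, H, W = xp.shape
        N = B * To * Ho * Wo
        col = np.empty((Ci * kt * kh * kw, N), dtype=F32)
        colv = col.reshape(Ci, kt * kh * kw, N)
        j = 0
        for dt in range(kt):
            for dy in range(kh):
                for dx in range(kw):
                    sl = xp[:, :, dt : dt + To, dy : dy + Ho, dx : dx + Wo]
                    colv[:, j, :] = sl.transpose(1, 0, 2, 3, 4).reshape(Ci, N)
                    j += 1
        return col

    def forward(self, x, train=False):
        kt, kh, kw = self.k
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (ph, ph), (pw, pw)))
        B, Ci, T, H, W = xp.shape
        To, Ho, Wo = T - kt + 1, H - kh + 1, W - kw + 1
        Co = self.W.shape[0]
        col = self._im2col(xp, To, Ho, Wo)
        if train:
            self._col = col
            self._dims = (B, Ci, T, H, W, To, Ho, Wo, ph, pw)
        y2 = self.W.reshape(Co, -1) @ col  # (Co, B*To*Ho*Wo)
        y = y2.reshape(Co, B, To, Ho, Wo).transpose(1, 0, 2, 3, 4)
        return np.ascontiguousarray(y) + self.b[None, :, None, None, None]

    def backward(self, g):
        kt, kh, kw = self.k
        B, Ci, T, H, W, To, Ho, Wo, ph, pw = self._dims
        Co = self.W.shape[0]
        N = B * To * Ho * Wo
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(Co, N)
        self.gW[...] = (g2 @ self._col.T).reshape(self.W.shape)
        self.gb[...] = g2.sum(axis=1)
        dcol = self.W.reshape(Co, -1).T @ g2  # (Ci*27, N)
        del self._col
        dxp = np.zeros((Ci, B, T, H, W), dtype=F32)
        dcolv = dcol.reshape(Ci, kt * kh * kw, B, To, Ho, Wo)
        j = 0
        for dt in range(kt):
            for dy in range(kh):
                for dx in range(kw):
                    dxp[:, :, dt : dt + To, dy : dy + Ho, dx : dx + Wo] += dcolv[:, j]
                    j += 1
        dx = dxp.transpose(1, 0, 2, 3, 4)[:, :, :, ph : H - ph, pw : W - pw]
        return np.ascontiguousarray(dx)


class TemporalMax(Layer):
    """Max over the time axis (B, C, T, H, W) -> (B, C, H, W)."""

    params = []

    def forward(self, x, train=False):
        self._arg = x.argmax(axis=2)
        self._T = x.shape[2]
        return x.max(axis=2)

    def backward(self, g):
        B, C, H, W = g.shape
        dx = np.zeros((B, C, self._T, H, W), dtype=F32)
        b, c, h, w = np.ogrid[:B, :C, :H, :W]
        dx[b, c, self._arg, h, w] = g
        return dx


class MaxPool2d(Layer):
    """k x k max pooling with stride s and optional zero-padding."""

    params = []

    def __init__(self, k=3, stride=2, pad=0):
        self.k, self.s, self.p = k, stride, pad

    def forward(self, x, train=False):
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        B, C, H, W = xp.shape
        Ho, Wo = (H - k) // s + 1, (W - k) // s + 1
        sB, sC, sH, sW = xp.strides
        P = as_strided(
            xp, (B, C, Ho, Wo, k, k), (sB, sC, sH * s, sW * s, sH, sW), writeable=False
        ).reshape(B, C, Ho, Wo, k * k)
        self._arg = P.argmax(axis=-1)
        self._in_shape = x.shape
        self._pad_shape = xp.shape
        return P.max(axis=-1)

    def backward(self, g):
        k, s, p = self.k, self.s, self.p
        B, C, Ho, Wo = g.shape
        Hp, Wp = self._pad_shape[2:]
        ay, ax = np.divmod(self._arg, k)
        oy = np.arange(Ho)[None, None, :, None] * s
        ox = np.arange(Wo)[None, None, None, :] * s
        iy = oy + ay
        ix = ox + ax
        bc = np.arange(B * C)[:, None, None].reshape(B, C, 1, 1)
        flat = (bc * (Hp * Wp) + iy * Wp + ix).ravel()
        dxp = np.bincount(flat, weights=g.ravel().astype(np.float64), minlength=B * C * Hp * Wp)
        dxp = dxp.reshape(B, C, Hp, Wp).astype(F32)
        H, W = self._in_shape[2:]
        return dxp[:, :, p : p + H, p : p + W]


class Conv2d(Layer):
    """Same-padding k x k 2D convolution, stride 1."""

    def __init__(self, rng, c_in, c_out, k=3):
        self.k = k
        self.W = he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = np.zeros(c_out, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def forward(self, x, train=False):
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        if train:
            self._xp = xp
        B, Ci, H, W = xp.shape
        Ho, Wo = H - self.k + 1, W - self.k + 1
        Co = self.W.shape[0]
        y = np.zeros((B, Co, Ho, Wo), dtype=F32)
        yf = y.reshape(B, Co, -1)
        for dy in range(self.k):
            for dx in range(self.k):
                sl = np.ascontiguousarray(xp[:, :, dy : dy + Ho, dx : dx + Wo]).reshape(B, Ci, -1)
                yf += self.W[:, :, dy, dx] @ sl
        return y + self.b[None, :, None, None]

    def backward(self, g):
        p = self.k // 2
        xp = self._xp
        B, Ci, H, W = xp.shape
        _, Co, Ho, Wo = g.shape
        gf = g.reshape(B, Co, -1)
        self.gb[...] = g.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for dy in range(self.k):
            for dx in range(self.k):
                sl = np.ascontiguousarray(xp[:, :, dy : dy + Ho, dx : dx + Wo]).reshape(B, Ci, -1)
                self.gW[:, :, dy, dx] = np.einsum("bop,bcp->oc", gf, sl, optimize=True)
                dsl = np.einsum("oc,bop->bcp", self.W[:, :, dy, dx], gf, optimize=True)
                dxp[:, :, dy : dy + Ho, dx : dx + Wo] += dsl.reshape(B, Ci, Ho, Wo)
        del self._xp
        return dxp[:, :, p : H - p, p : W - p]


class ConvTranspose2d(Layer):
    """Stride-2 transposed convolution doubling the spatial size.

    k = 2 (pad 0) gives disjoint 2x2 blocks; k = 4 (pad 1) gives the usual
    overlap-add upsampler with a larger receptive field.
    """

    def __init__(self, rng, c_in, c_out, k=2):
        if k not in (2, 4):
            raise ValueError("supported kernels: 2 (pad 0) or 4 (pad 1)")
        self.k = k
        self.p = 0 if k == 2 else 1
        self.W = he_init(rng, (c_in, c_out, k, k), c_in * (k // 2) ** 2)
        self.b = np.zeros(c_out, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def _spans(self, a, H):
        """Output slice indices for tap offset ``a`` over inputs 0..H-1:
        out = 2*i + a - p; returns (out_start, in_start, count)."""
        o0 = a - self.p
        i0 = 0
        if o0 < 0:
            i0 = 1
            o0 += 2
        cnt = H - i0
        if o0 + 2 * (cnt - 1) > 2 * H - 1:
            cnt -= 1
        return o0, i0, cnt

    def forward(self, x, train=False):
        if train:
            self._x = x
        B, Ci, H, W = x.shape
        Co = self.W.shape[1]
        y = np.zeros((B, Co, 2 * H, 2 * W), dtype=F32)
        for a in range(self.k):
            oy, iy, ny = self._spans(a, H)
            for b_ in range(self.k):
                ox, ix, nx = self._spans(b_, W)
                tap = self.W[:, :, a, b_]  # (Ci, Co)
                sl = x[:, :, iy : iy + ny, ix : ix + nx]
                contrib = np.tensordot(sl, tap, axes=(1, 0))  # (B, ny, nx, Co)
                y[:, :, oy : oy + 2 * ny : 2, ox : ox + 2 * nx : 2] += contrib.transpose(0, 3, 1, 2)
        return y + self.b[None, :, None, None]

    def backward(self, g):
        x = self._x
        B, Ci, H, W = x.shape
        Co = self.W.shape[1]
        self.gb[...] = g.sum(axis=(0, 2, 3))
        dx = np.zeros_like(x)
        for a in range(self.k):
            oy, iy, ny = self._spans(a, H)
            for b_ in range(self.k):
                ox, ix, nx = self._spans(b_, W)
                gsl = g[:, :, oy : oy + 2 * ny : 2, ox : ox + 2 * nx : 2]  # (B, Co, ny, nx)
                xsl = x[:, :, iy : iy + ny, ix : ix + nx]
                self.gW[:, :, a, b_] = np.einsum("bchw,bohw->co", xsl, gsl, optimize=True)
                dx[:, :, iy : iy + ny, ix : ix + nx] += np.einsum(
                    "co,bohw->bchw", self.W[:, :, a, b_], gsl, optimize=True
                )
        del self._x
        return dx


class ReLU(Layer):
    params = []

    def forward(self, x, train=False):
        self._m = x > 0
        return np.where(self._m, x, np.float32(0.0))

    def backward(self, g):
        g[~self._m] = 0.0  # caller discards its reference; safe in-place
        return g


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (n_out, n_in), endpoints aligned."""
    A = np.zeros((n_out, n_in), dtype=F32)
    src = np.linspace(0.0, n_in - 1.0, n_out)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(F32)
    A[np.arange(n_out), i0] += 1.0 - f
    A[np.arange(n_out), i1] += f
    return A


class BilinearResize(Layer):
    """Separable bilinear resize of (B, C, H, W) to a fixed output size."""

    params = []

    def __init__(self, n_out: int, n_in: int):
        self.A = _interp_matrix(n_out, n_in)

    def forward(self, x, train=False):
        y = np.einsum("oh,bchw,pw->bcop", self.A, x, self.A, optimize=True)
        return y.astype(F32)

    def backward(self, g):
        dx = np.einsum("oh,bcop,pw->bchw", self.A, g, self.A, optimize=True)
        return dx.astype(F32)


class Sigmoid(Layer):
    params = []

    def forward(self, x, train=False):
        from scipy.special import expit

        self._y = expit(np.asarray(x, dtype=np.float64))
        return self._y.astype(F32)

    def backward(self, g):
        return (g * self._y * (1.0 - self._y)).astype(F32)


class Adam:
    """Adam optimizer over a list of (array, grad) pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
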