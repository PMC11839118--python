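"""Minimal numpy neural-network engine for the patch autoencoders.

Implements exactly the pieces the fingerprint module needs — 2-D convolutions
(im2col), residual blocks, nearest-neighbour upsampling, global average
pooling, linear layers and Adam — with explicit forward/backward passes.
Tensors use NHWC layout throughout and float32 arithmetic. Every layer caches
what its backward pass needs; layers are single-use per forward pass.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32


@njit(fastmath=True)
def _im2col(xp, k, s, ho, wo):
    b, hp, wp, c = xp.shape
    cols = np.empty((b * ho * wo, k * k * c), np.float32)
    for bi in range(b):
        for i in range(ho):
            for j in range(wo):
                row = (bi * ho + i) * wo + j
                col = 0
                for di in range(k):
                    xi = i * s + di
                    for dj in range(k):
                        xj = j * s + dj
                        for ch in range(c):
                            cols[row, col] = xp[bi, xi, xj, ch]
                            col += 1
    return cols


@njit(fastmath=True)
def _col2im(dcols, b, hp, wp, c, k, s, ho, wo):
    dxp = np.zeros((b, hp, wp, c), np.float32)
    for bi in range(b):
        for i in range(ho):
            for j in range(wo):
                row = (bi * ho + i) * wo + j
                col = 0
                for di in range(k):
                    xi = i * s + di
                    for dj in range(k):
                        xj = j * s + dj
                        for ch in range(c):
                            dxp[bi, xi, xj, ch] += dcols[row, col]
                            col += 1
    return dxp


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad ** 2
            p.value -= self.lr * (p.m / corr1) / (np.sqrt(p.v / corr2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    """3x3 (or kxk) same-padded convolution, NHWC, optional stride."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 ksize: int = 3, stride: int = 1):
        self.cin, self.cout, self.k, self.stride = cin, cout, ksize, stride
        fan_in = cin * ksize * ksize
        self.w = Param(_he_init(rng, (ksize * ksize * cin, cout), fan_in))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        p = k // 2
        x = np.ascontiguousarray(x, dtype=F32)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        b_ = x.shape[0]
        ho = (x.shape[1] + 2 * p - k) // s + 1
        wo = (x.shape[2] + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo)
        out = cols @ self.w.value + self.b.value
        self._cache = (cols, x.shape, (b_, ho, wo))
        return out.reshape(b_, ho, wo, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (b_, ho, wo) = self._cache
        k, s = self.k, self.stride
        p = k // 2
        dy_flat = np.ascontiguousarray(dy, dtype=F32).reshape(b_ * ho * wo, self.cout)
        self.w.grad += cols.T @ dy_flat
        self.b.grad += dy_flat.sum(axis=0)
        dcols = dy_flat @ self.w.value.T            # (BHW, k*k*C)
        hp, wp = x_shape[1] + 2 * p, x_shape[2] + 2 * p
        dxp = _col2im(dcols, b_, hp, wp, self.cin, k, s, ho, wo)
        return dxp[:, p : p + x_shape[1], p : p + x_shape[2], :]


class Linear:
    def __init__(self, rng: np.random.Generator, din: int, dout: int):
        self.w = Param(_he_init(rng, (din, dout), din))
        self.b = Param(np.zeros(dout))
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(F32)
        return self._x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(F32)
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


class Upsample2:
    """Nearest-neighbour x2 spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h2, w2, c = dy.shape
        return dy.reshape(b, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


def _concat_cond(x: np.ndarray, cond: np.ndarray | None) -> np.ndarray:
    """Concatenate spatially homogeneous conditioning channels to x."""
    if cond is None:
        return x
    b, h, w, _ = x.shape
    maps = np.broadcast_to(cond[:, None, None, :], (b, h, w, cond.shape[1]))
    return np.concatenate([x, maps.astype(F32)], axis=3)


def _split_cond_grad(dx_cat: np.ndarray, c_main: int) -> tuple[np.ndarray, np.ndarray]:
    """Split gradient of a cond-concatenated tensor into (dx, dcond)."""
    dx = dx_cat[..., :c_main]
    dcond = dx_cat[..., c_main:].sum(axis=(1, 2))
    return dx, dcond


class ResBlock:
    """conv3x3(stride) -> relu -> conv3x3; skip via 1x1 conv when needed.

    Conditioning channels are concatenated to the main-path input only; the
    skip path carries the raw input.
    """

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 stride: int = 1, cond_dim: int = 0):
        self.cin, self.cout, self.stride, self.cond_dim = cin, cout, stride, cond_dim
        self.conv1 = Conv2d(rng, cin + cond_dim, cout, 3, stride)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(rng, cout, cout, 3, 1)
        # damp the residual branch's last conv at init: blocks start close to
        # (projected) identity, keeping output scale O(1) without silencing
        # the branch's gradients
        self.conv2.w.value *= 0.1
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Conv2d(rng, cin, cout, 1, stride)
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x: np.ndarray, cond: np.ndarray | None) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(
            self.conv1.forward(_concat_cond(x, cond if self.cond_dim else None))))
        skip = x if self.proj is None else self.proj.forward(x)
        return self.relu_out.forward(h + skip)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        dy = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.relu1.backward(self.conv2.backward(dy)))
        if self.cond_dim:
            dx_main, dcond = _split_cond_grad(dmain, self.cin)
        else:
            dx_main, dcond = dmain, None
        dskip = dy if self.proj is None else self.proj.backward(dy)
        return dx_main + dskip, dcond


class ResEncoder:
    """Residual conv encoder: side -> side/8 with global pooling to 2C."""

    def __init__(self, rng: np.random.Generator, in_ch: int, widths: tuple[int, ...],
                 latent_dim: int, cond_dim: int = 0, variational: bool = True):
        self.cond_dim = cond_dim
        self.in_ch = in_ch
        w0 = widths[0]
        self.stem = Conv2d(rng, in_ch + cond_dim, w0, 3, 1)
        self.stem_relu = ReLU()
        self.blocks = []
        prev = w0
        for w in widths:
            self.blocks.append(ResBlock(rng, prev, w, stride=2, cond_dim=cond_dim))
            prev = w
        self.pool = GlobalAvgPool()
        out_dim = 2 * latent_dim if variational else latent_dim
        self.head = Linear(rng, prev, out_dim)

    def params(self) -> list[Param]:
        out = self.stem.params() + self.head.params()
        for blk in self.blocks:
            out += blk.params()
        return out

    def forward(self, x: np.ndarray, cond: np.ndarray | None) -> np.ndarray:
        h = self.stem_relu.forward(self.stem.forward(
            _concat_cond(x, cond if self.cond_dim else None)))
        for blk in self.blocks:
            h = blk.forward(h, cond)
        return self.head.forward(self.pool.forward(h))

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        dh = self.pool.backward(self.head.backward(dy))
        dcond_total = None
        for blk in reversed(self.blocks):
            dh, dc = blk.backward(dh)
            if dc is not None:
                dcond_total = dc if dcond_total is None else dcond_total + dc
        dstem = self.stem.backward(self.stem_relu.backward(dh))
        if self.cond_dim:
            dx, dc = _split_cond_grad(dstem, self.in_ch)
            dcond_total = dc if dcond_total is None else dcond_total + dc
        else:
            dx = dstem
        return dx, dcond_total


class ConvNet2Encoder:
    """Plain two-layer strided conv encoder with a linear bottleneck."""

    def __init__(self, rng: np.random.Generator, in_ch: int, widths: tuple[int, int],
                 latent_dim: int, variational: bool = False):
        a, b = widths
        self.conv1 = Conv2d(rng, in_ch, a, 3, 2)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(rng, a, b, 3, 2)
        self.relu2 = ReLU()
        self.pool = GlobalAvgPool()
        self.head = Linear(rng, b, 2 * latent_dim if variational else latent_dim)

    def params(self) -> list[Param]:
        return (self.conv1.params() + self.conv2.params() + self.head.params())

    def forward(self, x: np.ndarray, cond=None) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.relu2.forward(self.conv2.forward(h))
        return self.head.forward(self.pool.forward(h))

    def backward(self, dy: np.ndarray):
        dh = self.pool.backward(self.head.backward(dy))
        dh = self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.relu2.backward(dh))))
        return dh, None


class ConvNet2Decoder:
    """Mirror of ConvNet2Encoder: bottleneck -> side/4 grid -> side."""

    def __init__(self, rng: np.random.Generator, out_ch: int, widths: tuple[int, int],
                 latent_dim: int, base_side: int):
        a, b = widths
        self.base_side = base_side
        self.entry = Linear(rng, latent_dim, base_side * base_side * b)
        self.relu0 = ReLU()
        self.up1 = Upsample2()
        self.conv1 = Conv2d(rng, b, a, 3, 1)
        self.relu1 = ReLU()
        self.up2 = Upsample2()
        self.conv2 = Conv2d(rng, a, out_ch, 3, 1)

    def params(self) -> list[Param]:
        return self.entry.params() + self.conv1.params() + self.conv2.params()

    def forward(self, z: np.ndarray, cond=None) -> np.ndarray:
        h = self.relu0.forward(self.entry.forward(z.astype(F32)))
        h = h.reshape(len(z), self.base_side, self.base_side, -1)
        h = self.relu1.forward(self.conv1.forward(self.up1.forward(h)))
        return self.conv2.forward(self.up2.forward(h))

    def backward(self, dy: np.ndarray):
        dh = self.up2.backward(self.conv2.backward(dy))
        dh = self.up1.backward(self.conv1.backward(self.relu1.backward(dh)))
        dz = self.entry.backward(self.relu0.backward(dh.reshape(len(dh), -1)))
        return dz, None


class ResDecoder:
    """Mirror of ResEncoder: latent -> side/8 grid -> upsampled to side."""

    def __init__(self, rng: np.random.Generator, out_ch: int, widths: tuple[int, ...],
                 latent_dim: int, base_side: int, cond_dim: int = 0):
        self.cond_dim = cond_dim
        self.base_side = base_side
        self.latent_dim = latent_dim
        rev = tuple(reversed(widths))          # deepest width first
        self.entry = Linear(rng, latent_dim + cond_dim, base_side * base_side * rev[0])
        self.entry_relu = ReLU()
        # mirror of the encoder: one up-block per residual stage except the
        # last upsample, which feeds the output conv (the stem's mirror)
        self.ups = []
        self.blocks = []
        prev = rev[0]
        for w in rev[1:]:
            self.ups.append(Upsample2())
            self.blocks.append(ResBlock(rng, prev, w, stride=1, cond_dim=cond_dim))
            prev = w
        self.out_up = Upsample2()
        self.out_conv = Conv2d(rng, prev, out_ch, 3, 1)

    def params(self) -> list[Param]:
        out = self.entry.params() + self.out_conv.params()
        for blk in self.blocks:
            out += blk.params()
        return out

    def forward(self, z: np.ndarray, cond: np.ndarray | None) -> np.ndarray:
        zin = z if not self.cond_dim else np.concatenate([z, cond], axis=1)
        h = self.entry_relu.forward(self.entry.forward(zin.astype(F32)))
        s = self.base_side
        h = h.reshape(len(z), s, s, -1)
        for up, blk in zip(self.ups, self.blocks):
            h = blk.forward(up.forward(h), cond)
        return self.out_conv.forward(self.out_up.forward(h))

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        dh = self.out_up.backward(self.out_conv.backward(dy))
        dcond_total = None
        for up, blk in zip(reversed(self.ups), reversed(self.blocks)):
            dh, dc = blk.backward(dh)
            if dc is not None:
                dcond_total = dc if dcond_total is None else dcond_total + dc
            dh = up.backward(dh)
        dflat = self.entry.backward(self.entry_relu.backward(dh.reshape(len(dh), -1)))
        if self.cond_dim:
            dz = dflat[:, : self.latent_dim]
            dcond_total = (
                dflat[:, self.latent_dim :]
                if dcond_total is None
                else dcond_total + dflat[:, self.latent_dim :]
            )
        else:
            dz = dflat
        return dz, dcond_total
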