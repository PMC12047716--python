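"""3D convolutional layers and the volumetric autoencoder networks.

Convolutions use 3x3x3 kernels with unit zero-padding (shape preserving);
down-sampling is 2x2x2 ceiling-mode max pooling, mirrored on the way up by
nearest-neighbour resizing to the exact pre-pool shape, so odd grid
dimensions round-trip losslessly (25 -> 13 -> 7 -> 13 -> 25).
"""

from __future__ import annotations

import numpy as np

from .core import Dense, Param, fan_in_uniform, relu, relu_grad

try:  # numba accelerates the im2col hot loop ~4x; NumPy path is equivalent
    import numba

    @numba.njit(cache=True)
    def _im2col_jit(xp, X, Y, Z, out):  # pragma: no cover - exercised via Conv3d
        B, C = xp.shape[0], xp.shape[1]
        for b in range(B):
            for c in range(C):
                for o in range(27):
                    i, j, k = o // 9, (o // 3) % 3, o % 3
                    n = 0
                    for x in range(X):
                        for y in range(Y):
                            for z in range(Z):
                                out[b, c * 27 + o, n] = xp[b, c, x + i, y + j, z + k]
                                n += 1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Conv3d:
    """3D convolution, kernel 3, stride 1, zero padding 1 (shape preserving)."""

    K = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * self.K**3
        self.W = Param(fan_in_uniform(rng, (c_out, c_in * self.K**3), fan_in))
        self.b = Param(fan_in_uniform(rng, (c_out,), fan_in))
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def _patches(x: np.ndarray) -> np.ndarray:
        """(B, C, X, Y, Z) -> (B, C*27, N) im2col, window offsets in C order."""
        B, C, X, Y, Z = x.shape
        N = X * Y * Z
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        out = np.empty((B, C * 27, N), dtype=x.dtype)
        if _HAVE_NUMBA and x.dtype in (np.float64, np.float32):
            _im2col_jit(np.ascontiguousarray(xp), X, Y, Z, out)
            return out
        patches = out.reshape(B, C, 27, N)
        for o in range(27):
            i, j, k = o // 9, (o // 3) % 3, o % 3
            patches[:, :, o, :] = xp[:, :, i:i + X, j:j + Y, k:k + Z].reshape(B, C, N)
        return out

    def forward(self, x: np.ndarray):
        B, C, X, Y, Z = x.shape
        patches = self._patches(x)
        out = np.matmul(self.W.value, patches) + self.b.value[:, None]
        return out.reshape(B, self.c_out, X, Y, Z), (patches, x.shape)

    def backward(self, dout: np.ndarray, cache):
        patches, in_shape = cache
        B, C, X, Y, Z = in_shape
        N = X * Y * Z
        d2 = dout.reshape(B, self.c_out, N)
        self.W.grad += np.matmul(d2, patches.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += d2.sum(axis=(0, 2))
        # input gradient = correlation of dout with the 180-degree-rotated,
        # channel-swapped kernel; reuse the im2col fast path
        Wb = (
            self.W.value.reshape(self.c_out, C, 27)[:, :, ::-1]
            .transpose(1, 0, 2)
            .reshape(C, self.c_out * 27)
        )
        dpatches = self._patches(dout)  # (B, c_out*27, N)
        dx = np.matmul(Wb, dpatches)
        return dx.reshape(B, C, X, Y, Z)


def _ceil_div(n: int) -> int:
    return (n + 1) // 2


class MaxPool3d:
    """2x2x2 max pooling, stride 2, ceiling mode (odd dims padded with -inf)."""

    def forward(self, x: np.ndarray):
        B, C, X, Y, Z = x.shape
        OX, OY, OZ = _ceil_div(X), _ceil_div(Y), _ceil_div(Z)
        xp = np.full((B, C, 2 * OX, 2 * OY, 2 * OZ), -np.inf, dtype=x.dtype)
        xp[:, :, :X, :Y, :Z] = x
        win = xp.reshape(B, C, OX, 2, OY, 2, OZ, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        win = win.reshape(B, C, OX, OY, OZ, 8)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        return out, (idx, x.shape)

    def backward(self, dout: np.ndarray, cache):
        idx, in_shape = cache
        B, C, X, Y, Z = in_shape
        OX, OY, OZ = dout.shape[2:]
        dwin = np.zeros((B, C, OX, OY, OZ, 8), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(B, C, OX, OY, OZ, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dxp = dwin.reshape(B, C, 2 * OX, 2 * OY, 2 * OZ)
        return dxp[:, :, :X, :Y, :Z]


class Upsample3d:
    """Nearest-neighbour resize to an explicit target shape."""

    def __init__(self, out_shape: tuple[int, int, int]):
        self.out_shape = out_shape

    def _indices(self, in_shape):
        return tuple(
            (np.arange(o) * n) // o for o, n in zip(self.out_shape, in_shape)
        )

    def forward(self, x: np.ndarray):
        ix, iy, iz = self._indices(x.shape[2:])
        out = x[:, :, ix[:, None, None], iy[None, :, None], iz[None, None, :]]
        return out, x.shape

    def backward(self, dout: np.ndarray, cache):
        in_shape = cache
        ix, iy, iz = self._indices(in_shape[2:])
        dx = np.zeros(in_shape, dtype=dout.dtype)
        np.add.at(
            dx,
            (
                slice(None),
                slice(None),
                ix[:, None, None],
                iy[None, :, None],
                iz[None, None, :],
            ),
            dout,
        )
        return dx


def _pool_schedule(grid: tuple[int, int, int], n_stages: int = 2):
    """Grid shapes after each ceiling-mode pooling stage."""
    shapes = [tuple(grid)]
    for _ in range(n_stages):
        shapes.append(tuple(_ceil_div(d) for d in shapes[-1]))
    return shapes


class CNNEncoderNet:
    """Volume -> latent: conv/pool stages narrowing to a flat projection."""

    def __init__(self, grid: tuple[int, int, int], d_latent: int,
                 channels: tuple[int, int, int] = (16, 32, 64),
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        c1, c2, c3 = channels
        self.grid = tuple(grid)
        self.shapes = _pool_schedule(grid)
        self.conv1 = Conv3d(2, c1, rng)
        self.pool1 = MaxPool3d()
        self.conv2 = Conv3d(c1, c2, rng)
        self.pool2 = MaxPool3d()
        self.conv3 = Conv3d(c2, c3, rng)
        self.flat_dim = c3 * int(np.prod(self.shapes[2]))
        self.proj = Dense(self.flat_dim, d_latent, rng)

    def params(self):
        return (self.conv1.params() + self.conv2.params() + self.conv3.params()
                + self.proj.params())

    def forward(self, v: np.ndarray):
        """v: (B, nx, ny, nz, 2) standardized volume tensor."""
        x = v.transpose(0, 4, 1, 2, 3)
        h1, c1 = self.conv1.forward(x)
        a1 = relu(h1)
        p1, cp1 = self.pool1.forward(a1)
        h2, c2 = self.conv2.forward(p1)
        a2 = relu(h2)
        p2, cp2 = self.pool2.forward(a2)
        h3, c3 = self.conv3.forward(p2)
        a3 = relu(h3)
        flat = a3.reshape(a3.shape[0], -1)
        z, cz = self.proj.forward(flat)
        return z, (c1, h1, cp1, c2, h2, cp2, c3, h3, a3.shape, cz)

    def backward(self, dz: np.ndarray, cache):
        c1, h1, cp1, c2, h2, cp2, c3, h3, a3_shape, cz = cache
        dflat = self.proj.backward(dz, cz)
        da3 = dflat.reshape(a3_shape)
        dh3 = relu_grad(da3, h3)
        dp2 = self.conv3.backward(dh3, c3)
        da2 = self.pool2.backward(dp2, cp2)
        dh2 = relu_grad(da2, h2)
        dp1 = self.conv2.backward(dh2, c2)
        da1 = self.pool1.backward(dp1, cp1)
        dh1 = relu_grad(da1, h1)
        dx = self.conv1.backward(dh1, c1)
        return dx.transpose(0, 2, 3, 4, 1)


class CNNDecoderNet:
    """Latent -> volume: dense seed, two upsample/conv stages, linear head."""

    def __init__(self, grid: tuple[int, int, int], d_latent: int,
                 channels: tuple[int, int, int] = (16, 32, 64),
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        c1, c2, c3 = channels
        self.grid = tuple(grid)
        shapes = _pool_schedule(grid)
        self.seed_shape = (c3,) + shapes[2]
        self.seed = Dense(d_latent, int(np.prod(self.seed_shape)), rng)
        self.up1 = Upsample3d(shapes[1])
        self.conv1 = Conv3d(c3, c2, rng)
        self.up2 = Upsample3d(shapes[0])
        self.conv2 = Conv3d(c2, c1, rng)
        self.head = Conv3d(c1, 2, rng)

    def params(self):
        return (self.seed.params() + self.conv1.params() + self.conv2.params()
                + self.head.params())

    def forward(self, z: np.ndarray):
        s, cs = self.seed.forward(z)
        a0 = relu(s)
        x = a0.reshape(z.shape[0], *self.seed_shape)
        u1, cu1 = self.up1.forward(x)
        h1, c1 = self.conv1.forward(u1)
        a1 = relu(h1)
        u2, cu2 = self.up2.forward(a1)
        h2, c2 = self.conv2.forward(u2)
        a2 = relu(h2)
        out, ch = self.head.forward(a2)
        v = out.transpose(0, 2, 3, 4, 1)  # (B, nx, ny, nz, 2)
        return v, (cs, s, cu1, c1, h1, cu2, c2, h2, ch)

    def backward(self, dv: np.ndarray, cache):
        cs, s, cu1, c1, h1, cu2, c2, h2, ch = cache
        dout = dv.transpose(0, 4, 1, 2, 3)
        da2 = self.head.backward(dout, ch)
        dh2 = relu_grad(da2, h2)
        du2 = self.conv2.backward(dh2, c2)
        da1 = self.up2.backward(du2, cu2)
        dh1 = relu_grad(da1, h1)
        du1 = self.conv1.backward(dh1, c1)
        dx = self.up1.backward(du1, cu1)
        da0 = dx.reshape(dx.shape[0], -1)
        ds = relu_grad(da0, s)
        dz = self.seed.backward(ds, cs)
        return dz
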