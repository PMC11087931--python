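"""Minimal NumPy compute engine for the compact 3D residual UNet.

Implements exactly the layers the segmenter needs — 3D convolution (im2col),
instance normalisation, ReLU, 2x average pooling, 2x nearest/trilinear
upsampling, residual blocks — each with a hand-written backward pass, plus the
Adam optimizer. Everything is float32, CPU-only and fully deterministic given
the initialisation RNG. Activations are laid out channel-first: (C, D, H, W).

This is not a general autodiff framework; layers are wired explicitly in
:class:`UNet3D`, whose ``backward`` traverses the graph in reverse.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

# ---------------------------------------------------------------------------
# low-level ops
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, D, H, W) -> (k^3 * C, D*H*W) patch matrix, offset-major, same-padding.

    Row block o (of k^3) holds the input shifted by spatial offset o; each block
    is one contiguous copy of a strided view, which keeps the transform cheap.
    """
    c, d, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    n = d * h * w
    col = np.empty((k**3, c, n), dtype=x.dtype)
    o = 0
    for a in range(k):
        for b in range(k):
            for cc in range(k):
                col[o] = xp[:, a : a + d, b : b + h, cc : cc + w].reshape(c, n)
                o += 1
    return col.reshape(k**3 * c, n)


class Conv3d:
    """Same-padded 3D convolution, kernel k in {1, 3}, stride 1.

    Weights are stored as (cout, cin * k^3) with the kernel offset minor
    (cin-major), matching the (cout, cin, k, k, k) tensor layout.
    """

    #: patch matrices above this many float32 elements are rebuilt in backward
    #: instead of cached from forward (keeps clinical-scale crops within memory)
    CACHE_LIMIT = 64 * 10**6

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._col: np.ndarray | None = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def _w_offset_major(self) -> np.ndarray:
        """(cout, cin*k^3) cin-major -> (cout, k^3*cin) offset-major."""
        k3 = self.k**3
        return np.ascontiguousarray(
            self.w.reshape(self.cout, self.cin, k3).transpose(0, 2, 1).reshape(self.cout, -1)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        spatial = x.shape[1:]
        if self.k == 1:
            out = self.w @ x.reshape(self.cin, -1) + self.b[:, None]
            return np.ascontiguousarray(out.reshape(self.cout, *spatial))
        col = _im2col(x, self.k)
        self._col = col if col.size <= self.CACHE_LIMIT else None
        out = self._w_offset_major() @ col + self.b[:, None]
        return np.ascontiguousarray(out.reshape(self.cout, *spatial))

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        spatial = x.shape[1:]
        gm = g.reshape(self.cout, -1)
        self.gb += gm.sum(axis=1)
        if self.k == 1:
            self.gw += gm @ x.reshape(self.cin, -1).T
            return np.ascontiguousarray((self.w.T @ gm).reshape(self.cin, *spatial))
        k3 = self.k**3
        col = self._col if self._col is not None else _im2col(x, self.k)
        self._col = None
        gw_om = gm @ col.T  # (cout, k^3*cin), offset-major
        self.gw += gw_om.reshape(self.cout, k3, self.cin).transpose(0, 2, 1).reshape(self.cout, -1)
        # grad wrt input = correlation of g with spatially flipped, transposed kernels
        w3 = self.w.reshape(self.cout, self.cin, self.k, self.k, self.k)
        wt = np.ascontiguousarray(
            w3[:, :, ::-1, ::-1, ::-1].reshape(self.cout, self.cin, k3).transpose(1, 2, 0)
        ).reshape(self.cin, -1)  # (cin, k^3*cout), offset-major over cout blocks... see colg
        colg = _im2col(np.ascontiguousarray(g), self.k)  # (k^3*cout, n)
        dx = wt @ colg
        return np.ascontiguousarray(dx.reshape(self.cin, *spatial))


class InstanceNorm:
    """Per-channel normalisation over the spatial volume, learnable affine."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.g = np.ones(c, dtype=np.float32)
        self.b = np.zeros(c, dtype=np.float32)
        self.gg = np.zeros_like(self.g)
        self.gb = np.zeros_like(self.b)
        self._xhat: np.ndarray | None = None
        self._istd: np.ndarray | None = None

    def params(self):
        return [(self.g, self.gg), (self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * istd
        self._xhat, self._istd = xhat, istd
        return (self.g[:, None] * xhat + self.b[:, None]).reshape(x.shape).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c = gy.shape[0]
        gyf = gy.reshape(c, -1)
        xhat = self._xhat
        self.gg += (gyf * xhat).sum(axis=1)
        self.gb += gyf.sum(axis=1)
        dxhat = gyf * self.g[:, None]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        dx = self._istd * (dxhat - m1 - xhat * m2)
        return dx.reshape(gy.shape).astype(np.float32)


class Identity:
    def params(self):
        return []

    def forward(self, x):
        return x

    def backward(self, g):
        return g


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, g):
        return np.where(self._mask, g, 0.0).astype(np.float32)


class AvgPool2:
    """2x2x2 average pooling; spatial dims must be even."""

    def params(self):
        return []

    def forward(self, x):
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ParameterError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        self._shape = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, g):
        c, d, h, w = self._shape
        out = np.broadcast_to(
            g[:, :, None, :, None, :, None] / 8.0,
            (c, d // 2, 2, h // 2, 2, w // 2, 2),
        )
        return np.ascontiguousarray(out).reshape(self._shape).astype(np.float32)


def _upsample_axis_linear(x: np.ndarray, axis: int) -> np.ndarray:
    """Double the length of ``axis`` by linear interpolation (half-voxel aligned)."""
    x = np.moveaxis(x, axis, -1)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)  # x[i-1], clamped
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)  # x[i+1], clamped
    even = 0.75 * x + 0.25 * left
    odd = 0.75 * x + 0.25 * right
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=np.float32)
    out[..., 0::2] = even
    out[..., 1::2] = odd
    return np.moveaxis(out, -1, axis)


def _upsample_axis_linear_T(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of :func:`_upsample_axis_linear`."""
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    dx = 0.75 * (ge + go)
    # even output j=2i took 0.25 * x[i-1] (clamped at i=0 -> x[0])
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 0] += 0.25 * ge[..., 0]
    # odd output j=2i+1 took 0.25 * x[i+1] (clamped at i=n-1 -> x[n-1])
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(dx.astype(np.float32), -1, axis)


class Upsample2:
    """2x upsampling, 'nearest' or 'trilinear' (separable linear per axis)."""

    def __init__(self, mode: str = "trilinear"):
        if mode not in ("nearest", "trilinear"):
            raise ParameterError(f"unknown upsampling mode {mode!r}")
        self.mode = mode

    def params(self):
        return []

    def forward(self, x):
        if self.mode == "nearest":
            return np.ascontiguousarray(
                x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
            )
        for axis in (1, 2, 3):
            x = _upsample_axis_linear(x, axis)
        return np.ascontiguousarray(x)

    def backward(self, g):
        if self.mode == "nearest":
            c, d, h, w = g.shape
            return (
                g.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6)).astype(np.float32)
            )
        for axis in (1, 2, 3):
            g = _upsample_axis_linear_T(g, axis)
        return np.ascontiguousarray(g)


class ResBlock:
    """conv3-norm-relu-conv3-norm with an additive skip (1x1 conv if widths differ),
    final ReLU. With ``residual=False`` the skip is dropped (plain block)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, residual: bool = True, norm: str = "instance"):
        def make_norm():
            return InstanceNorm(cout) if norm == "instance" else Identity()

        self.conv1 = Conv3d(cin, cout, 3, rng)
        self.n1 = make_norm()
        self.r1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, rng)
        self.n2 = make_norm()
        self.r2 = ReLU()
        self.residual = residual
        self.skip = Conv3d(cin, cout, 1, rng) if (residual and cin != cout) else None

    def params(self):
        ps = self.conv1.params() + self.n1.params() + self.conv2.params() + self.n2.params()
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def forward(self, x):
        h = self.r1.forward(self.n1.forward(self.conv1.forward(x)))
        h = self.n2.forward(self.conv2.forward(h))
        if self.residual:
            h = h + (self.skip.forward(x) if self.skip is not None else x)
        return self.r2.forward(h)

    def backward(self, g):
        g = self.r2.backward(g)
        dx_skip = 0.0
        if self.residual:
            dx_skip = self.skip.backward(g) if self.skip is not None else g
        g = self.conv2.backward(self.n2.backward(g))
        g = self.conv1.backward(self.n1.backward(self.r1.backward(g)))
        return g + dx_skip


class UNet3D:
    """Compact 3D residual UNet: encoder/decoder with skip concatenation.

    ``depth`` levels; level i works at 1/2^i resolution with ``base * 2^i``
    features; the deepest level is the bottleneck. Decoder levels upsample,
    concatenate the encoder feature map and apply a residual block; a final
    1x1x1 convolution maps to class logits.
    """

    def __init__(
        self,
        in_channels: int,
        num_classes: int,
        depth: int = 3,
        base_features: int = 16,
        residual: bool = True,
        norm: str = "instance",
        upsample: str = "trilinear",
        seed: int = 0,
    ):
        if depth < 2:
            raise ParameterError("UNet depth must be >= 2")
        rng = np.random.default_rng(seed)
        feats = [base_features * 2**i for i in range(depth)]
        self.depth = depth
        self.enc = []
        cin = in_channels
        for f in feats:
            self.enc.append(ResBlock(cin, f, rng, residual, norm))
            cin = f
        self.pools = [AvgPool2() for _ in range(depth - 1)]
        self.ups = [Upsample2(upsample) for _ in range(depth - 1)]
        self.dec = []
        for i in range(depth - 2, -1, -1):
            self.dec.append(ResBlock(feats[i + 1] + feats[i], feats[i], rng, residual, norm))
        self.head = Conv3d(feats[0], num_classes, 1, rng)

    def params(self):
        ps = []
        for block in [*self.enc, *self.dec, self.head]:
            ps += block.params()
        return ps

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(C_in, D, H, W) float32 -> (num_classes, D, H, W) logits."""
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < self.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._split = []
        for j, block in enumerate(self.dec):
            x = self.ups[j].forward(x)
            skip = skips[-(j + 1)]
            self._split.append(x.shape[0])
            x = np.concatenate([x, skip], axis=0)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        # dec[j] consumed skips[depth-2-j]; walking the decoder in reverse
        # (shallowest first) therefore yields skip gradients for levels 0, 1, ...
        skip_grads = []
        for j in range(len(self.dec) - 1, -1, -1):
            g = self.dec[j].backward(g)
            split = self._split[j]
            skip_grads.append(g[split:])
            g = self.ups[j].backward(np.ascontiguousarray(g[:split]))
        # encoder (deepest first)
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)


class Adam:
    """Standard Adam on a parameter list of (value, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
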