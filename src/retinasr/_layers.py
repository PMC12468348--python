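"""Neural-network building blocks on top of the :mod:`retinasr._tensor` engine.

Convolutions use im2col/col2im with BLAS matmuls; transposed convolution is
the exact adjoint of the strided convolution.  All modules take an explicit
``numpy.random.Generator`` for weight initialization so that model
construction is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = [
    "Parameter", "Module", "Conv2d", "ConvTranspose2d", "Linear",
    "BatchNorm2d", "Dropout", "Adam",
    "conv2d", "conv_transpose2d", "maxpool2d", "batch_norm",
    "bilinear_sample_taps", "fused_attention",
]


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C*kh*kw, OH*OW) patch matrix."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    cols = np.empty((B, C, kh, kw, OH, OW), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + OH * stride:stride,
                                 j:j + OW * stride:stride]
    return cols.reshape(B, C * kh * kw, OH * OW), (OH, OW)


def _im2col_flat(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (C*kh*kw, B*OH*OW) patch matrix for one big GEMM."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    cols = np.empty((C, kh, kw, B, OH, OW), dtype=x.dtype)
    xs = np.moveaxis(x, 0, 1)  # (C, B, Hp, Wp) view
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xs[:, :, i:i + OH * stride:stride,
                               j:j + OW * stride:stride]
    return cols.reshape(C * kh * kw, B * OH * OW), (OH, OW)


def _col2im_flat(cols: np.ndarray, B: int, out_hw: tuple, kh: int, kw: int,
                 stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col_flat`."""
    H, W = out_hw
    C = cols.shape[0] // (kh * kw)
    Hp, Wp = H + 2 * pad, W + 2 * pad
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    cols6 = cols.reshape(C, kh, kw, B, OH, OW)
    xp = np.zeros((C, B, Hp, Wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + OH * stride:stride,
               j:j + OW * stride:stride] += cols6[:, i, j]
    xp = np.moveaxis(xp, 0, 1)  # back to (B, C, Hp, Wp)
    if pad:
        return np.ascontiguousarray(xp[:, :, pad:-pad, pad:-pad])
    return np.ascontiguousarray(xp)


def _col2im(cols: np.ndarray, out_hw: tuple, kh: int, kw: int,
            stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (B,C,H,W)."""
    H, W = out_hw
    B = cols.shape[0]
    C = cols.shape[1] // (kh * kw)
    Hp, Wp = H + 2 * pad, W + 2 * pad
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    cols6 = cols.reshape(B, C, kh, kw, OH, OW)
    xp = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + OH * stride:stride,
               j:j + OW * stride:stride] += cols6[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of (B,C,H,W) with (F,C,kh,kw)."""
    B, C, H, W = x.data.shape
    F, Cw, kh, kw = weight.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C} vs weight {Cw}")
    cols, (OH, OW) = _im2col_flat(x.data, kh, kw, stride, padding)
    w2 = weight.data.reshape(F, C * kh * kw)
    # (F, CK) @ (CK, B*OH*OW): one large GEMM, then split the batch axis out
    out = np.matmul(w2, cols).reshape(F, B, OH, OW).swapaxes(0, 1)
    if bias is not None:
        out = out + bias.data.reshape(1, F, 1, 1)
    else:
        out = np.ascontiguousarray(out)
    del cols  # rebuilt in backward; retaining it here dominates memory

    def bw(g):
        gf = np.ascontiguousarray(np.moveaxis(g, 0, 1)).reshape(F, B * OH * OW)
        if weight.requires_grad:
            cols_b, _ = _im2col_flat(x.data, kh, kw, stride, padding)
            gw = np.matmul(gf, cols_b.T)
            del cols_b
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, gf)
            x._accum(_col2im_flat(dcols, B, (H, W), kh, kw, stride, padding))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, bw)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2, padding: int = 0) -> Tensor:
    """Transposed convolution; weight is (C_in, C_out, kh, kw).

    Output side = (H - 1) * stride - 2 * padding + kh.
    """
    B, C, H, W = x.data.shape
    Cw, F, kh, kw = weight.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C} vs weight {Cw}")
    OH = (H - 1) * stride - 2 * padding + kh
    OW = (W - 1) * stride - 2 * padding + kw
    wr = weight.data.reshape(C, F * kh * kw)
    cols = np.matmul(wr.T, x.data.reshape(B, C, H * W))
    out = _col2im(cols, (OH, OW), kh, kw, stride, padding)
    if bias is not None:
        out = out + bias.data.reshape(1, F, 1, 1)

    def bw(g):
        gcols, _ = _im2col(g, kh, kw, stride, padding)
        if x.requires_grad:
            x._accum(np.matmul(wr, gcols).reshape(B, C, H, W))
        if weight.requires_grad:
            gw = np.matmul(x.data.reshape(B, C, H * W),
                           np.swapaxes(gcols, 1, 2)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, bw)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling with pool size == stride == k."""
    B, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by pool {k}")
    Ho, Wo = H // k, W // k
    xr = x.data.reshape(B, C, Ho, k, Wo, k).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(B, C, Ho, Wo, k * k)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gr = np.zeros((B, C, Ho, Wo, k * k), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(B, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(B, C, H, W)
        x._accum(gx)

    return Tensor._make(out, (x,), bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (B, H, W); mutates running stats."""
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    sh = (1, -1, 1, 1)
    xhat = (x.data - mu.reshape(sh)) * inv_std.reshape(sh)
    out = gamma.data.reshape(sh) * xhat + beta.data.reshape(sh)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gmean = g.mean(axis=axes).reshape(sh)
                gxhat_mean = (g * xhat).sum(axis=axes).reshape(sh) / n
                dx = (gamma.data * inv_std).reshape(sh) * \
                    (g - gmean - xhat * gxhat_mean)
            else:
                dx = (gamma.data * inv_std).reshape(sh) * g
            x._accum(dx.astype(x.data.dtype))

    return Tensor._make(out.astype(x.data.dtype), (x, gamma, beta), bw)


def fused_attention(q: Tensor, k: Tensor, v: Tensor,
                    chunk: int = 256) -> Tensor:
    """softmax(q @ k) @ v computed in query chunks.

    q (B,N,E), k (B,E,N), v (B,N,C) -> (B,N,C).  The N x N affinity matrix
    is never fully materialized: forward streams over row chunks and
    backward recomputes them, which keeps memory O(chunk * N) while staying
    exactly equal to the dense computation.
    """
    B, N, E = q.data.shape
    C = v.data.shape[2]
    out = np.empty((B, N, C), dtype=q.data.dtype)
    for s in range(0, N, chunk):
        sl = slice(s, min(s + chunk, N))
        S = np.matmul(q.data[:, sl], k.data)
        S -= S.max(axis=-1, keepdims=True)
        np.exp(S, out=S)
        S *= np.reciprocal(S.sum(axis=-1, keepdims=True))
        out[:, sl] = np.matmul(S, v.data)

    def bw(g):
        dq = np.zeros_like(q.data) if q.requires_grad else None
        dk = np.zeros_like(k.data) if k.requires_grad else None
        dv = np.zeros_like(v.data) if v.requires_grad else None
        vT = np.swapaxes(v.data, -1, -2)
        for s in range(0, N, chunk):
            sl = slice(s, min(s + chunk, N))
            S = np.matmul(q.data[:, sl], k.data)
            S -= S.max(axis=-1, keepdims=True)
            np.exp(S, out=S)
            S *= np.reciprocal(S.sum(axis=-1, keepdims=True))
            if dv is not None:
                dv += np.matmul(np.swapaxes(S, -1, -2), g[:, sl])
            dA = np.matmul(g[:, sl], vT)
            dA -= (dA * S).sum(axis=-1, keepdims=True)
            dA *= S
            if dq is not None:
                dq[:, sl] = np.matmul(dA, np.swapaxes(k.data, -1, -2))
            if dk is not None:
                dk += np.matmul(np.swapaxes(q.data[:, sl], -1, -2), dA)
        if dq is not None:
            q._accum(dq)
        if dk is not None:
            k._accum(dk)
        if dv is not None:
            v._accum(dv)

    return Tensor._make(out, (q, k, v), bw)


def bilinear_sample_taps(x: Tensor, py: np.ndarray, px: np.ndarray):
    """Bilinearly sample (B,C,H,W) at K per-position tap locations.

    ``py``/``px`` are (B, K, H*W) absolute fractional coordinates.  Points
    outside the raster read zero.  Returns the sampled Tensor (B, C, K, H*W)
    plus the partial derivatives of each sample w.r.t. the coordinates
    (arrays of shape (B, K, H*W) after channel contraction happens in the
    caller's backward) packaged as a closure-friendly tuple.
    """
    B, C, H, W = x.data.shape
    K = py.shape[1]
    HW = py.shape[2]
    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    fy = (py - y0).astype(x.data.dtype)
    fx = (px - x0).astype(x.data.dtype)
    xflat = x.data.reshape(B, C, H * W)

    vals = []      # 4 neighbour values (B,C,K,HW), zeroed outside
    idxs = []      # clipped flat indices (B,K,HW)
    valids = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yi = y0 + dy
        xi = x0 + dx
        valid = ((yi >= 0) & (yi < H) & (xi >= 0) & (xi < W))
        yc = np.clip(yi, 0, H - 1)
        xc = np.clip(xi, 0, W - 1)
        flat = (yc * W + xc).reshape(B, 1, K * HW)
        v = np.take_along_axis(xflat, np.broadcast_to(flat, (B, C, K * HW)),
                               axis=2).reshape(B, C, K, HW)
        v *= valid[:, None, :, :]
        vals.append(v)
        idxs.append((yc * W + xc))
        valids.append(valid.astype(x.data.dtype))
    v00, v01, v10, v11 = vals
    w00 = ((1 - fy) * (1 - fx))[:, None]
    w01 = ((1 - fy) * fx)[:, None]
    w10 = (fy * (1 - fx))[:, None]
    w11 = (fy * fx)[:, None]
    sampled = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11

    # derivatives of the sample w.r.t. py / px (per channel, contracted later)
    dsdy = (1 - fx)[:, None] * (v10 - v00) + fx[:, None] * (v11 - v01)
    dsdx = (1 - fy)[:, None] * (v01 - v00) + fy[:, None] * (v11 - v10)

    def scatter_dx(dsampled: np.ndarray) -> np.ndarray:
        """Accumulate gradient w.r.t. x given d(sampled) of (B,C,K,HW)."""
        dx = np.zeros((B, C, H * W), dtype=x.data.dtype)
        weights = (w00, w01, w10, w11)
        for n in range(4):
            contrib = dsampled * weights[n] * valids[n][:, None]
            idx = idxs[n].reshape(B, K * HW)
            cfl = contrib.reshape(B, C, K * HW)
            for b in range(B):
                ib = idx[b]
                for c in range(C):
                    dx[b, c] += np.bincount(ib, weights=cfl[b, c],
                                            minlength=H * W)
        return dx.reshape(B, C, H, W)

    return sampled, dsdy, dsdx, scatter_dx


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        seen = set()
        for name, mod in self._named_modules(""):
            for attr, val in mod.__dict__.items():
                if isinstance(val, Parameter) and id(val) not in seen:
                    seen.add(id(val))
                    yield (f"{name}.{attr}" if name else attr), val

    def _named_modules(self, prefix):
        yield prefix, self
        for attr, v in self.__dict__.items():
            sub = f"{prefix}.{attr}" if prefix else attr
            if isinstance(v, Module):
                yield from v._named_modules(sub)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{sub}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self._named_modules(""):
            if isinstance(mod, BatchNorm2d):
                state[f"{name}.running_mean"] = mod.running_mean.copy()
                state[f"{name}.running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name]).reshape(p.data.shape) \
                .astype(p.data.dtype)
        for name, mod in self._named_modules(""):
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.asarray(state[f"{name}.running_mean"]) \
                    .astype(mod.running_mean.dtype)
                mod.running_var = np.asarray(state[f"{name}.running_var"]) \
                    .astype(mod.running_var.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 dtype=np.float32, zero_init: bool = False):
        super().__init__()
        self.stride, self.padding = stride, padding
        shape = (c_out, c_in, k, k)
        if zero_init:
            self.weight = Parameter(np.zeros(shape, dtype=dtype))
        else:
            self.weight = Parameter(_he_init(rng, shape, c_in * k * k, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 2, padding: int = 0, bias: bool = True,
                 dtype=np.float32):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_he_init(rng, (c_in, c_out, k, k),
                                         c_in * k * k, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias,
                                self.stride, self.padding)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (n_in, n_out), n_in, dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, c: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self.freeze_stats = False   # train with running stats (fine-tune mode)

    def forward(self, x: Tensor) -> Tensor:
        training = self.training and not self.freeze_stats
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, training,
                          self.momentum, self.eps)


class Dropout(Module):
    """Inverted dropout; active only in training mode and needs an rng.

    With ``spatial`` the mask is drawn per channel of a (B,C,H,W) map
    (SpatialDropout), which avoids the train/eval variance shift that
    elementwise masks induce in downstream convolutions.
    """

    def __init__(self, p: float, spatial: bool = False):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1): {p}")
        self.p = p
        self.spatial = spatial

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        shape = x.data.shape
        if self.spatial and x.data.ndim == 4:
            shape = shape[:2] + (1, 1)
        mask = (rng.random(shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(mask / (1.0 - self.p))


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = None):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            sq = sum(float((p.grad ** 2).sum())
                     for p in self.params if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
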