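"""Numeric primitives of the hybrid local-global super-resolution block.

Each primitive exists in two forms: a trainable :class:`~retinasr._layers.Module`
operating on batched tensors, and a functional wrapper operating on a single
(C, H, W) feature map, used directly by the oracle tests.  Both forms share
one implementation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._layers import (Conv2d, Linear, Module, Parameter, bilinear_sample_taps,
                      fused_attention)
from ._tensor import Tensor, no_grad

__all__ = [
    "FeatureMap", "DeformableKernelParams", "NonLocalConfig", "PatchSequence",
    "BASE_OFFSETS", "deformable_conv", "learn_offsets", "pointwise_conv",
    "nonlocal_block", "patchify", "unpatchify", "patch_transformer",
    "pixel_shuffle", "pixel_unshuffle",
    "DeformableConv2d", "OffsetPredictor", "NonLocalBlock", "PatchTransformer",
]

# Nine base offsets of the 3x3 sampling grid, row-major (dy, dx).
BASE_OFFSETS = tuple((dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1))


@dataclasses.dataclass
class FeatureMap:
    values: np.ndarray  # (C, H, W)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("FeatureMap must be 3-D (C, H, W)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap contains non-finite values")


def _as_chw(features) -> np.ndarray:
    arr = features.values if isinstance(features, FeatureMap) else np.asarray(features)
    if arr.ndim != 3:
        raise ValueError(f"expected (C, H, W) features, got shape {arr.shape}")
    return arr


@dataclasses.dataclass
class DeformableKernelParams:
    """Parameters of one 3x3 modulated deformable convolution.

    weights     -- (C_out, C_in, 9) per-tap kernel weights
    offsets     -- (18, H, W) learned fractional displacements, tap-major
                   (dy_1, dx_1, dy_2, dx_2, ...)
    modulations -- (9, H, W) per-tap gates in [0, 1]
    base_offsets-- 9 integer (dy, dx) pairs; defaults to the 3x3 grid
    """

    weights: np.ndarray
    offsets: np.ndarray
    modulations: np.ndarray
    base_offsets: tuple = BASE_OFFSETS
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        self.offsets = np.asarray(self.offsets)
        self.modulations = np.asarray(self.modulations)
        if len(self.base_offsets) != 9:
            raise ValueError("base offset set must contain exactly 9 taps")
        if self.weights.ndim != 3 or self.weights.shape[2] != 9:
            raise ValueError("weights must have shape (C_out, C_in, 9)")
        if self.offsets.ndim != 3 or self.offsets.shape[0] != 18:
            raise ValueError("offsets must have shape (18, H, W)")
        if self.modulations.ndim != 3 or self.modulations.shape[0] != 9:
            raise ValueError("modulations must have shape (9, H, W)")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets contain non-finite values")
        if self.modulations.min() < 0 or self.modulations.max() > 1:
            raise ValueError("modulations must lie in [0, 1]")


# ---------------------------------------------------------------------------
# modulated deformable convolution
# ---------------------------------------------------------------------------

def deform_conv_core(x: Tensor, weight: Tensor, bias: Tensor | None,
                     offsets: Tensor, modulation: Tensor,
                     base_offsets=BASE_OFFSETS) -> Tensor:
    """y(r) = sum_k w_k * z(r + q_k + delta_k) * gamma_k with bilinear
    sampling; zero outside the raster; spatial dims preserved.

    x (B,C,H,W); weight (F,C,9); offsets (B,18,H,W); modulation (B,9,H,W).
    """
    B, C, H, W = x.data.shape
    F = weight.data.shape[0]
    HW = H * W
    K = 9
    q = np.asarray(base_offsets, dtype=x.data.dtype)  # (9, 2) as (dy, dx)
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    base_y = ii.reshape(1, 1, HW) + q[:, 0].reshape(1, K, 1)
    base_x = jj.reshape(1, 1, HW) + q[:, 1].reshape(1, K, 1)
    off = offsets.data.reshape(B, K, 2, HW)
    py = (base_y + off[:, :, 0]).astype(np.float64)
    px = (base_x + off[:, :, 1]).astype(np.float64)

    sampled, dsdy, dsdx, scatter_dx = bilinear_sample_taps(x, py, px)
    mod = modulation.data.reshape(B, 1, K, HW)
    cols = (sampled * mod).reshape(B, C * K, HW)
    w2 = weight.data.reshape(F, C * K)
    out = np.matmul(w2, cols).reshape(B, F, H, W)
    if bias is not None:
        out = out + bias.data.reshape(1, F, 1, 1)

    def bw(g):
        g2 = g.reshape(B, F, HW)
        if weight.requires_grad:
            gw = np.matmul(g2, np.swapaxes(cols, 1, 2)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        need_rest = x.requires_grad or offsets.requires_grad or \
            modulation.requires_grad
        if not need_rest:
            return
        dcols = np.matmul(w2.T, g2).reshape(B, C, K, HW)
        if modulation.requires_grad:
            dmod = (dcols * sampled).sum(axis=1)  # (B, K, HW)
            modulation._accum(dmod.reshape(B, K, H, W))
        dsamp = dcols * mod
        if x.requires_grad:
            x._accum(scatter_dx(dsamp))
        if offsets.requires_grad:
            dpy = (dsamp * dsdy).sum(axis=1)  # (B, K, HW)
            dpx = (dsamp * dsdx).sum(axis=1)
            doff = np.stack([dpy, dpx], axis=2).reshape(B, 2 * K, H, W)
            offsets._accum(doff)

    parents = [p for p in (x, weight, bias, offsets, modulation)
               if p is not None]
    return Tensor._make(out, parents, bw)


class OffsetPredictor(Module):
    """3x3 convolution emitting 18 offset + 9 modulation channels.

    Zero-initialized so training starts from a plain (modulation 0.5)
    convolution with an undisplaced grid.
    """

    def __init__(self, c_in: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(c_in, 27, 3, rng, padding=1, dtype=dtype,
                           zero_init=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        raw = self.conv(x)
        B, _, H, W = raw.data.shape
        r = raw.reshape(B, 27, H * W)
        # split channels via reshape: first 18 offsets, last 9 modulations
        offs = _narrow(r, 1, 0, 18).reshape(B, 18, H, W)
        mods = _narrow(r, 1, 18, 9).reshape(B, 9, H, W).sigmoid()
        return offs, mods


def _narrow(t: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Differentiable slice along one axis."""
    sl = [slice(None)] * t.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def bw(g):
        full = np.zeros_like(t.data)
        full[sl] = g
        t._accum(full)
    return Tensor._make(t.data[sl], (t,), bw)


class DeformableConv2d(Module):
    """3x3 modulated deformable convolution with a learned offset predictor."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / (c_in * 9))
        self.weight = Parameter((rng.standard_normal((c_out, c_in, 9)) * std)
                                .astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.predictor = OffsetPredictor(c_in, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        offs, mods = self.predictor(x)
        return deform_conv_core(x, self.weight, self.bias, offs, mods)


def deformable_conv(features, params: DeformableKernelParams) -> np.ndarray:
    """Functional single-map modulated deformable convolution."""
    arr = _as_chw(features)
    if arr.shape[1] < 3 or arr.shape[2] < 3:
        raise ValueError("deformable convolution needs H, W >= 3")
    with no_grad():
        out = deform_conv_core(
            Tensor(arr[None]), Tensor(params.weights),
            None if params.bias is None else Tensor(params.bias),
            Tensor(params.offsets[None]), Tensor(params.modulations[None]),
            base_offsets=params.base_offsets)
    return out.data[0]


def learn_offsets(features, predictor: OffsetPredictor):
    """Predict (offsets (18,H,W), modulations (9,H,W)) for one feature map."""
    arr = _as_chw(features)
    with no_grad():
        offs, mods = predictor(Tensor(arr[None]))
    return offs.data[0], mods.data[0]


# ---------------------------------------------------------------------------
# point-wise convolution
# ---------------------------------------------------------------------------

def pointwise_conv(features, weights, bias=None) -> np.ndarray:
    """Per-pixel linear map across channels: (C_in,H,W) x (C_out,C_in)."""
    arr = _as_chw(features)
    w = np.asarray(weights)
    if w.ndim != 2:
        raise ValueError("pointwise weights must be a (C_out, C_in) matrix")
    if w.shape[1] != arr.shape[0]:
        raise ValueError(
            f"channel mismatch: features {arr.shape[0]} vs weights {w.shape[1]}")
    out = np.tensordot(w, arr, axes=([1], [0]))
    if bias is not None:
        out = out + np.asarray(bias).reshape(-1, 1, 1)
    return out


# ---------------------------------------------------------------------------
# non-local (inter-pixel) attention
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NonLocalConfig:
    embed_channels: int | None = None   # None -> max(C // 2, 1)
    residual: bool = True


class NonLocalBlock(Module):
    """Embedded-Gaussian non-local attention.

    Pairwise affinity F(x_i, x_j) = exp(theta(x_i) . phi(x_j)) with 1x1-conv
    embeddings; value signal G is a 1x1 convolution at full channel width so
    that the pre-residual output is a convex combination of G(x_j); the
    per-row softmax denominator realizes the normalizer.  A residual input
    addition wraps the block (toggleable).
    """

    def __init__(self, c: int, rng: np.random.Generator,
                 config: NonLocalConfig | None = None, dtype=np.float32):
        super().__init__()
        config = config or NonLocalConfig()
        e = config.embed_channels or max(c // 2, 1)
        self.residual = config.residual
        self.theta = Conv2d(c, e, 1, rng, bias=False, dtype=dtype)
        self.phi = Conv2d(c, e, 1, rng, bias=False, dtype=dtype)
        self.g = Conv2d(c, c, 1, rng, bias=False, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        HW = H * W
        th = self.theta(x).reshape(B, -1, HW).swapaxes(1, 2)   # (B, HW, E)
        ph = self.phi(x).reshape(B, -1, HW)                    # (B, E, HW)
        gv = self.g(x).reshape(B, C, HW).swapaxes(1, 2)        # (B, HW, C)
        # streamed softmax(th @ ph) @ gv: affinity rows sum to 1
        out = fused_attention(th, ph, gv).swapaxes(1, 2).reshape(B, C, H, W)
        if self.residual:
            out = out + x
        return out

    def affinity(self, x: Tensor) -> np.ndarray:
        """Dense (HW x HW) affinity matrix (diagnostic, small inputs only)."""
        B, C, H, W = x.data.shape
        HW = H * W
        with no_grad():
            th = self.theta(x).reshape(B, -1, HW).swapaxes(1, 2)
            ph = self.phi(x).reshape(B, -1, HW)
            return (th @ ph).softmax(axis=-1).data


def nonlocal_block(features, block: NonLocalBlock) -> np.ndarray:
    """Apply a non-local block to one (C, H, W) map."""
    arr = _as_chw(features)
    with no_grad():
        out = block(Tensor(arr[None]))
    return out.data[0]


# ---------------------------------------------------------------------------
# patch sequence + transformer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PatchSequence:
    tokens: np.ndarray          # (num_tokens, token_dim)
    patch_side: int
    grid: tuple[int, int]
    channels: int

    def __post_init__(self):
        gh, gw = self.grid
        if self.tokens.shape[0] != gh * gw:
            raise ValueError("token count inconsistent with grid")
        if self.tokens.shape[1] != self.channels * self.patch_side ** 2:
            raise ValueError("token dim inconsistent with channels * p^2")


def _patchify_data(arr: np.ndarray, p: int) -> np.ndarray:
    C, H, W = arr.shape[-3:]
    gh, gw = H // p, W // p
    lead = arr.shape[:-3]
    x = arr.reshape(*lead, C, gh, p, gw, p)
    nd = x.ndim
    # -> (..., gh, gw, C, p, p): tokens flatten channels then rows then cols
    x = np.moveaxis(x, (nd - 4, nd - 2), (nd - 5, nd - 4))
    return x.reshape(*lead, gh * gw, C * p * p)


def patchify(features, patch_side: int) -> PatchSequence:
    arr = _as_chw(features)
    C, H, W = arr.shape
    if H % patch_side or W % patch_side:
        raise ValueError(
            f"spatial dims ({H},{W}) not divisible by patch side {patch_side}")
    tokens = _patchify_data(arr, patch_side)
    return PatchSequence(tokens=tokens, patch_side=patch_side,
                         grid=(H // patch_side, W // patch_side), channels=C)


def unpatchify(seq: PatchSequence) -> np.ndarray:
    p, (gh, gw), C = seq.patch_side, seq.grid, seq.channels
    x = seq.tokens.reshape(gh, gw, C, p, p)
    x = np.moveaxis(x, (2, 3), (0, 2))   # -> (C, gh, p, gw, p)
    return x.reshape(C, gh * p, gw * p)


class _LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        d = x - mu
        var = (d * d).mean(axis=-1, keepdims=True)
        return self.gamma * (d * ((var + self.eps) ** -0.5)) + self.beta


class _MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if dim % heads:
            raise ValueError(f"token dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.dh = dim // heads
        self.wq = Linear(dim, dim, rng, dtype=dtype)
        self.wk = Linear(dim, dim, rng, dtype=dtype)
        self.wv = Linear(dim, dim, rng, dtype=dtype)
        self.proj = Linear(dim, dim, rng, dtype=dtype)

    def _split(self, t: Tensor, B: int, N: int) -> Tensor:
        return t.reshape(B, N, self.heads, self.dh).transpose((0, 2, 1, 3))

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.data.shape
        q = self._split(self.wq(x), B, N)
        k = self._split(self.wk(x), B, N)
        v = self._split(self.wv(x), B, N)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, N, D)
        return self.proj(out)

    def attention_rows(self, x: Tensor) -> np.ndarray:
        """Per-head attention matrix (diagnostic; used by tests)."""
        B, N, D = x.data.shape
        with no_grad():
            q = self._split(self.wq(x), B, N)
            k = self._split(self.wk(x), B, N)
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
            return scores.softmax(axis=-1).data


class _TransformerLayer(Module):
    """Pre-norm encoder layer: x + MHSA(LN(x)); x + FF(LN(x)); FF = 2x dim."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.ln1 = _LayerNorm(dim, dtype=dtype)
        self.attn = _MultiHeadSelfAttention(dim, heads, rng, dtype=dtype)
        self.ln2 = _LayerNorm(dim, dtype=dtype)
        self.ff1 = Linear(dim, 2 * dim, rng, dtype=dtype)
        self.ff2 = Linear(2 * dim, dim, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class PatchTransformer(Module):
    """Two pre-norm transformer encoder layers, four heads, no positional
    encoding (token count and dim preserved)."""

    def __init__(self, dim: int, rng: np.random.Generator, heads: int = 4,
                 n_layers: int = 2, dtype=np.float32):
        super().__init__()
        self.layers = [_TransformerLayer(dim, heads, rng, dtype=dtype)
                       for _ in range(n_layers)]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def patch_transformer(seq: PatchSequence, model: PatchTransformer) -> PatchSequence:
    with no_grad():
        out = model(Tensor(seq.tokens[None]))
    return dataclasses.replace(seq, tokens=out.data[0])


# ---------------------------------------------------------------------------
# pixel shuffle
# ---------------------------------------------------------------------------

def _pixel_shuffle_t(x: Tensor, r: int) -> Tensor:
    B, C, H, W = x.data.shape
    if C % (r * r):
        raise ValueError(f"channels {C} not divisible by r^2 = {r * r}")
    co = C // (r * r)
    return (x.reshape(B, co, r, r, H, W)
            .transpose((0, 1, 4, 2, 5, 3))
            .reshape(B, co, H * r, W * r))


def pixel_shuffle(features, r: int) -> np.ndarray:
    """(C, H, W) -> (C / r^2, rH, rW) sub-pixel rearrangement."""
    arr = _as_chw(features)
    with no_grad():
        return _pixel_shuffle_t(Tensor(arr[None]), r).data[0]


def pixel_unshuffle(features, r: int) -> np.ndarray:
    arr = _as_chw(features)
    C, H, W = arr.shape
    if H % r or W % r:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by {r}")
    x = arr.reshape(C, H // r, r, W // r, r)
    x = np.moveaxis(x, (2, 4), (1, 2))
    return x.reshape(C * r * r, H // r, W // r)
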