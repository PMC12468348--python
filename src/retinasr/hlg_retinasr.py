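"""Super-resolution networks: the hybrid local-global model and the three-
stage SRCNN baseline, both trained with pixelwise MSE.

The hybrid model is residual by construction: its final 1x1 reconstruction
convolution is zero-initialized, so an untrained network reproduces the
bicubic interpolation of its input exactly and training learns a correction
on top of it.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from scipy.ndimage import zoom as _nd_zoom

from ._layers import Adam, Conv2d, ConvTranspose2d, Module
from ._tensor import Tensor, no_grad
from .fundus_io import GrayImage
from .sr_ops import (DeformableConv2d, NonLocalBlock, NonLocalConfig,
                     PatchTransformer, _pixel_shuffle_t)

__all__ = [
    "SRConfig", "TrainSRConfig", "SRTrainState", "HLGBlockOutput",
    "AggregatedFeatures", "PreliminaryFeatures", "HLGBlock", "FeatureReuse",
    "Reconstructor", "HLGRetinaSR", "SRCNN", "bicubic_upsample", "mse_loss",
    "train_sr", "enhance_image", "save_checkpoint", "load_checkpoint",
    "build_sr_model",
]


@dataclasses.dataclass
class SRConfig:
    n_blocks: int = 4
    channels: int = 32
    patch_side: int = 2
    scale: int = 2
    psgm_deformable: bool = True
    ipgm_residual: bool = True
    expansion: int = 2          # channel expansion of the preliminary stage
    dtype: str = "float32"

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclasses.dataclass
class TrainSRConfig:
    epochs: int = 5
    batch_size: int = 8
    lr: float = 1e-3
    crop_size: int | None = None   # LR-side crop; None trains on full images


@dataclasses.dataclass
class SRTrainState:
    loss_history: list[float]
    epoch: int
    seed: int

    def __post_init__(self):
        if any(not np.isfinite(v) or v < 0 for v in self.loss_history):
            raise ValueError("loss history must be finite and nonnegative")


@dataclasses.dataclass
class HLGBlockOutput:
    alm: np.ndarray
    ipgm: np.ndarray
    psgm: np.ndarray
    fused: np.ndarray


@dataclasses.dataclass
class AggregatedFeatures:
    m: np.ndarray


def bicubic_upsample(arr: np.ndarray, r: int) -> np.ndarray:
    """Cubic-spline x r upsampling of a 2-D raster."""
    return _nd_zoom(arr.astype(np.float64), r, order=3, mode="reflect",
                    grid_mode=True, prefilter=True)


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class PreliminaryFeatures(Module):
    """pw(1 -> eC) -> 3x3 conv (eC -> eC) -> pw(eC -> C); dims preserved."""

    def __init__(self, channels: int, rng, expansion: int = 2,
                 dtype=np.float32):
        super().__init__()
        e = expansion * channels
        self.expand = Conv2d(1, e, 1, rng, dtype=dtype)
        self.spatial = Conv2d(e, e, 3, rng, padding=1, dtype=dtype)
        self.merge = Conv2d(e, channels, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.merge(self.spatial(self.expand(x)))


def _patchify_t(x: Tensor, p: int) -> Tensor:
    B, C, H, W = x.data.shape
    gh, gw = H // p, W // p
    return (x.reshape(B, C, gh, p, gw, p)
            .transpose((0, 2, 4, 1, 3, 5))
            .reshape(B, gh * gw, C * p * p))


def _unpatchify_t(x: Tensor, C: int, H: int, W: int, p: int) -> Tensor:
    B = x.data.shape[0]
    gh, gw = H // p, W // p
    return (x.reshape(B, gh, gw, C, p, p)
            .transpose((0, 3, 1, 4, 2, 5))
            .reshape(B, C, H, W))


class HLGBlock(Module):
    """Adaptive local + inter-pixel global + patch-scope global branches,
    concatenated with the block input and fused by a point-wise convolution;
    an input-to-output residual skip wraps the block."""

    def __init__(self, channels: int, rng, patch_side: int = 2,
                 psgm_deformable: bool = True, ipgm_residual: bool = True,
                 dtype=np.float32):
        super().__init__()
        c = channels
        self.patch_side = patch_side
        self.alm_deform = DeformableConv2d(c, c, rng, dtype=dtype)
        self.alm_pw = Conv2d(c, c, 1, rng, dtype=dtype)
        self.ipgm = NonLocalBlock(c, rng, NonLocalConfig(residual=ipgm_residual),
                                  dtype=dtype)
        self.psgm_tr = PatchTransformer(c * patch_side ** 2, rng, dtype=dtype)
        self.psgm_deform = (DeformableConv2d(c, c, rng, dtype=dtype)
                            if psgm_deformable else None)
        self.fuse = Conv2d(4 * c, c, 1, rng, dtype=dtype)

    def branches(self, x: Tensor):
        B, C, H, W = x.data.shape
        p = self.patch_side
        if H % p or W % p:
            raise ValueError(f"spatial dims ({H},{W}) not divisible by patch "
                             f"side {p}")
        alm = self.alm_pw(self.alm_deform(x))
        ipgm = self.ipgm(x)
        psgm = _unpatchify_t(self.psgm_tr(_patchify_t(x, p)), C, H, W, p)
        if self.psgm_deform is not None:
            psgm = self.psgm_deform(psgm)
        return alm, ipgm, psgm

    def forward(self, x: Tensor) -> Tensor:
        alm, ipgm, psgm = self.branches(x)
        fused = self.fuse(Tensor.concat([alm, ipgm, psgm, x], axis=1))
        return fused + x


class FeatureReuse(Module):
    """Compress each block output with a 1x1 conv, concatenate, fuse with a
    final 1x1 conv back to the base channel count."""

    def __init__(self, channels: int, n_blocks: int, rng, dtype=np.float32,
                 compress_channels: int | None = None):
        super().__init__()
        half = compress_channels or max(channels // 2, 1)
        self.compress = [Conv2d(channels, half, 1, rng, dtype=dtype)
                         for _ in range(n_blocks)]
        self.fuse = Conv2d(half * n_blocks, channels, 1, rng, dtype=dtype)

    def forward(self, block_outputs: list[Tensor]) -> Tensor:
        if len(block_outputs) != len(self.compress):
            raise ValueError(
                f"expected {len(self.compress)} block outputs, "
                f"got {len(block_outputs)}")
        shapes = {t.data.shape for t in block_outputs}
        if len(shapes) != 1:
            raise ValueError(f"block outputs disagree in shape: {shapes}")
        parts = [conv(t) for conv, t in zip(self.compress, block_outputs)]
        return self.fuse(Tensor.concat(parts, axis=1))


class Reconstructor(Module):
    """1x1 channel reduction -> pixel shuffle -> additive bicubic skip."""

    def __init__(self, channels: int, scale: int, rng, dtype=np.float32):
        super().__init__()
        self.scale = scale
        # zero init: untrained output == bicubic interpolation of the input
        self.reduce = Conv2d(channels, scale * scale, 1, rng, dtype=dtype,
                             zero_init=True)

    def forward(self, m: Tensor, lr_input: np.ndarray) -> Tensor:
        branch = _pixel_shuffle_t(self.reduce(m), self.scale)
        up = np.stack([bicubic_upsample(img[0], self.scale)
                       for img in lr_input])[:, None]
        return branch + Tensor(up.astype(branch.data.dtype))


class HLGRetinaSR(Module):
    def __init__(self, config: SRConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        self.prelim = PreliminaryFeatures(config.channels, rng,
                                          config.expansion, dtype=dt)
        self.blocks = [HLGBlock(config.channels, rng, config.patch_side,
                                config.psgm_deformable, config.ipgm_residual,
                                dtype=dt)
                       for _ in range(config.n_blocks)]
        self.reuse = FeatureReuse(config.channels, config.n_blocks, rng,
                                  dtype=dt)
        self.recon = Reconstructor(config.channels, config.scale, rng,
                                   dtype=dt)

    def forward(self, x: Tensor) -> Tensor:
        feats = self.prelim(x)
        outs = []
        for block in self.blocks:
            feats = block(feats)
            outs.append(feats)
        m = self.reuse(outs)
        return self.recon(m, x.data)

    def zero_sr_branch(self) -> None:
        """Zero the learned reconstruction branch: output becomes bicubic."""
        self.recon.reduce.weight.data[...] = 0.0
        self.recon.reduce.bias.data[...] = 0.0


class SRCNN(Module):
    """Three-stage baseline: two 3x3/64 feature-extraction convolutions,
    a 4x4 stride-2 transposed convolution doubling the resolution, and a
    3x3 reconstruction convolution back to one channel."""

    def __init__(self, seed: int = 0, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(1, 64, 3, rng, padding=1, dtype=dtype)
        self.conv2 = Conv2d(64, 64, 3, rng, padding=1, dtype=dtype)
        self.up = ConvTranspose2d(64, 64, 4, rng, stride=2, padding=1,
                                  dtype=dtype)
        self.recon = Conv2d(64, 1, 3, rng, padding=1, dtype=dtype)

    def extract(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()

    def upsample(self, feats: Tensor) -> Tensor:
        return self.up(feats).relu()

    def forward(self, x: Tensor) -> Tensor:
        return self.recon(self.upsample(self.extract(x)))


def build_sr_model(name: str, config: SRConfig | None = None,
                   seed: int = 0) -> Module:
    if name == "hlg":
        return HLGRetinaSR(config or SRConfig(), seed=seed)
    if name == "srcnn":
        return SRCNN(seed=seed)
    raise ValueError(f"unknown SR model {name!r} (expected 'hlg' or 'srcnn')")


# ---------------------------------------------------------------------------
# single-map functional wrappers
# ---------------------------------------------------------------------------

def preliminary_features(image: GrayImage, module: PreliminaryFeatures) -> np.ndarray:
    with no_grad():
        out = module(Tensor(image.pixels[None, None].astype(
            module.expand.weight.data.dtype)))
    return out.data[0]


def hlg_block(features: np.ndarray, module: HLGBlock) -> HLGBlockOutput:
    x = Tensor(np.asarray(features)[None])
    with no_grad():
        alm, ipgm, psgm = module.branches(x)
        fused = module.fuse(Tensor.concat([alm, ipgm, psgm, x], axis=1)) + x
    return HLGBlockOutput(alm=alm.data[0], ipgm=ipgm.data[0],
                          psgm=psgm.data[0], fused=fused.data[0])


def feature_reuse(block_outputs: list[np.ndarray],
                  module: FeatureReuse) -> AggregatedFeatures:
    tensors = [Tensor(np.asarray(b)[None]) for b in block_outputs]
    with no_grad():
        return AggregatedFeatures(m=module(tensors).data[0])


def reconstruct(m: AggregatedFeatures, input_image: GrayImage,
                module: Reconstructor) -> GrayImage:
    with no_grad():
        out = module(Tensor(np.asarray(m.m)[None]),
                     input_image.pixels[None, None])
    return GrayImage(out.data[0, 0].astype(np.float64),
                     dynamic_range=input_image.dynamic_range)


def srcnn_forward(image: GrayImage, model: SRCNN) -> GrayImage:
    with no_grad():
        out = model(Tensor(image.pixels[None, None].astype(
            model.conv1.weight.data.dtype)))
    return GrayImage(out.data[0, 0].astype(np.float64),
                     dynamic_range=image.dynamic_range)


# ---------------------------------------------------------------------------
# loss + training
# ---------------------------------------------------------------------------

def mse_loss(pred, target) -> float:
    """Mean over the batch of per-image mean squared pixel differences."""
    p = np.asarray([x.pixels if isinstance(x, GrayImage) else x for x in pred],
                   dtype=np.float64)
    t = np.asarray([x.pixels if isinstance(x, GrayImage) else x for x in target],
                   dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.shape[0] < 1:
        raise ValueError("need at least one image pair")
    per_image = ((p - t) ** 2).reshape(p.shape[0], -1).mean(axis=1)
    return float(per_image.mean())


def _to_array_pairs(pairs, dtype):
    out = []
    for lr, hr in pairs:
        lr = lr.pixels if isinstance(lr, GrayImage) else np.asarray(lr)
        hr = hr.pixels if isinstance(hr, GrayImage) else np.asarray(hr)
        out.append((lr.astype(dtype), hr.astype(dtype)))
    return out


def train_sr(model: Module, pairs, config: TrainSRConfig,
             seed: int) -> SRTrainState:
    """Minimize the MSE between super-resolved and target images with Adam.

    Deterministic under a fixed seed (single-threaded execution assumed).
    With ``config.crop_size`` set, each epoch samples one random LR crop per
    pair (the network is fully convolutional, so crop training is valid and
    keeps desk-scale runtimes bounded).
    """
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    dtype = model.parameters()[0].data.dtype
    scale = getattr(getattr(model, "config", None), "scale", 2)
    data = _to_array_pairs(pairs, dtype)
    for lr, hr in data:
        if (lr.shape[0] * scale, lr.shape[1] * scale) != hr.shape:
            raise ValueError(
                f"LR {lr.shape} x{scale} does not match HR {hr.shape}")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=config.lr)
    model.train(True)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(data))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            lrs, hrs = [], []
            for i in idx:
                lr_img, hr_img = data[i]
                if config.crop_size is not None and \
                        config.crop_size < min(lr_img.shape):
                    cs = config.crop_size
                    r0 = int(rng.integers(0, lr_img.shape[0] - cs + 1))
                    c0 = int(rng.integers(0, lr_img.shape[1] - cs + 1))
                    lr_img = lr_img[r0:r0 + cs, c0:c0 + cs]
                    hr_img = hr_img[r0 * scale:(r0 + cs) * scale,
                                    c0 * scale:(c0 + cs) * scale]
                lrs.append(lr_img)
                hrs.append(hr_img)
            x = Tensor(np.stack(lrs)[:, None])
            y = np.stack(hrs)[:, None]
            pred = model(x)
            diff = pred - Tensor(y.astype(pred.data.dtype))
            loss = (diff * diff).mean()
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"NaN/Inf loss at epoch {epoch}, step {start // config.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(val)
        history.append(float(np.mean(epoch_losses)))
    model.eval()
    return SRTrainState(loss_history=history, epoch=config.epochs, seed=seed)


def enhance_image(model: Module, image: GrayImage) -> GrayImage:
    """Run a trained SR model on one normalized image."""
    dtype = model.parameters()[0].data.dtype
    model.eval()
    with no_grad():
        out = model(Tensor(image.pixels[None, None].astype(dtype)))
    return GrayImage(out.data[0, 0].astype(np.float64),
                     dynamic_range=image.dynamic_range)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Module, path, meta: dict | None = None) -> None:
    path = pathlib.Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = dict(meta or {})
    if isinstance(model, HLGRetinaSR):
        sidecar["model"] = "hlg"
        sidecar["sr_config"] = dataclasses.asdict(model.config)
    elif isinstance(model, SRCNN):
        sidecar["model"] = "srcnn"
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> Module:
    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["model"] == "hlg":
        model = HLGRetinaSR(SRConfig(**meta["sr_config"]))
    elif meta["model"] == "srcnn":
        model = SRCNN()
    else:
        raise ValueError(f"unknown checkpoint model {meta['model']!r}")
    state = dict(np.load(path.with_suffix(".npz")))
    model.load_state_dict(state)
    model.eval()
    return model
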