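"""Fundus preprocessing: ROI crop, resize, Gaussian smoothing/blending, and
per-image min-max normalization onto [-1, 1].
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.signal import convolve2d
from skimage.transform import resize as _sk_resize

from .fundus_io import GrayImage

__all__ = [
    "GaussianKernel", "BlendParams", "PreprocessConfig",
    "crop_roi", "resize", "gaussian_kernel", "gaussian_blur", "blend",
    "normalize_minmax", "preprocess_pipeline",
]

# Graham-style sharpening coefficients kept as a named preset; the default
# blend is pure smoothing.
SHARPEN_BLEND = (4.0, -4.0, 0.5)


@dataclasses.dataclass
class GaussianKernel:
    weights: np.ndarray
    sigma: float
    radius: int

    def __post_init__(self):
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 != 1:
            raise ValueError("kernel must be square with odd side")
        if not np.all(w >= 0):
            raise ValueError("kernel weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to 1")


@dataclasses.dataclass
class BlendParams:
    alpha: float = 0.0
    beta: float = 1.0
    gamma: float = 0.0

    def __post_init__(self):
        for v in (self.alpha, self.beta, self.gamma):
            if not math.isfinite(v):
                raise ValueError("blend coefficients must be finite")


@dataclasses.dataclass
class PreprocessConfig:
    target_size: tuple[int, int] = (224, 224)
    roi_threshold: float = 0.05
    sigma: float | None = None          # None -> width / 30 after resize
    blur_enabled: bool = True
    blend: tuple[float, float, float] = (0.0, 1.0, 0.0)


def crop_roi(image: GrayImage, threshold: float = 0.05) -> GrayImage:
    """Tight bounding box of pixels above threshold * max; degenerate input
    (nothing above threshold) passes through unchanged."""
    px = image.pixels
    mask = px > threshold * px.max()
    if not mask.any():
        return image
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return GrayImage(px[r0:r1, c0:c1].copy(), dynamic_range=image.dynamic_range)


def resize(image: GrayImage, target: tuple[int, int]) -> GrayImage:
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError(f"target size must be positive, got {target}")
    if (th, tw) == (image.height, image.width):
        return GrayImage(image.pixels.copy(), dynamic_range=image.dynamic_range)
    out = _sk_resize(image.pixels.astype(np.float64), (th, tw), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return GrayImage(out, dynamic_range=image.dynamic_range)


def gaussian_kernel(sigma: float) -> GaussianKernel:
    """Truncated, renormalized isotropic Gaussian; radius = ceil(3 * sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r = math.ceil(3.0 * sigma)
    u = np.arange(-r, r + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    w = np.exp(-(uu ** 2 + vv ** 2) / (2.0 * sigma ** 2))
    w /= w.sum()
    return GaussianKernel(weights=w, sigma=float(sigma), radius=r)


def gaussian_blur(image: GrayImage, kernel: GaussianKernel) -> GrayImage:
    out = convolve2d(image.pixels.astype(np.float64), kernel.weights,
                     mode="same", boundary="fill", fillvalue=0.0)
    return GrayImage(out, dynamic_range=image.dynamic_range)


def blend(original: GrayImage, blurred: GrayImage,
          params: BlendParams) -> GrayImage:
    if original.pixels.shape != blurred.pixels.shape:
        raise ValueError(
            f"shape mismatch {original.pixels.shape} vs {blurred.pixels.shape}")
    out = (params.alpha * original.pixels + params.beta * blurred.pixels
           + params.gamma)
    return GrayImage(out, dynamic_range=original.dynamic_range)


def normalize_minmax(image: GrayImage) -> GrayImage:
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi <= lo:
        raise ValueError("cannot min-max normalize a constant image")
    out = (px - lo) / (hi - lo) * 2.0 - 1.0
    return GrayImage(out, dynamic_range=(-1.0, 1.0))


def preprocess_pipeline(image: GrayImage,
                        config: PreprocessConfig | None = None) -> GrayImage:
    """crop ROI -> resize -> (blur + blend) -> min-max normalize to [-1, 1]."""
    config = config or PreprocessConfig()
    img = crop_roi(image, config.roi_threshold)
    img = resize(img, config.target_size)
    if config.blur_enabled:
        sigma = config.sigma if config.sigma is not None else img.width / 30.0
        blurred = gaussian_blur(img, gaussian_kernel(sigma))
        img = blend(img, blurred, BlendParams(*config.blend))
    return normalize_minmax(img)
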