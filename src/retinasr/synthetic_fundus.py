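"""Seeded synthetic fundus phantoms for the five severity grades.

Each phantom is a circular retina disc with an optic disc, a branching
vessel tree, and grade-dependent lesions: dark microaneurysm dots, larger
irregular hemorrhage blobs, bright exudate clusters, and (highest grade
only) fine high-tortuosity neovessel tufts.  Lesion counts are Poisson with
grade-dependent rates, so expected lesion load grows monotonically with
grade.  Everything is a pure function of (params, seed).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from skimage.draw import disk as _disk
from skimage.transform import resize as _sk_resize

from .fundus_io import (GRADES, DatasetManifest, GradedImageRecord, GrayImage,
                        save_manifest)
from .preprocess import gaussian_blur, gaussian_kernel

__all__ = [
    "PhantomParams", "PhantomRecord", "DEFAULT_LESION_RATES",
    "generate_fundus", "generate_dataset", "make_sr_pairs",
]

# grade -> (microaneurysm, hemorrhage, exudate, neovessel) Poisson rates
DEFAULT_LESION_RATES = {
    0: (0.0, 0.0, 0.0, 0.0),
    1: (12.0, 0.0, 0.0, 0.0),
    2: (18.0, 6.0, 6.0, 0.0),
    3: (24.0, 14.0, 14.0, 0.0),
    4: (24.0, 14.0, 14.0, 16.0),
}

LESION_TYPES = ("microaneurysm", "hemorrhage", "exudate", "neovessel")


@dataclasses.dataclass
class PhantomParams:
    image_side: int = 448
    vessel_branches: int = 7
    vessel_tortuosity: float = 0.25
    lesion_rates: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LESION_RATES))
    noise_sigma: float = 4.0
    illumination_gradient: float = 0.1

    def __post_init__(self):
        rates = self.lesion_rates
        if any(r != 0 for r in rates[0]):
            raise ValueError("grade-0 lesion rates must all be zero")
        for t in range(4):
            if t == 3:
                continue  # neovessels appear only at the top grade
            for g in range(4):
                if rates[g][t] > rates[g + 1][t] + 1e-12:
                    raise ValueError(
                        f"lesion rate for type {LESION_TYPES[t]} decreases "
                        f"from grade {g} to {g + 1}")


@dataclasses.dataclass
class PhantomRecord:
    image: GrayImage
    grade: int
    lesion_inventory: dict
    seed: int
    lesion_mask: np.ndarray | None = None   # bool raster of stamped lesions


def _clip_disk(canvas, center, radius):
    rr, cc = _disk(center, radius, shape=canvas.shape)
    return rr, cc


def _draw_vessel(canvas, start, angle, length, width, depth, rng,
                 tortuosity, intensity, mask=None):
    """Random-walk vessel segment with recursive branching."""
    y, x = start
    step = 2.5
    n = max(int(length / step), 2)
    for _ in range(n):
        angle += tortuosity * rng.normal() * 0.5
        y += step * np.sin(angle)
        x += step * np.cos(angle)
        if not (0 <= y < canvas.shape[0] and 0 <= x < canvas.shape[1]):
            return
        rr, cc = _clip_disk(canvas, (y, x), max(width, 0.8))
        canvas[rr, cc] = np.minimum(canvas[rr, cc], intensity)
        if mask is not None:
            mask[rr, cc] = True
    if depth > 0:
        for sgn in (-1.0, 1.0):
            _draw_vessel(canvas, (y, x), angle + sgn * rng.uniform(0.25, 0.6),
                         length * 0.72, width * 0.75, depth - 1, rng,
                         tortuosity, intensity, mask)


def _random_point_in_disc(rng, center, radius):
    for _ in range(100):
        y = center[0] + rng.uniform(-radius, radius)
        x = center[1] + rng.uniform(-radius, radius)
        if (y - center[0]) ** 2 + (x - center[1]) ** 2 <= radius ** 2:
            return y, x
    return center


def generate_fundus(grade: int, params: PhantomParams,
                    seed: int) -> PhantomRecord:
    if grade not in GRADES:
        raise ValueError(f"grade must be in 0..4, got {grade}")
    rng = np.random.default_rng(seed)
    S = params.image_side
    canvas = np.zeros((S, S), dtype=np.float64)
    center = (S / 2.0, S / 2.0)
    retina_r = 0.47 * S

    # retina disc with gentle radial shading
    yy, xx = np.mgrid[0:S, 0:S]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    inside = d2 <= retina_r ** 2
    canvas[inside] = 110.0 - 25.0 * (d2[inside] / retina_r ** 2)

    # optic disc: bright ellipse offset horizontally from the center
    od_center = (center[0] + rng.uniform(-0.05, 0.05) * S,
                 center[1] + rng.choice([-1, 1]) * 0.22 * S)
    od_r = 0.065 * S
    od = ((yy - od_center[0]) / (od_r * 1.1)) ** 2 + \
        ((xx - od_center[1]) / od_r) ** 2 <= 1.0
    canvas[od & inside] = 205.0

    # vessel tree growing out of the optic disc
    base_angle = np.arctan2(center[0] - od_center[0],
                            center[1] - od_center[1])
    for b in range(params.vessel_branches):
        ang = base_angle + rng.uniform(-1.4, 1.4)
        _draw_vessel(canvas, od_center, ang, length=0.5 * S,
                     width=0.006 * S + 1.0, depth=3, rng=rng,
                     tortuosity=params.vessel_tortuosity, intensity=60.0)

    # lesions (stamped positions recorded in a mask)
    lesion_mask = np.zeros((S, S), dtype=bool)
    rates = params.lesion_rates[grade]
    counts = {name: int(rng.poisson(lam)) if lam > 0 else 0
              for name, lam in zip(LESION_TYPES, rates)}
    lesion_r = 0.9 * retina_r
    for _ in range(counts["microaneurysm"]):
        y, x = _random_point_in_disc(rng, center, lesion_r)
        rr, cc = _clip_disk(canvas, (y, x), rng.uniform(1.0, 3.0))
        canvas[rr, cc] = np.minimum(canvas[rr, cc], 35.0)
        lesion_mask[rr, cc] = True
    for _ in range(counts["hemorrhage"]):
        y, x = _random_point_in_disc(rng, center, lesion_r)
        for _blob in range(rng.integers(3, 6)):
            dy, dx = rng.normal(scale=4.0, size=2)
            rr, cc = _clip_disk(canvas, (y + dy, x + dx),
                                rng.uniform(4.0, 9.0))
            canvas[rr, cc] = np.minimum(canvas[rr, cc], 15.0)
            lesion_mask[rr, cc] = True
    for _ in range(counts["exudate"]):
        y, x = _random_point_in_disc(rng, center, lesion_r)
        for _dot in range(rng.integers(5, 9)):
            dy, dx = rng.normal(scale=4.0, size=2)
            rr, cc = _clip_disk(canvas, (y + dy, x + dx),
                                rng.uniform(2.0, 4.0))
            canvas[rr, cc] = np.maximum(canvas[rr, cc], 240.0)
            lesion_mask[rr, cc] = True
    for _ in range(counts["neovessel"]):
        y, x = _random_point_in_disc(rng, center, 0.5 * retina_r)
        for _twig in range(10):
            _draw_vessel(canvas, (y, x), rng.uniform(0, 2 * np.pi),
                         length=0.12 * S, width=1.3, depth=0, rng=rng,
                         tortuosity=1.8, intensity=35.0, mask=lesion_mask)

    # keep everything inside the retina disc
    canvas[~inside] = 0.0

    # smooth illumination gradient + pixel noise
    theta = rng.uniform(0, 2 * np.pi)
    plane = ((yy * np.sin(theta) + xx * np.cos(theta)) / S - 0.5)
    canvas[inside] += params.illumination_gradient * 255.0 * plane[inside]
    canvas += rng.normal(scale=params.noise_sigma, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)

    lesion_mask &= inside
    return PhantomRecord(image=GrayImage(canvas, dynamic_range=(0.0, 255.0)),
                         grade=grade, lesion_inventory=counts, seed=seed,
                         lesion_mask=lesion_mask)


def generate_dataset(n_per_grade: int, params: PhantomParams, seed: int,
                     out_dir) -> DatasetManifest:
    """Balanced phantom dataset: PNGs + manifest CSV + params JSON."""
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).spawn(5 * n_per_grade)
    records = []
    k = 0
    from .fundus_io import write_image
    for grade in GRADES:
        for i in range(n_per_grade):
            rec_seed = int(child_seeds[k].generate_state(1)[0])
            k += 1
            rec = generate_fundus(grade, params, rec_seed)
            name = f"phantom_g{grade}_{i:04d}.png"
            write_image(rec.image, out_dir / name)
            records.append(GradedImageRecord(path=name, grade=grade))
    manifest = DatasetManifest(records, seed=seed)
    save_manifest(manifest, out_dir / "manifest.csv")
    payload = dataclasses.asdict(params)
    payload["seed"] = seed
    payload["n_per_grade"] = n_per_grade
    (out_dir / "params.json").write_text(json.dumps(payload, indent=2))
    return manifest


def make_sr_pairs(records, scale: int = 2, degradation: str = "bicubic",
                  normalize: bool = True, noise_sigma: float = 0.02,
                  seed: int = 0):
    """LR/HR training pairs from phantom records (or GrayImages).

    HR is the phantom raster (min-max normalized to [-1, 1] by default); LR
    is its bicubic downscale, optionally blurred beforehand or noised
    afterwards.  Pairing order is preserved.
    """
    if degradation not in ("bicubic", "bicubic+blur", "bicubic+noise"):
        raise ValueError(f"unknown degradation {degradation!r}")
    rng = np.random.default_rng(seed)
    pairs = []
    for rec in records:
        img = rec.image if isinstance(rec, PhantomRecord) else rec
        hr = img.pixels.astype(np.float64)
        if hr.shape[0] % scale or hr.shape[1] % scale:
            raise ValueError(
                f"HR dims {hr.shape} not divisible by scale {scale}")
        if normalize:
            lo, hi = hr.min(), hr.max()
            hr = (hr - lo) / (hi - lo) * 2.0 - 1.0
        src = hr
        if degradation == "bicubic+blur":
            blurred = gaussian_blur(GrayImage(src, dynamic_range=(-1, 1)),
                                    gaussian_kernel(1.0))
            src = blurred.pixels
        lr = _sk_resize(src, (hr.shape[0] // scale, hr.shape[1] // scale),
                        order=3, mode="reflect", anti_aliasing=True,
                        preserve_range=True)
        if degradation == "bicubic+noise":
            lr = lr + rng.normal(scale=noise_sigma, size=lr.shape)
        dr = (-1.0, 1.0) if normalize else img.dynamic_range
        pairs.append((GrayImage(lr, dynamic_range=dr),
                      GrayImage(hr, dynamic_range=dr)))
    return pairs
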