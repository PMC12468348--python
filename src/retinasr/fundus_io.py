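"""Image and dataset-manifest I/O.

Conventions used throughout the package: rasters are row-major with origin
top-left and 0-based indices; crops use half-open intervals; RGB inputs are
collapsed to luminance with ITU-R BT.601 weights.
"""

from __future__ import annotations

import dataclasses
import math
import pathlib

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "GrayImage", "GradedImageRecord", "DatasetManifest",
    "read_image", "write_image", "load_manifest", "save_manifest",
    "split_manifest", "GRADES",
]

GRADES = (0, 1, 2, 3, 4)

BT601 = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass
class GrayImage:
    """2-D intensity raster with an explicit representable dynamic range."""

    pixels: np.ndarray
    dynamic_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected 2-D raster, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixel values")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class GradedImageRecord:
    path: str
    grade: int
    split: str = "unassigned"

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValueError(f"grade must be in 0..4, got {self.grade}")
        if self.split not in ("train", "test", "unassigned"):
            raise ValueError(f"invalid split {self.split!r}")


@dataclasses.dataclass
class DatasetManifest:
    records: list[GradedImageRecord]
    seed: int | None = None

    def __post_init__(self):
        paths = [r.path for r in self.records]
        if len(paths) != len(set(paths)):
            raise ValueError("manifest contains duplicate paths")

    @property
    def class_counts(self) -> dict[int, int]:
        counts = {g: 0 for g in GRADES}
        for r in self.records:
            counts[r.grade] += 1
        return counts

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split],
                               seed=self.seed)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _range_from_pil(img: Image.Image) -> tuple[float, float]:
    if img.mode in ("I;16", "I;16B", "I;16L", "I"):
        return (0.0, 65535.0)
    if img.mode == "F":
        return (0.0, 1.0)
    return (0.0, 255.0)


def read_image(path, as_gray: bool = True) -> GrayImage:
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # undecodable bytes
        raise ValueError(f"cannot decode image {path}: {exc}") from exc
    rng = _range_from_pil(img)
    arr = np.asarray(img)
    if arr.ndim == 3:
        if not as_gray:
            raise ValueError("color image read with as_gray=False is unsupported")
        arr = arr[..., :3].astype(np.float64) @ BT601
    return GrayImage(arr.astype(np.float64), dynamic_range=rng)


def write_image(image: GrayImage, path, quantize: bool = False) -> None:
    """Write a raster as PNG/TIFF.

    With ``quantize`` the pixels are treated as lying in [-1, 1] and mapped
    affinely onto [0, 255] with round-half-even; otherwise pixels must be
    within the image's dynamic range already.
    """
    path = pathlib.Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory missing: {path.parent}")
    px = image.pixels
    if quantize:
        arr = np.rint((px + 1.0) * 127.5).clip(0, 255).astype(np.uint8)
    else:
        lo, hi = image.dynamic_range
        if px.min() < lo or px.max() > hi:
            raise ValueError(
                f"pixels [{px.min()}, {px.max()}] outside dynamic range "
                f"({lo}, {hi}); quantize first")
        if hi > 255:
            arr = np.rint(px).astype(np.uint16)
        else:
            arr = np.rint(px).astype(np.uint8)
    mode = "I;16" if arr.dtype == np.uint16 else "L"
    Image.fromarray(arr, mode=mode).save(path)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def load_manifest(path) -> DatasetManifest:
    path = pathlib.Path(path)
    df = pd.read_csv(path, dtype={"path": str})
    for col in ("path", "grade"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            grade = int(row.grade)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: grade {row.grade!r} is not an integer") from exc
        if grade not in GRADES:
            raise ValueError(f"row {i}: grade {grade} outside 0..4")
        split = getattr(row, "split", "unassigned")
        if not isinstance(split, str) or split not in ("train", "test", "unassigned"):
            split = "unassigned"
        records.append(GradedImageRecord(path=row.path, grade=grade, split=split))
    return DatasetManifest(records)


def save_manifest(manifest: DatasetManifest, path) -> None:
    df = pd.DataFrame(
        {"path": [r.path for r in manifest.records],
         "grade": [r.grade for r in manifest.records],
         "split": [r.split for r in manifest.records]})
    df.to_csv(path, index=False)


def split_manifest(manifest: DatasetManifest, test_fraction: float,
                   seed: int) -> DatasetManifest:
    """Stratified train/test split: ceil(frac * n_g) test records per grade."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    counts = manifest.class_counts
    present = [g for g in GRADES if counts[g] > 0]
    for g in present:
        if counts[g] < 2:
            raise ValueError(f"grade {g} has fewer than 2 records; cannot split")
    rng = np.random.default_rng(seed)
    new_records = [dataclasses.replace(r, split="train") for r in manifest.records]
    for g in present:
        idx = [i for i, r in enumerate(new_records) if r.grade == g]
        n_test = math.ceil(test_fraction * len(idx))
        chosen = rng.permutation(len(idx))[:n_test]
        for c in chosen:
            new_records[idx[c]] = dataclasses.replace(new_records[idx[c]],
                                                      split="test")
    return DatasetManifest(new_records, seed=seed)
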