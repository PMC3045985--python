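"""Shared data model, raster I/O and binarization.

Coordinate convention (fixed throughout the package): 0-based, row-major
``(row, col)`` indices with pixel-center coordinates.  All geometry after
registration is expressed in pixel units of the H&E grid.

The two modalities are an RGB brightfield H&E image (~0.9636 um/pixel) and
a cell-type label raster derived from infrared spectroscopic imaging
(~6.25 um/pixel).  The label vocabulary is closed: 0=background,
1=epithelium, 2=stroma, 3=other.  Only epithelium is consumed downstream,
so any richer histologic palette collapses onto "other" upstream of this
package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

# Physical pixel sizes of the two acquisition grids, in micrometres.
HE_PIXEL_SIZE_UM = 0.9636
IR_PIXEL_SIZE_UM = 6.25

#: Closed label vocabulary of the IR cell-type raster.
LABEL_BACKGROUND = 0
LABEL_EPITHELIUM = 1
LABEL_STROMA = 2
LABEL_OTHER = 3
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_EPITHELIUM, LABEL_STROMA, LABEL_OTHER})

#: Intensity above which a channel counts as "white" (empty space / lumen).
WHITE_THRESHOLD = 200


class FormatError(ValueError):
    """Raised when an input raster violates the declared format."""


@dataclass
class RgbImage:
    """8-bit RGB H&E image with its physical pixel size."""

    pixels: np.ndarray  # H x W x 3 uint8
    pixel_size_um: float = HE_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected HxWx3 RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("image must be at least 1x1")
        if px.min() < 0 or px.max() > 255:
            raise FormatError("channel values must lie in [0, 255]")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel size must be positive")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelImage:
    """Integer cell-type raster from IR imaging (closed 4-code vocabulary)."""

    labels: np.ndarray  # H x W small ints
    pixel_size_um: float = IR_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise FormatError(f"expected HxW label array, got shape {lab.shape}")
        codes = set(np.unique(lab).tolist())
        unknown = codes - VALID_LABELS
        if unknown:
            raise FormatError(f"unknown label code(s) {sorted(unknown)}; valid codes are {sorted(VALID_LABELS)}")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel size must be positive")
        self.labels = lab.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class BinaryMask:
    """Boolean raster sharing the shape of its source image.

    ``origin_convention`` is fixed: 0-based, row-major, pixel-center.
    """

    mask: np.ndarray
    origin_convention: str = field(default="0-based,row-major,pixel-center", repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError(f"expected 2-D mask, got shape {self.mask.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def sum(self) -> int:
        return int(self.mask.sum())


@dataclass
class SamplePair:
    """One tissue sample: H&E image, IR label map and (optional) class label."""

    he: RgbImage
    ir: LabelImage
    sample_id: str = ""
    class_label: int | None = None  # 0 = benign, 1 = cancer, None = unknown


def _read_raster(path: str) -> np.ndarray:
    """Read a TIFF/PNG/CSV raster as a numpy array."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return tifffile.imread(path)
    if ext == ".csv":
        return np.loadtxt(path, delimiter=",", dtype=np.int64)
    with Image.open(path) as im:
        return np.asarray(im)


def read_he(path: str, pixel_size_um: float = HE_PIXEL_SIZE_UM) -> RgbImage:
    """Read an H&E image; must decode to 8-bit RGB."""
    arr = _read_raster(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: H&E image must be RGB, got shape {arr.shape}")
    return RgbImage(arr, pixel_size_um=pixel_size_um)


def read_label_map(path: str, pixel_size_um: float = IR_PIXEL_SIZE_UM) -> LabelImage:
    """Read an IR cell-type label raster (TIFF/PNG/CSV integer grid)."""
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be a single-channel integer raster")
    return LabelImage(arr, pixel_size_um=pixel_size_um)


def read_sample_pair(
    he_path: str,
    ir_path: str,
    sample_id: str = "",
    class_label: int | None = None,
    he_pixel_size_um: float = HE_PIXEL_SIZE_UM,
    ir_pixel_size_um: float = IR_PIXEL_SIZE_UM,
) -> SamplePair:
    """Load the paired H&E and IR rasters of one sample."""
    he = read_he(he_path, pixel_size_um=he_pixel_size_um)
    ir = read_label_map(ir_path, pixel_size_um=ir_pixel_size_um)
    return SamplePair(he=he, ir=ir, sample_id=sample_id or os.path.basename(he_path), class_label=class_label)


def read_manifest(path: str) -> pd.DataFrame:
    """Read a cohort manifest CSV (columns sample_id, he_path, ir_path, label).

    Relative image paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "he_path", "ir_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s) in manifest: {dupes}")
    base = os.path.dirname(os.path.abspath(path))
    for col in ("he_path", "ir_path"):
        df[col] = [p if os.path.isabs(p) else os.path.join(base, p) for p in df[col]]
    return df


def binarize_he(img: RgbImage, white_threshold: int = WHITE_THRESHOLD) -> BinaryMask:
    """Tissue mask of an H&E image.

    A pixel is "white" (empty space) when *all three* channels exceed the
    threshold; the mask is true on the complement, i.e. wherever tissue is
    present.
    """
    if not 0 <= white_threshold <= 255:
        raise ValueError("white_threshold must lie in [0, 255]")
    px = img.pixels
    white = np.all(px > white_threshold, axis=2)
    return BinaryMask(~white)


def binarize_ir(img: LabelImage) -> BinaryMask:
    """Tissue mask of an IR label map: true wherever the label is not background."""
    return BinaryMask(img.labels != LABEL_BACKGROUND)
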