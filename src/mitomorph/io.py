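"""Calibrated image and table I/O.

Images travel through the pipeline as small dataclasses wrapping numpy
arrays plus a physical calibration (µm per pixel, isotropic).  A z-stack is
an ordered list of equally shaped slices; all quantitative analysis runs on
its maximum-intensity projection, mirroring the standard wide-field
workflow where serial optical sections are flattened before segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: provenance tags a binary mask may carry
MASK_PROVENANCES = ("threshold", "external", "ground_truth", "phantom")


@dataclass
class Image2D:
    """A single grayscale image with physical pixel calibration."""

    pixels: np.ndarray
    pixel_size: float = 1.0  # µm per pixel, isotropic
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"Image2D requires a 2D grid, got shape {self.pixels.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("intensities must be finite")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ZStack:
    """Ordered optical sections sharing shape and calibration."""

    slices: list[Image2D]
    z_step: float = 0.25  # µm between sections

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("ZStack needs at least one slice")
        if not self.z_step > 0:
            raise ValueError("z_step must be > 0")
        shape0 = self.slices[0].shape
        for s in self.slices[1:]:
            if s.shape != shape0:
                raise ValueError("all slices must share one shape")

    @property
    def pixel_size(self) -> float:
        return self.slices[0].pixel_size


@dataclass
class BinaryMask:
    """Foreground mask paired with the image it segments."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    provenance: str = "external"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask requires a 2D grid")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.provenance not in MASK_PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Integer-labelled objects; 0 is background, k>0 is object k."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("LabelMask requires a 2D grid")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("LabelMask requires integer labels")
        if self.pixels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        vals = np.unique(self.pixels)
        return vals[vals > 0]


def _pixel_size_from_tags(page) -> float | None:
    """Pixel size (µm/px) from TIFF XResolution, when present and sane."""
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    return den / num


def read_tiff(path: str | Path, pixel_size: float | None = None,
              z_step: float = 0.25):
    """Read a grayscale TIFF as :class:`Image2D` (1 page) or :class:`ZStack`.

    Calibration precedence: explicit ``pixel_size`` argument > TIFF
    resolution tags > 1.0 µm/px with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # pragma: no cover - corrupt file branch
        raise ValueError(f"unreadable TIFF {path.name}: {exc}") from exc
    with tif:
        pages = tif.pages
        if pages[0].samplesperpixel and pages[0].samplesperpixel > 1:
            raise ValueError(f"RGB/multichannel TIFF not supported: {path.name}")
        arrays = [p.asarray() for p in pages]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent page shapes in {path.name}: {sorted(shapes)}")
    if arrays[0].ndim != 2:
        raise ValueError(f"expected 2D grayscale pages in {path.name}")
    if pixel_size is None:
        pixel_size = _pixel_size_from_tags(pages[0])
    if pixel_size is None:
        logger.warning("%s: no calibration found, assuming 1.0 µm/px", path.name)
        pixel_size = 1.0
    name = path.stem
    if len(arrays) == 1:
        return Image2D(arrays[0], pixel_size=pixel_size, name=name)
    slices = [Image2D(a, pixel_size=pixel_size, name=f"{name}_z{i}")
              for i, a in enumerate(arrays)]
    return ZStack(slices, z_step=z_step)


def write_tiff(obj, path: str | Path) -> None:
    """Write an image or mask as a grayscale TIFF.

    Binary masks are stored as 8-bit {0, 255}; label masks keep their
    integer dtype; images keep theirs.  Resolution tags carry the
    calibration back out (pixels per µm).
    """
    path = Path(path)
    if isinstance(obj, BinaryMask):
        data = np.where(obj.pixels, 255, 0).astype(np.uint8)
        ps = obj.pixel_size
    elif isinstance(obj, LabelMask):
        data = obj.pixels.astype(np.uint16 if obj.pixels.max(initial=0) < 2**16 else np.uint32)
        ps = obj.pixel_size
    elif isinstance(obj, Image2D):
        data = obj.pixels
        ps = obj.pixel_size
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    res = 1.0 / ps
    tifffile.imwrite(path, data, resolution=(res, res))


def read_binary_mask(path: str | Path, pixel_size: float | None = None,
                     provenance: str = "external") -> BinaryMask:
    """Read a mask TIFF; any nonzero pixel counts as foreground."""
    img = read_tiff(path, pixel_size=pixel_size)
    if isinstance(img, ZStack):
        raise ValueError(f"mask file {Path(path).name} has multiple pages")
    return BinaryMask(img.pixels != 0, pixel_size=img.pixel_size, provenance=provenance)


def read_label_mask(path: str | Path, pixel_size: float | None = None) -> LabelMask:
    """Read an integer-labelled mask TIFF (e.g. per-cell labels)."""
    img = read_tiff(path, pixel_size=pixel_size)
    if isinstance(img, ZStack):
        raise ValueError(f"label file {Path(path).name} has multiple pages")
    pix = img.pixels
    if not np.issubdtype(pix.dtype, np.integer):
        rounded = np.rint(pix)
        if not np.allclose(pix, rounded):
            raise ValueError(f"label file {Path(path).name} holds non-integer values")
        pix = rounded.astype(np.int64)
    return LabelMask(pix.astype(np.int64), pixel_size=img.pixel_size)


def max_intensity_projection(stack: ZStack) -> Image2D:
    """Pixelwise maximum over all optical sections."""
    data = np.stack([s.pixels for s in stack.slices])
    mip = data.max(axis=0)
    base = stack.slices[0]
    name = base.name.rsplit("_z", 1)[0] if "_z" in base.name else base.name
    return Image2D(mip, pixel_size=base.pixel_size, name=f"{name}_mip" if name else "mip")


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write row-records to CSV (RFC 4180, header row, deterministic order).

    Rows are sorted by image name then label when those columns exist, so
    repeated runs produce byte-identical files.  ``columns`` fixes the
    header (and its order) even when the record list is empty.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        df = pd.DataFrame.from_records(records, columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    sort_cols = [c for c in ("image_name", "cell_label", "label") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, lineterminator="\r\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
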