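"""Global-thresholding segmentation sweep.

The classic ImageJ-style route to a mitochondrial mask: subtract a
rolling-ball background, median-smooth, then apply a *range* of global
thresholds, clean each candidate mask with a binary opening and a
small-object filter, and finally pick one candidate.  Where the original
workflow had an expert choose the best threshold by eye, this module
offers three deterministic selection modes: nearest-to-Otsu (the
parameter-free default), maximum Dice against a supplied reference mask,
and an explicit manual index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, restoration

from .io import BinaryMask, Image2D


@dataclass
class ThresholdSweepConfig:
    """Preprocessing and sweep parameters.

    ``thresholds`` may be an explicit increasing list, a ``(t_min, t_max,
    t_step)`` triple, or None, in which case 20 evenly spaced levels
    between the 70th and 99.5th intensity percentile of the preprocessed
    image are used.
    """

    background_radius_px: float = 50.0
    median_radius_px: int = 1
    opening_radius_px: int = 1
    thresholds: list[float] | tuple[float, float, float] | None = None
    n_auto_thresholds: int = 20
    auto_percentiles: tuple[float, float] = (70.0, 99.5)
    min_fragment_area_px: int = 4

    def __post_init__(self) -> None:
        if self.background_radius_px < 0 or self.median_radius_px < 0 \
                or self.opening_radius_px < 0:
            raise ValueError("radii must be >= 0")
        if self.min_fragment_area_px < 0:
            raise ValueError("min_fragment_area_px must be >= 0")

    def resolve_thresholds(self, img: Image2D) -> np.ndarray:
        if self.thresholds is None:
            lo, hi = np.percentile(np.asarray(img.pixels, dtype=float),
                                   self.auto_percentiles)
            ts = np.linspace(lo, hi, self.n_auto_thresholds)
        elif isinstance(self.thresholds, tuple) and len(self.thresholds) == 3:
            t_min, t_max, t_step = self.thresholds
            ts = np.arange(t_min, t_max + 0.5 * t_step, t_step, dtype=float)
        else:
            ts = np.asarray(list(self.thresholds), dtype=float)
        if ts.size == 0:
            raise ValueError("empty threshold list")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        return ts


@dataclass
class SweepResult:
    """Candidate masks of a threshold sweep plus the chosen one."""

    thresholds: list[float]
    candidates: list[BinaryMask]
    selected_index: int = 0
    selection_mode: str = "auto_otsu"

    def selected(self) -> BinaryMask:
        return self.candidates[self.selected_index]


def preprocess(img: Image2D, cfg: ThresholdSweepConfig) -> Image2D:
    """Rolling-ball background subtraction then square median filter.

    Both steps are skipped when their radius is 0, so ``(0, 0)`` is the
    identity.  Output intensities are clipped at 0.
    """
    data = np.asarray(img.pixels, dtype=float)
    if cfg.background_radius_px > 0:
        background = restoration.rolling_ball(data, radius=cfg.background_radius_px)
        data = data - background
    if cfg.median_radius_px > 0:
        size = 2 * int(cfg.median_radius_px) + 1
        data = ndimage.median_filter(data, size=size, mode="nearest")
    data = np.clip(data, 0, None)
    return Image2D(data, pixel_size=img.pixel_size, name=img.name)


def _clean(mask: np.ndarray, cfg: ThresholdSweepConfig) -> np.ndarray:
    if cfg.opening_radius_px > 0:
        footprint = morphology.disk(int(cfg.opening_radius_px))
        mask = morphology.opening(mask, footprint)
    if cfg.min_fragment_area_px > 0:
        # drop components with area < min_fragment_area_px
        mask = morphology.remove_small_objects(
            mask, max_size=cfg.min_fragment_area_px - 1, connectivity=2)
    return mask


def sweep_thresholds(img: Image2D, cfg: ThresholdSweepConfig) -> SweepResult:
    """Candidate mask per threshold: (img >= t), opened, size-filtered."""
    ts = cfg.resolve_thresholds(img)
    data = np.asarray(img.pixels, dtype=float)
    candidates = []
    for t in ts:
        mask = _clean(data >= t, cfg)
        candidates.append(BinaryMask(mask, pixel_size=img.pixel_size,
                                     provenance="threshold"))
    return SweepResult(thresholds=[float(t) for t in ts], candidates=candidates)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    tp = int(np.sum(a & b))
    denom = 2 * tp + int(np.sum(a & ~b)) + int(np.sum(~a & b))
    return 1.0 if denom == 0 else 2 * tp / denom


def select_candidate(res: SweepResult, mode: str = "auto_otsu",
                     truth: BinaryMask | None = None,
                     preprocessed: Image2D | None = None,
                     manual_index: int | None = None) -> BinaryMask:
    """Pick one candidate mask and record the choice in ``res``.

    auto_otsu: candidate whose threshold is nearest the Otsu threshold of
    the preprocessed image (required argument for this mode).
    max_dice_vs_truth: candidate maximising Dice against ``truth``; ties
    go to the lowest threshold.  manual_index: that candidate.
    """
    if not res.candidates:
        raise ValueError("sweep produced no candidates")
    if mode == "auto_otsu":
        if preprocessed is None:
            raise ValueError("auto_otsu selection needs the preprocessed image")
        t_otsu = filters.threshold_otsu(np.asarray(preprocessed.pixels, dtype=float))
        idx = int(np.argmin(np.abs(np.asarray(res.thresholds) - t_otsu)))
    elif mode == "max_dice_vs_truth":
        if truth is None:
            raise ValueError("max_dice_vs_truth selection needs a truth mask")
        scores = [_dice(c.pixels, truth.pixels) for c in res.candidates]
        idx = int(np.argmax(scores))  # argmax takes the first (lowest t) on ties
    elif mode == "manual_index":
        if manual_index is None or not 0 <= manual_index < len(res.candidates):
            raise ValueError(f"invalid manual candidate index {manual_index!r}")
        idx = manual_index
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    res.selected_index = idx
    res.selection_mode = mode
    return res.candidates[idx]
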