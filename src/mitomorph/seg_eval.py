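"""Segmentation evaluation and method-agreement analysis.

Dice coefficient of a predicted mask against ground truth,

    dc = 2·TP / (2·TP + FP + FN),

with exact integer pixel counts and a per-pixel confusion map; per-image
aggregation of fragment tables (unweighted mean per parameter, the
convention used when per-fragment analyses are compared with tools that
only report per-image values); and Pearson correlation of paired
per-image means between two analysis routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BinaryMask

# confusion-map pixel codes
TN, TP, FP, FN = 0, 1, 2, 3


@dataclass
class SegmentationEval:
    """Pixel confusion counts for one predicted/truth mask pair."""

    image_name: str
    tp: int
    fp: int
    fn: int
    confusion_map: np.ndarray | None = None

    @property
    def dice(self) -> float:
        return dice(self)


def confusion_counts(pred: BinaryMask, truth: BinaryMask,
                     image_name: str = "", keep_map: bool = True) -> SegmentationEval:
    """Exact TP/FP/FN pixel counts of ``pred`` against ``truth``."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks must share one shape")
    p = pred.pixels
    t = truth.pixels
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    cmap = None
    if keep_map:
        cmap = np.zeros(p.shape, dtype=np.uint8)
        cmap[p & t] = TP
        cmap[p & ~t] = FP
        cmap[~p & t] = FN
    return SegmentationEval(image_name=image_name, tp=tp, fp=fp, fn=fn,
                            confusion_map=cmap)


def dice(ev: SegmentationEval) -> float:
    """dc = 2TP/(2TP+FP+FN); two empty masks agree perfectly (1.0)."""
    denom = 2 * ev.tp + ev.fp + ev.fn
    if denom == 0:
        return 1.0
    return 2 * ev.tp / denom


def dice_score(pred: BinaryMask, truth: BinaryMask) -> float:
    """Convenience: Dice coefficient straight from two masks."""
    return dice(confusion_counts(pred, truth, keep_map=False))


#: fragment-table columns that are averaged into per-image values
AGGREGATE_PARAMS = ("area", "perimeter", "major_axis_length", "minor_axis_length",
                    "circularity", "roundness", "solidity", "mean_intensity",
                    "integrated_intensity", "length")


def per_image_aggregate(records, image_name: str | None = None,
                        params=AGGREGATE_PARAMS, weighted_by_area: bool = False) -> dict:
    """Unweighted arithmetic mean per parameter over one image's fragments.

    ``records`` is a DataFrame or a sequence of FragmentRecord/dict rows
    from a single image.  Zero fragments yield NaN for every parameter.
    ``weighted_by_area`` switches to area-weighted means.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [(r if isinstance(r, dict) else r.as_dict()) for r in records]
        df = pd.DataFrame(rows)
    if image_name is None:
        image_name = str(df["image_name"].iloc[0]) if len(df) else ""
    out: dict = {"image_name": image_name, "n_fragments": int(len(df))}
    for p in params:
        if len(df) == 0 or p not in df.columns:
            out[p] = float("nan")
        elif weighted_by_area:
            w = df["area"].to_numpy(dtype=float)
            out[p] = float(np.average(df[p].to_numpy(dtype=float), weights=w))
        else:
            out[p] = float(df[p].mean())
    return out


def method_agreement(a, b, parameter: str) -> float:
    """Pearson r between two methods' per-image means of one parameter.

    ``a`` and ``b`` are sequences of per-image aggregate dicts (or
    DataFrames) covering the same images.  Requires ≥ 3 paired images;
    zero variance in either vector yields NaN.
    """
    da = pd.DataFrame(a) if not isinstance(a, pd.DataFrame) else a
    db = pd.DataFrame(b) if not isinstance(b, pd.DataFrame) else b
    merged = da[["image_name", parameter]].merge(
        db[["image_name", parameter]], on="image_name", suffixes=("_a", "_b"))
    if set(da["image_name"]) != set(db["image_name"]):
        raise ValueError("the two methods must cover the same image set")
    if len(merged) < 3:
        raise ValueError("method agreement needs at least 3 paired images")
    x = merged[f"{parameter}_a"].to_numpy(dtype=float)
    y = merged[f"{parameter}_b"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)
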