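"""Bind mitochondrial fragments to cells and aggregate per-cell metrics.

Cell masks come from an external cell segmenter (any integer-labelled
TIFF); this module never computes them.  Each fragment is assigned whole
to the cell it overlaps most (ties to the lower cell label); fragments
touching no cell are *orphans* and are excluded from per-cell statistics
but tallied.  Per cell the module reports the mitochondrial-to-cell area
ratio, fragment count, filamentous factor over the assigned fragments,
and mean fragment length and circularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabelMask
from .skeleton_metrics import SkeletonSummary, filamentous_factor


@dataclass
class CellRecord:
    """Per-cell aggregation row."""

    image_name: str
    cell_label: int
    cell_area: float  # µm²
    mito_area: float  # µm²
    mito_to_cell_area_ratio: float
    n_fragments: int
    filamentous_factor: float  # NaN when the cell holds no fragments
    mean_fragment_length: float  # µm; NaN when no fragments
    mean_circularity: float  # NaN when no fragments

    def as_dict(self) -> dict:
        return asdict(self)


CELL_COLUMNS = list(CellRecord.__dataclass_fields__)

ORPHAN = 0  # assignment value for fragments overlapping no cell


def assign_fragments_to_cells(fragments: LabelMask, cells: LabelMask) -> dict[int, int]:
    """Map each fragment label to the cell label with maximal pixel overlap.

    Ties go to the lower cell label; fragments with zero overlap map to
    ``ORPHAN`` (0).
    """
    if fragments.shape != cells.shape:
        raise ValueError("fragment and cell masks must share one shape")
    assignment: dict[int, int] = {}
    objects = ndimage.find_objects(fragments.pixels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        under = cells.pixels[sl][fragments.pixels[sl] == lab]
        under = under[under > 0]
        if under.size == 0:
            assignment[lab] = ORPHAN
            continue
        counts = np.bincount(under)
        assignment[lab] = int(np.argmax(counts))  # argmax → lowest label on ties
    return assignment


def summarize_cells(assignment: dict[int, int],
                    fragment_records,
                    skeleton_summaries: list[SkeletonSummary],
                    cells: LabelMask,
                    lengths: dict[int, float] | None = None,
                    image_name: str = "",
                    clip_to_cell: bool = False,
                    fragments: LabelMask | None = None,
                    exclude_border_cells: bool = False) -> list[CellRecord]:
    """One :class:`CellRecord` per cell label present in the cell mask.

    ``fragment_records`` is a sequence of FragmentRecord (or dicts) with
    ``label``, ``area`` and ``circularity``; ``lengths`` maps fragment
    label → length in µm.  With ``clip_to_cell`` (needs ``fragments``),
    mitochondrial area sums count only pixels inside the assigned cell,
    which guarantees ratio ≤ 1 even when the masks disagree.
    """
    ps = cells.pixel_size
    recs = [(r if isinstance(r, dict) else r.as_dict()) for r in fragment_records]
    by_label = {int(r["label"]): r for r in recs}
    summaries = {s.label: s for s in skeleton_summaries}
    lengths = lengths or {}

    cell_labels = cells.labels()
    if exclude_border_cells:
        border = np.unique(np.concatenate([
            cells.pixels[0, :], cells.pixels[-1, :],
            cells.pixels[:, 0], cells.pixels[:, -1]]))
        cell_labels = np.array([c for c in cell_labels if c not in set(border.tolist())])

    areas = ndimage.sum_labels(np.ones(cells.shape), cells.pixels,
                               index=cell_labels) if len(cell_labels) else []

    by_cell: dict[int, list[int]] = {int(c): [] for c in cell_labels}
    for frag_lab, cell_lab in assignment.items():
        if cell_lab in by_cell:
            by_cell[cell_lab].append(frag_lab)

    out: list[CellRecord] = []
    for c, cell_area_px in zip(cell_labels, areas):
        c = int(c)
        frag_labs = sorted(by_cell[c])
        if clip_to_cell:
            if fragments is None:
                raise ValueError("clip_to_cell requires the fragment label mask")
            inside = (cells.pixels == c)
            mito_px = sum(int(np.sum((fragments.pixels == f) & inside))
                          for f in frag_labs)
            mito_area = mito_px * ps * ps
        else:
            mito_area = sum(by_label[f]["area"] for f in frag_labs if f in by_label)
        cell_area = float(cell_area_px) * ps * ps
        n = len(frag_labs)
        ff = filamentous_factor([summaries[f] for f in frag_labs if f in summaries]) \
            if n else float("nan")
        mean_len = float(np.mean([lengths[f] for f in frag_labs if f in lengths])) \
            if any(f in lengths for f in frag_labs) else float("nan")
        mean_circ = float(np.mean([by_label[f]["circularity"] for f in frag_labs
                                   if f in by_label])) if n else float("nan")
        out.append(CellRecord(
            image_name=image_name,
            cell_label=c,
            cell_area=cell_area,
            mito_area=mito_area,
            mito_to_cell_area_ratio=0.0 if cell_area == 0 else mito_area / cell_area,
            n_fragments=n,
            filamentous_factor=ff,
            mean_fragment_length=mean_len,
            mean_circularity=mean_circ,
        ))
    return out


def orphan_area(assignment: dict[int, int], fragment_records) -> float:
    """Total area (µm²) of fragments assigned to no cell."""
    recs = [(r if isinstance(r, dict) else r.as_dict()) for r in fragment_records]
    by_label = {int(r["label"]): r for r in recs}
    return sum(by_label[f]["area"] for f, c in assignment.items()
               if c == ORPHAN and f in by_label)
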