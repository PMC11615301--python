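"""End-to-end analysis run binding all stages together.

One call takes a fluorescence image (z-stack or 2D), an optional external
binary mask (e.g. from a deep-learning segmenter), and an optional cell
label mask, and writes the three output tables:

* ``fragments.csv`` — one row per mitochondrial fragment (morphology +
  skeleton metrics),
* ``image_aggregates.csv`` — per-image means over fragments,
* ``cells.csv`` — per-cell aggregation, only when a cell mask is given,

plus the selected segmentation mask and a JSON run manifest (config echo,
package version, input checksums).  With fixed inputs and config the CSV
outputs are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .cell_assign import (CELL_COLUMNS, assign_fragments_to_cells, orphan_area,
                          summarize_cells)
from .config import PipelineConfig
from .fragment_morph import FRAGMENT_COLUMNS, label_fragments, measure_fragments
from .seg_eval import per_image_aggregate
from .skeleton_metrics import (filamentous_factor, fragment_length,
                               summarize_fragments)
from .threshold_seg import preprocess, select_candidate, sweep_thresholds

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def fragment_table(mask: mio.BinaryMask, image: mio.Image2D,
                   cfg: PipelineConfig) -> tuple[pd.DataFrame, mio.LabelMask, list]:
    """Per-fragment morphology + skeleton metrics for one image."""
    labels = label_fragments(mask)
    records = measure_fragments(labels, image, perimeter_mode=cfg.perimeter_mode)
    summaries = summarize_fragments(labels)
    by_label = {s.label: s for s in summaries}
    rows = []
    for rec in records:
        s = by_label[rec.label]
        row = rec.as_dict()
        row["length"] = fragment_length(s, rec.area, mode=cfg.length_mode)
        row["n_junctions"] = s.n_junctions
        row["n_branches"] = s.n_branches
        row["n_endpoints"] = s.n_endpoints
        row["total_skeleton_length"] = s.total_skeleton_length
        row["longest_path_length"] = s.longest_path_length
        rows.append(row)
    columns = FRAGMENT_COLUMNS + ["length", "n_junctions", "n_branches",
                                  "n_endpoints", "total_skeleton_length",
                                  "longest_path_length"]
    df = pd.DataFrame(rows, columns=columns)
    return df, labels, summaries


def run_pipeline(cfg: PipelineConfig,
                 image_path: str | Path,
                 out_dir: str | Path,
                 mask_path: str | Path | None = None,
                 cells_path: str | Path | None = None,
                 truth_path: str | Path | None = None) -> dict:
    """Run segmentation + the three analysis approaches; write artefacts.

    Returns a summary dict (paths written, fragment/cell counts, image FF).
    """
    image_path = Path(image_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {"image": image_path}

    obj = mio.read_tiff(image_path, pixel_size=cfg.pixel_size_um,
                        z_step=cfg.z_step_um)
    if isinstance(obj, mio.ZStack):
        image = mio.max_intensity_projection(obj)
    else:
        image = obj

    truth = None
    if truth_path is not None:
        truth_path = Path(truth_path)
        truth = mio.read_binary_mask(truth_path, pixel_size=image.pixel_size,
                                     provenance="ground_truth")
        inputs["truth"] = truth_path

    if mask_path is not None:
        mask_path = Path(mask_path)
        mask = mio.read_binary_mask(mask_path, pixel_size=image.pixel_size,
                                    provenance="external")
        inputs["mask"] = mask_path
        pre = None
    else:
        pre = preprocess(image, cfg.sweep)
        sweep = sweep_thresholds(pre, cfg.sweep)
        mask = select_candidate(sweep, mode=cfg.selection_mode, truth=truth,
                                preprocessed=pre, manual_index=cfg.manual_index)
        summary_rows = [{"threshold": t,
                         "foreground_px": int(c.pixels.sum())}
                        for t, c in zip(sweep.thresholds, sweep.candidates)]
        mio.write_table(pd.DataFrame(summary_rows), out_dir / "sweep_summary.csv")
    if mask.shape != image.shape:
        raise ValueError("segmentation mask and image shapes differ")

    mio.write_tiff(mask, out_dir / "selected_mask.tif")

    df, labels, summaries = fragment_table(mask, image, cfg)
    mio.write_table(df, out_dir / "fragments.csv")

    agg = per_image_aggregate(df, image_name=image.name)
    agg["filamentous_factor"] = filamentous_factor(summaries)
    mio.write_table(pd.DataFrame([agg]), out_dir / "image_aggregates.csv")

    result = {
        "out_dir": str(out_dir),
        "n_fragments": int(len(df)),
        "image_filamentous_factor": agg["filamentous_factor"],
    }

    if cells_path is not None:
        cells_path = Path(cells_path)
        cells = mio.read_label_mask(cells_path, pixel_size=image.pixel_size)
        inputs["cells"] = cells_path
        assignment = assign_fragments_to_cells(labels, cells)
        lengths = dict(zip(df["label"].astype(int), df["length"]))
        cell_records = summarize_cells(
            assignment, df.to_dict("records"), summaries, cells,
            lengths=lengths, image_name=image.name,
            clip_to_cell=cfg.clip_fragments_to_cells, fragments=labels,
            exclude_border_cells=cfg.exclude_border_cells)
        mio.write_table([r.as_dict() for r in cell_records],
                        out_dir / "cells.csv", columns=CELL_COLUMNS)
        result["n_cells"] = len(cell_records)
        result["orphan_area"] = orphan_area(assignment, df.to_dict("records"))

    manifest = {
        "package": "mitomorph",
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)}
                   for k, p in inputs.items()},
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return result
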