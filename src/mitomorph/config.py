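"""Pipeline configuration: defaults, YAML parsing, validation.

A single YAML file drives a full run.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import yaml

from .threshold_seg import ThresholdSweepConfig

LENGTH_MODES = ("longest_path", "total")
FF_LEVELS = ("cell", "image")
SELECTION_MODES = ("auto_otsu", "max_dice_vs_truth", "manual_index")
PERIMETER_MODES = ("crofton", "boundary")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs beyond its input paths."""

    pixel_size_um: float | None = None  # None: TIFF tags, else 1.0 µm/px
    z_step_um: float = 0.25
    sweep: ThresholdSweepConfig = field(default_factory=ThresholdSweepConfig)
    selection_mode: str = "auto_otsu"
    manual_index: int | None = None
    length_mode: str = "longest_path"
    ff_level: str = "cell"
    perimeter_mode: str = "crofton"
    clip_fragments_to_cells: bool = False
    exclude_border_cells: bool = False
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.length_mode not in LENGTH_MODES:
            raise ValueError(f"length_mode must be one of {LENGTH_MODES}")
        if self.ff_level not in FF_LEVELS:
            raise ValueError(f"ff_level must be one of {FF_LEVELS}")
        if self.selection_mode not in SELECTION_MODES:
            raise ValueError(f"selection_mode must be one of {SELECTION_MODES}")
        if self.perimeter_mode not in PERIMETER_MODES:
            raise ValueError(f"perimeter_mode must be one of {PERIMETER_MODES}")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("sweep", {}).get("thresholds"), tuple):
            d["sweep"]["thresholds"] = list(d["sweep"]["thresholds"])
        return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing path means all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    sweep_raw = kwargs.pop("sweep", None)
    if sweep_raw is not None:
        sweep_known = {f.name for f in dc_fields(ThresholdSweepConfig)}
        sweep_unknown = set(sweep_raw) - sweep_known
        if sweep_unknown:
            raise ValueError(f"unknown sweep config keys: {sorted(sweep_unknown)}")
        # thresholds: an explicit list, or {min, max, step} for a range
        t = sweep_raw.get("thresholds")
        if isinstance(t, dict):
            if set(t) != {"min", "max", "step"}:
                raise ValueError("threshold range needs exactly min, max, step")
            sweep_raw["thresholds"] = (t["min"], t["max"], t["step"])
        if isinstance(sweep_raw.get("auto_percentiles"), list):
            sweep_raw["auto_percentiles"] = tuple(sweep_raw["auto_percentiles"])
        kwargs["sweep"] = ThresholdSweepConfig(**sweep_raw)
    return PipelineConfig(**kwargs)
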