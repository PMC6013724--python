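"""Pipeline configuration and the single μm→px conversion utility.

All physical parameters are expressed in micrometres; every conversion to
pixels goes through :func:`um_to_px` so that rounding conventions cannot
drift between modules.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


def um_to_px(length_um: float, pixel_size_um: float) -> float:
    """Convert a physical length to (fractional) pixels.

    Callers decide how to round; keeping the conversion un-rounded here lets
    each site apply its documented rounding rule (grid lines round half away
    from the exit, window sizes round to the nearest odd integer, ...).
    """
    if not (pixel_size_um > 0 and math.isfinite(pixel_size_um)):
        raise ConfigurationError(f"pixel_size_um must be finite and > 0, got {pixel_size_um}")
    return float(length_um) / float(pixel_size_um)


def odd_window_px(length_um: float, pixel_size_um: float, minimum: int = 3) -> int:
    """Convert a window size in μm to the nearest odd pixel count, at least ``minimum``."""
    px = int(round(um_to_px(length_um, pixel_size_um)))
    if px % 2 == 0:
        px += 1
    return max(px, minimum)


@dataclass
class PipelineConfig:
    """All tunable parameters of the chamber-analysis pipeline.

    Physical defaults follow the chamber geometry the pipeline targets:
    500 μm microgrooves, grid lines every 50 μm, first measured line at
    100 μm from the microgroove exits (the 50 μm line is skipped because
    axonal debris accumulates at the exits after axotomy).
    """

    pixel_size_um: float = 1.3
    groove_length_um: float = 500.0
    grid_spacing_um: float = 50.0
    first_line_um: float = 100.0
    omit_debris_line: bool = True
    intersection_mode: str = "runs"

    # adaptive-threshold segmentation
    seg_block_size_um: float = 51.0
    seg_offset_frac: float = 0.05
    seg_min_area_um2: float = 20.0
    seg_presmooth_um: float = 1.0

    # soma counting
    soma_smoothing_um: float = 5.0
    soma_min_area_um2: float = 80.0
    soma_max_area_um2: float = 800.0

    # rotation estimation / zone location
    rotation_half_range_deg: float = 15.0
    rotation_resolution_deg: float = 0.05
    edge_quantile: float = 0.95
    band_tolerance_frac: float = 0.10
    vertical_margin_um: float = 0.0
    border_guard_px: int = 10

    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (self.pixel_size_um > 0 and math.isfinite(self.pixel_size_um)):
            raise ConfigurationError("pixel_size_um must be finite and > 0")
        for name in ("groove_length_um", "grid_spacing_um", "first_line_um",
                     "rotation_half_range_deg", "rotation_resolution_deg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        ratio = self.first_line_um / self.grid_spacing_um
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigurationError(
                "first_line_um must be a positive multiple of grid_spacing_um")
        if self.omit_debris_line and self.first_line_um < 2 * self.grid_spacing_um:
            raise ConfigurationError(
                "with omit_debris_line, first_line_um must be >= 2 * grid_spacing_um")
        if self.intersection_mode not in ("runs", "pixels"):
            raise ConfigurationError("intersection_mode must be 'runs' or 'pixels'")
        if not (0 <= self.seg_offset_frac < 1):
            raise ConfigurationError("seg_offset_frac must lie in [0, 1)")
        if not (0 < self.soma_min_area_um2 < self.soma_max_area_um2):
            raise ConfigurationError("soma area bounds must satisfy 0 < min < max")

    # ----- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        """Load a config from a YAML or JSON file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
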