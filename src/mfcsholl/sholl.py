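"""Linear Sholl analysis: grid lines, intersection counting, normalization.

The readout of the pipeline: the number of axonal intersections on vertical
grid lines drawn every ``grid_spacing_um`` (default 50 μm) from the
microgroove exit, normalized by the number of neurons in the main channel.
Distance 0 is the exit; by default the first measured line sits at 100 μm
because debris accumulates at the exits after an in vitro axotomy and would
corrupt the 50 μm line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, um_to_px
from .errors import NormalizationError, ValidationError

SIDES = ("left", "right")


@dataclass
class ShollProfile:
    """Per-grid-line intersection counts for one axonal compartment.

    ``normalized`` is always the correctly rounded quotient
    ``intersections / soma_count`` computed at construction, never a value
    set independently: the integer counts are recovered exactly by rounding
    ``normalized * soma_count``. (Bit-exact float equality of the product is
    unattainable for non-dyadic ratios such as 28/194 — no double satisfies
    ``q * 194 == 28``.)
    """

    distances_um: np.ndarray
    intersections: np.ndarray
    soma_count: int
    side: str
    intersection_mode: str = "runs"
    chamber_id: str = "chamber"
    normalized: np.ndarray = field(init=False)

    def __post_init__(self):
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.intersection_mode not in ("runs", "pixels"):
            raise ValidationError("intersection_mode must be 'runs' or 'pixels'")
        if self.distances_um.shape != self.intersections.shape:
            raise ValidationError("distances and intersections differ in length")
        if np.any(self.intersections < 0):
            raise ValidationError("intersection counts must be non-negative")
        if self.soma_count < 1:
            raise NormalizationError(
                f"soma_count must be >= 1 to normalize, got {self.soma_count}")
        n = len(self.distances_um)
        if n >= 2:
            steps = np.diff(self.distances_um)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValidationError("grid distances must increase with constant spacing")
        self.soma_count = int(self.soma_count)
        self.normalized = self.intersections / self.soma_count

    @property
    def spacing_um(self) -> float:
        if len(self.distances_um) >= 2:
            return float(self.distances_um[1] - self.distances_um[0])
        return math.nan

    def __len__(self):
        return len(self.distances_um)


def grid_columns(alignment, side: str, config: PipelineConfig):
    """Pixel columns of the grid lines for one analysis zone.

    Returns ``(columns, distances_um)``. Lines sit at
    ``first_line_um + k * grid_spacing_um`` from the microgroove exit; the
    pixel column is the exit column plus/minus the offset rounded half away
    from the exit. Left-side columns count leftward from the left exit
    (distance 0 is the exit for both sides). Lines falling outside the
    half-open zone interval are dropped, not clamped; a zone too narrow for
    any line yields empty arrays plus a warning.
    """
    if side not in SIDES:
        raise ValidationError(f"side must be one of {SIDES}, got {side!r}")
    x_left_exit, x_right_exit = alignment.groove_band
    if side == "right":
        exit_col = x_right_exit
        x0, x1 = alignment.right_zone
        sign = +1
    else:
        exit_col = x_left_exit
        x0, x1 = alignment.left_zone
        sign = -1
    cols, dists = [], []
    d = config.first_line_um
    while True:
        offset = um_to_px(d, config.pixel_size_um)
        col = exit_col + sign * int(math.floor(offset + 0.5))
        if not (x0 <= col < x1):
            break
        cols.append(col)
        dists.append(d)
        d += config.grid_spacing_um
    if not cols:
        warnings.warn(
            f"analysis zone [{x0}, {x1}) too narrow for a grid line at "
            f"{config.first_line_um} um; empty profile", stacklevel=2)
    return np.asarray(cols, dtype=int), np.asarray(dists, dtype=float)


def count_intersections(skeleton, columns, mode: str = "runs") -> np.ndarray:
    """Count axonal intersections of a skeleton with each vertical grid line.

    mode='pixels' counts foreground skeleton pixels in the one-pixel-wide
    column; mode='runs' (default) counts maximal vertically contiguous runs
    of foreground pixels, so one transversal crossing contributes one
    intersection regardless of how many pixels it occupies.
    """
    pixels = np.asarray(getattr(skeleton, "pixels", skeleton)).astype(bool)
    columns = np.asarray(columns, dtype=int)
    if columns.size == 0:
        return np.zeros(0, dtype=int)
    if columns.min() < 0 or columns.max() >= pixels.shape[1]:
        raise ValidationError("grid column outside the skeleton raster")
    if mode == "pixels":
        return pixels[:, columns].sum(axis=0).astype(int)
    if mode == "runs":
        cols = pixels[:, columns]
        starts = cols & ~np.vstack([np.zeros((1, cols.shape[1]), dtype=bool), cols[:-1]])
        return starts.sum(axis=0).astype(int)
    raise ValidationError(f"unknown intersection mode {mode!r}")


def normalize_profile(distances_um, intersections, soma_count: int, side: str,
                      intersection_mode: str = "runs",
                      chamber_id: str = "chamber") -> ShollProfile:
    """Build a :class:`ShollProfile`, normalizing counts by the soma count."""
    if soma_count is None or soma_count < 1:
        raise NormalizationError(f"cannot normalize by soma_count={soma_count}")
    return ShollProfile(
        distances_um=distances_um,
        intersections=intersections,
        soma_count=int(soma_count),
        side=side,
        intersection_mode=intersection_mode,
        chamber_id=chamber_id,
    )


def outermost_gridline(profile: ShollProfile):
    """Largest grid-line distance still harboring an intersection, or None.

    Interior zeros are irrelevant: the outermost line is defined purely by
    the farthest nonzero count. Summaries across replicates (the median per
    treatment) live in :mod:`mfcsholl.stats`.
    """
    nz = np.nonzero(profile.intersections)[0]
    if nz.size == 0:
        return None
    return float(profile.distances_um[nz[-1]])
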