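"""Chamber alignment: Hough-based rotation estimation and zone location.

The chamber's straight walls and the parallel microgroove array dominate the
edge map of the phase-contrast channel, so the in-plane rotation is the
angle at which a straight-line Hough transform of the edge pixels
concentrates its votes. Both the near-vertical family (microgroove exits,
compartment walls) and the near-horizontal family (groove walls, channel
walls) vote for the same chamber angle.

Conventions: pixel indices are 0-based; zone intervals are half-open
``[x_start, x_end)``; a positive ``angle_deg`` means the chamber appears
rotated counter-clockwise in the image (array displayed row 0 on top), so
aligning means rotating the image content clockwise by the same amount.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.transform import hough_line

from .config import PipelineConfig, um_to_px
from .errors import AlignmentFailureError, ConfigurationError, DegenerateImageError
from .image_io import ChamberImage

# peak-to-median Hough score ratio below which no orientation is trusted
_NOISE_FLOOR_RATIO = 1.5


@dataclass(frozen=True)
class AlignmentResult:
    """Rotation angle and analysis-zone boundaries in the rotated frame.

    ``left_zone`` = (x_outer, x_exit), ``right_zone`` = (x_exit, x_outer),
    ``groove_band`` = (x_left_exit, x_right_exit); all half-open column
    intervals in the axis-aligned frame.
    """

    angle_deg: float
    left_zone: tuple
    right_zone: tuple
    groove_band: tuple

    def validate(self, config: PipelineConfig, image_width: int) -> None:
        xl, xr = self.groove_band
        band_um = (xr - xl) * config.pixel_size_um
        tol = config.band_tolerance_frac * config.groove_length_um
        if not (abs(band_um - config.groove_length_um) <= tol):
            raise AlignmentFailureError(
                f"groove band width {band_um:.1f} um deviates from "
                f"{config.groove_length_um} um by more than {tol:.1f} um",
                candidates=(xl, xr))
        for name, (a, b) in (("left_zone", self.left_zone), ("right_zone", self.right_zone)):
            if not (0 <= a < b <= image_width):
                raise AlignmentFailureError(f"{name} {a, b} empty or outside the image")
        if not (self.left_zone[1] <= xl < xr <= self.right_zone[0]):
            raise AlignmentFailureError("zones overlap the groove band")


def _edge_map(raster: np.ndarray, quantile: float) -> np.ndarray:
    """Binary edge map: gradient magnitude above a robust quantile."""
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ConfigurationError("phase raster must be 2-D")
    if np.ptp(raster) == 0:
        raise DegenerateImageError("constant image: no edges to align on")
    gy = ndimage.sobel(raster, axis=0)
    gx = ndimage.sobel(raster, axis=1)
    mag = np.hypot(gx, gy)
    thr = np.quantile(mag, quantile)
    edges = mag > thr
    if not edges.any():
        raise DegenerateImageError("no edge pixels above the gradient quantile")
    return edges


def _hough_scores(edges: np.ndarray, cand_deg: np.ndarray) -> np.ndarray:
    """Peak-energy score for each candidate chamber angle.

    For candidate angle a, chamber lines appear at Hough normal angles
    -a (vertical family) and -a±90° (horizontal family). The score is the
    mean of the strongest accumulator bins in those two columns, which
    rewards votes concentrating onto few straight lines.
    """
    cand = np.asarray(cand_deg, dtype=float)
    theta_v = np.deg2rad(-cand)
    theta_h = np.deg2rad(np.where(cand <= 0, -cand - 90.0, 90.0 - cand))
    thetas = np.concatenate([theta_v, theta_h])
    acc, _, _ = hough_line(edges, theta=thetas)
    acc = acc.astype(float)
    k = max(1, min(10, acc.shape[0] // 100))
    top = np.sort(acc, axis=0)[-k:, :].mean(axis=0)
    n = cand.size
    return top[:n] + top[n:]


def estimate_rotation(phase, search_half_range_deg: float = 15.0,
                      resolution_deg: float = 0.05,
                      edge_quantile: float = 0.95) -> float:
    """Estimate the chamber's in-plane rotation from the phase channel.

    Runs a coarse-to-fine Hough search over ``±search_half_range_deg``;
    deterministic, ties broken toward the smallest ``|angle|``. Raises
    :class:`DegenerateImageError` on constant input and
    :class:`AlignmentFailureError` when no orientation stands out of the
    Hough noise floor.
    """
    if search_half_range_deg <= 0 or resolution_deg <= 0:
        raise ConfigurationError("search range and resolution must be > 0")
    edges = _edge_map(phase, edge_quantile)

    coarse_step = max(resolution_deg, 0.5)
    cand = _symmetric_grid(search_half_range_deg, coarse_step)
    scores = _hough_scores(edges, cand)
    if scores.max() < _NOISE_FLOOR_RATIO * max(np.median(scores), 1e-12):
        raise AlignmentFailureError(
            "no Hough orientation peak above the noise floor")
    best = _pick_smallest_abs(cand, scores)

    if coarse_step > resolution_deg:
        lo = max(-search_half_range_deg, best - coarse_step)
        hi = min(search_half_range_deg, best + coarse_step)
        fine = np.arange(lo, hi + resolution_deg / 2, resolution_deg)
        fine_scores = _hough_scores(edges, fine)
        best = _pick_smallest_abs(fine, fine_scores)
    return float(best)


def _symmetric_grid(half_range: float, step: float) -> np.ndarray:
    n = int(round(half_range / step))
    return np.arange(-n, n + 1) * step


def _pick_smallest_abs(cand: np.ndarray, scores: np.ndarray) -> float:
    best_score = scores.max()
    tied = np.flatnonzero(scores >= best_score - 1e-12)
    return float(cand[tied[np.argmin(np.abs(cand[tied]))]])


def rotate_channels(image: ChamberImage, angle_deg: float, order: int = 1) -> ChamberImage:
    """Rotate all channels by ``-angle_deg`` about the image center.

    Output size expands to hold the whole rotated frame (the template stays
    centered); spline order 1 (bilinear) by default, order 0 (nearest) is
    binary-safe for masks. ``angle_deg == 0`` returns the channels
    unchanged.
    """
    if not np.isfinite(angle_deg):
        raise ConfigurationError("rotation angle must be finite")
    if angle_deg % 360.0 == 0.0:
        return ChamberImage(channels=dict(image.channels),
                            pixel_size_um=image.pixel_size_um)
    out = {}
    for role, arr in image.channels.items():
        rot = ndimage.rotate(arr, -angle_deg, reshape=True, order=order,
                             mode="constant", cval=0, prefilter=order > 1)
        out[role] = rot.astype(arr.dtype) if order == 0 else rot
    return ChamberImage(channels=out, pixel_size_um=image.pixel_size_um)


def _column_edge_profile(raster: np.ndarray) -> np.ndarray:
    """Strength of vertical edges per pixel column."""
    gx = ndimage.sobel(np.asarray(raster, dtype=float), axis=1)
    return np.abs(gx).sum(axis=0)


def locate_zones(aligned_phase, config: PipelineConfig,
                 angle_deg: float = 0.0) -> AlignmentResult:
    """Locate the microgroove band and both analysis zones.

    Finds the pair of dominant vertical edge lines whose separation best
    matches ``groove_length_um`` (the two microgroove exits), then extends
    each analysis zone outward to the nearest strong vertical edge (the
    compartment wall) or, failing that, to the image border minus a guard.
    """
    raster = np.asarray(aligned_phase, dtype=float)
    if raster.ndim != 2:
        raise ConfigurationError("aligned phase raster must be 2-D")
    if np.ptp(raster) == 0:
        raise DegenerateImageError("constant image: cannot locate zones")
    width = raster.shape[1]
    profile = _column_edge_profile(raster)

    expected_px = um_to_px(config.groove_length_um, config.pixel_size_um)
    tol_px = config.band_tolerance_frac * expected_px
    min_dist = max(3, int(expected_px * 0.05))
    prominence = 0.1 * (profile.max() - np.median(profile))
    peaks, props = find_peaks(profile, distance=min_dist, prominence=max(prominence, 1e-9))
    # a genuine wall/exit line must stand clearly above the unstructured
    # column-gradient baseline; random textures never do
    floor = 1.3 * np.median(profile)
    peaks = peaks[profile[peaks] >= floor]
    if peaks.size < 2:
        raise AlignmentFailureError(
            "fewer than two vertical edge lines stand above the noise floor",
            candidates=peaks.tolist())
    strengths = profile[peaks]

    best_pair, best_score = None, -np.inf
    for i in range(peaks.size):
        for j in range(i + 1, peaks.size):
            sep = peaks[j] - peaks[i]
            if abs(sep - expected_px) <= tol_px:
                score = strengths[i] + strengths[j]
                if score > best_score:
                    best_score = score
                    best_pair = (int(peaks[i]), int(peaks[j]))
    if best_pair is None:
        raise AlignmentFailureError(
            f"no vertical line pair separated by ~{expected_px:.0f} px "
            f"(tolerance ±{tol_px:.0f} px)", candidates=peaks.tolist())
    x_left_exit, x_right_exit = best_pair
    exit_strength = (profile[x_left_exit] + profile[x_right_exit]) / 2

    guard = config.border_guard_px
    x_left_outer = _outer_wall(peaks, strengths, x_left_exit, exit_strength,
                               side="left", fallback=guard, min_zone=min_dist)
    x_right_outer = _outer_wall(peaks, strengths, x_right_exit, exit_strength,
                                side="right", fallback=width - guard, min_zone=min_dist)
    result = AlignmentResult(
        angle_deg=float(angle_deg),
        left_zone=(x_left_outer, x_left_exit),
        right_zone=(x_right_exit, x_right_outer),
        groove_band=(x_left_exit, x_right_exit),
    )
    result.validate(config, width)
    return result


def _outer_wall(peaks, strengths, exit_col, exit_strength, side, fallback, min_zone):
    """Innermost strong vertical edge beyond the exit, else the fallback."""
    if side == "left":
        sel = peaks < exit_col - min_zone
    else:
        sel = peaks > exit_col + min_zone
    cand = peaks[sel]
    cand_s = strengths[sel]
    strong = cand[cand_s >= 0.3 * exit_strength]
    if strong.size == 0:
        return int(fallback)
    # the wall nearest the exit bounds the compartment from outside
    return int(strong.max()) if side == "left" else int(strong.min())
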