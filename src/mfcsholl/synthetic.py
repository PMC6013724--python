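"""Synthetic chamber images with exhaustive ground truth.

Every pipeline stage is testable without real microscopy data: the generator
renders a rotated chamber template (a 500 μm microgroove band flanked by two
axonal compartments), curvilinear axons emanating outward from the
microgroove exits, disk-like somata with a known count, and additive /
shot noise — while recording the true rotation angle, the axon polylines
(so grid-line crossings can be counted exactly), and the soma centroids.

Axons are persistent random walks whose heading is kept strictly within
±``max_heading_deg`` (< 90°) of the outward axis, so every step advances
away from the exit and no segment can run parallel to a vertical grid line:
all crossings are transversal and the exact per-line crossing count is the
number of sign changes of ``x − d`` along each polyline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .errors import ConfigurationError
from .image_io import ChamberImage

SIDES = ("left", "right")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic chamber; a fixed seed gives bit-identical output.

    Lengths are in μm unless suffixed ``_px``. The defaults emulate a
    stitched 10× wide-field image of a tripartite chamber: 1.3 μm pixels,
    500 μm microgroove band, 1 mm axonal compartments, ~30 axons per side
    with a mean length of 600 μm, and ~120 somata of 6–11 μm radius in the
    main-channel strip.
    """

    # geometry
    pixel_size_um: float = 1.3
    compartment_width_um: float = 1000.0
    groove_length_um: float = 500.0
    margin_um: float = 65.0
    chamber_height_um: float = 900.0
    groove_pitch_um: float = 50.0
    groove_width_um: float = 10.0
    main_channel_width_um: float = 300.0
    rotation_deg: float = 0.0

    # axons
    axons_per_side: int = 30
    axon_step_um: float = 25.0
    heading_sigma_deg: float = 18.0
    max_heading_deg: float = 78.0
    mean_length_um: float = 600.0
    axon_amplitude: float = 600.0
    axon_width_px: float = 1.5

    # somata
    soma_count: int = 120
    soma_radius_um: tuple = (6.0, 11.0)
    soma_amplitude: float = 800.0
    touching_fraction: float = 0.0

    # signal / noise
    background: float = 50.0
    phase_background: float = 1000.0
    noise_sd: float = 25.0
    shot_noise: bool = False
    ramp_amplitude: float = 0.0

    seed: int = 0

    def __post_init__(self):
        for name in ("pixel_size_um", "compartment_width_um", "groove_length_um",
                     "chamber_height_um", "groove_pitch_um", "groove_width_um",
                     "axon_step_um", "mean_length_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0 < self.max_heading_deg < 90):
            raise ConfigurationError("max_heading_deg must lie in (0, 90)")
        if self.axons_per_side < 0 or self.soma_count < 0:
            raise ConfigurationError("counts must be non-negative")

    # template-frame landmarks, in (fractional) pixels -------------------

    @property
    def template_shape(self):
        h = int(round(self.chamber_height_um / self.pixel_size_um))
        w_um = 2 * self.margin_um + 2 * self.compartment_width_um + self.groove_length_um
        return (h, int(round(w_um / self.pixel_size_um)))

    @property
    def exit_cols(self):
        psz = self.pixel_size_um
        xl = (self.margin_um + self.compartment_width_um) / psz
        xr = xl + self.groove_length_um / psz
        return (xl, xr)

    @property
    def wall_cols(self):
        psz = self.pixel_size_um
        return (self.margin_um / psz, self.template_shape[1] - self.margin_um / psz)


@dataclass
class SyntheticTruth:
    """Ground truth recorded before noise is applied.

    Axon polylines are stored per side as (n, 2) arrays of
    ``(distance_from_exit_um, y_um)`` vertices; soma centers as template
    frame ``(x_px, y_px)``.
    """

    rotation_deg: float
    pixel_size_um: float
    template_shape: tuple
    exit_cols: tuple
    wall_cols: tuple
    polylines: dict
    soma_centers: list
    soma_count: int
    spec: SyntheticSpec

    def aligned_exit_cols(self, aligned_shape) -> tuple:
        """Expected exit columns after rotating the image back to axis alignment.

        Both rotations are about the image center with an expanding canvas,
        so the template ends up centered: columns shift by half the width
        difference.
        """
        off = (aligned_shape[1] - self.template_shape[1]) / 2.0
        return (self.exit_cols[0] + off, self.exit_cols[1] + off)


# ---------------------------------------------------------------------------
# axon polylines and the exact crossing oracle


def _groove_centers_um(spec: SyntheticSpec) -> np.ndarray:
    """y positions (μm) of the microgroove centerlines."""
    pitch = spec.groove_pitch_um
    n = int(spec.chamber_height_um // pitch)
    return (np.arange(n) + 0.5) * pitch + (spec.chamber_height_um - n * pitch) / 2


def sample_axon_polylines(spec: SyntheticSpec, rng: np.random.Generator) -> dict:
    """Persistent outward random walks starting at the microgroove exits.

    Returns {'left': [...], 'right': [...]} with (n, 2) float arrays of
    (d_um, y_um); d grows strictly along each polyline.
    """
    grooves = _groove_centers_um(spec)
    y_lo, y_hi = 2.0, spec.chamber_height_um - 2.0
    max_head = math.radians(spec.max_heading_deg)
    sigma = math.radians(spec.heading_sigma_deg)
    mean_steps = max(spec.mean_length_um / spec.axon_step_um, 1.0)
    out = {}
    for side in SIDES:
        polys = []
        for _ in range(spec.axons_per_side):
            if grooves.size:
                y = grooves[rng.integers(grooves.size)]
                y += rng.uniform(-spec.groove_width_um / 2, spec.groove_width_um / 2)
            else:
                y = rng.uniform(y_lo, y_hi)
            n_steps = 1 + rng.geometric(1.0 / mean_steps)
            heading = np.clip(rng.normal(0.0, sigma), -max_head, max_head)
            d = 0.0
            verts = [(d, y)]
            for _ in range(n_steps):
                heading = np.clip(heading + rng.normal(0.0, sigma), -max_head, max_head)
                d += spec.axon_step_um * math.cos(heading)
                y += spec.axon_step_um * math.sin(heading)
                if y < y_lo:
                    y = 2 * y_lo - y
                    heading = -heading
                elif y > y_hi:
                    y = 2 * y_hi - y
                    heading = -heading
                verts.append((d, y))
            polys.append(np.asarray(verts, dtype=float))
        out[side] = polys
    return out


def crossings_of_polyline(d_coords, line_d: float) -> int:
    """Transversal crossings of one polyline with the vertical line at ``line_d``.

    Strict-straddle convention: a crossing is a sign change of ``d − line_d``
    along the vertex sequence with exact zeros compressed away, so a vertex
    sitting exactly on the line counts only when the polyline continues to
    the other side, and an endpoint on the line never counts.
    """
    s = np.sign(np.asarray(d_coords, dtype=float) - line_d)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def truth_crossings(truth: SyntheticTruth, distances_um, side: str) -> np.ndarray:
    """Exact per-grid-line crossing counts from the stored polylines."""
    distances_um = np.asarray(distances_um, dtype=float)
    counts = np.zeros(distances_um.shape, dtype=int)
    for poly in truth.polylines.get(side, []):
        for i, d in enumerate(distances_um):
            counts[i] += crossings_of_polyline(poly[:, 0], d)
    return counts


# ---------------------------------------------------------------------------
# rasterization


def _clip_segment(p0, p1, h, w):
    """Liang–Barsky clip of segment p0→p1 (row, col floats) to the raster; None if outside."""
    t0, t1 = 0.0, 1.0
    dr, dc = p1[0] - p0[0], p1[1] - p0[1]
    for p, q in ((-dr, p0[0]), (dr, h - 1 - p0[0]), (-dc, p0[1]), (dc, w - 1 - p0[1])):
        if p == 0:
            if q < 0:
                return None
        else:
            t = q / p
            if p < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
    if t0 > t1:
        return None
    a = (p0[0] + t0 * dr, p0[1] + t0 * dc)
    b = (p0[0] + t1 * dr, p0[1] + t1 * dc)
    return a, b


def rasterize_polylines(polys, shape, exit_col: float, side: str,
                        pixel_size_um: float) -> np.ndarray:
    """Draw polylines as 1-px-wide 8-connected curves into a boolean raster.

    ``exit_col`` is the (template frame) column of this side's microgroove
    exit; distance grows rightward for the right side and leftward for the
    left side.
    """
    sign = 1.0 if side == "right" else -1.0
    canvas = np.zeros(shape, dtype=bool)
    h, w = shape
    for poly in polys:
        cols = exit_col + sign * poly[:, 0] / pixel_size_um
        rows = poly[:, 1] / pixel_size_um
        for k in range(len(poly) - 1):
            seg = _clip_segment((rows[k], cols[k]), (rows[k + 1], cols[k + 1]), h, w)
            if seg is None:
                continue
            (r0, c0), (r1, c1) = seg
            rr, cc = draw_line(int(round(r0)), int(round(c0)),
                               int(round(r1)), int(round(c1)))
            canvas[rr, cc] = True
    return canvas


def _line_peak_factor(sigma_px: float) -> float:
    """Peak intensity of a unit 1-px line after Gaussian blurring."""
    probe = np.zeros((31, 31))
    probe[15, :] = 1.0
    return float(ndimage.gaussian_filter(probe, sigma_px).max())


# ---------------------------------------------------------------------------
# channel rendering


def _render_phase(spec: SyntheticSpec) -> np.ndarray:
    h, w = spec.template_shape
    psz = spec.pixel_size_um
    img = np.full((h, w), spec.phase_background, dtype=float)
    dark = 0.4 * spec.phase_background
    xl_exit, xr_exit = spec.exit_cols
    xl_wall, xr_wall = spec.wall_cols
    for x in (xl_wall, xl_exit, xr_exit, xr_wall):
        c = int(round(x))
        img[:, max(c, 0):min(c + 2, w)] = dark
    # horizontal microgroove walls across the band
    c0, c1 = int(round(xl_exit)), int(round(xr_exit)) + 2
    for y_um in np.arange(spec.groove_pitch_um, spec.chamber_height_um,
                          spec.groove_pitch_um):
        r = int(round(y_um / psz))
        if 0 <= r < h:
            img[r, c0:c1] = 0.5 * spec.phase_background
    # chamber top/bottom walls
    img[:2, :] = dark
    img[-2:, :] = dark
    return img


def _render_axons(spec: SyntheticSpec, polylines: dict) -> np.ndarray:
    h, w = spec.template_shape
    xl_exit, xr_exit = spec.exit_cols
    centerlines = np.zeros((h, w), dtype=bool)
    centerlines |= rasterize_polylines(polylines["right"], (h, w), xr_exit,
                                       "right", spec.pixel_size_um)
    centerlines |= rasterize_polylines(polylines["left"], (h, w), xl_exit,
                                       "left", spec.pixel_size_um)
    sigma = spec.axon_width_px / 2.355  # FWHM -> sigma
    img = ndimage.gaussian_filter(centerlines.astype(float), sigma)
    peak = _line_peak_factor(sigma)
    img = spec.background + spec.axon_amplitude * img / peak
    if spec.ramp_amplitude:
        img += spec.ramp_amplitude * np.linspace(0, 1, w)[np.newaxis, :]
    return img


def sample_soma_centers(spec: SyntheticSpec, rng: np.random.Generator):
    """Soma centers (x_px, y_px) and radii (px) in the main-channel strip.

    Somata are non-overlapping by rejection sampling; a ``touching_fraction``
    of them is placed as near-touching pairs to exercise blob splitting.
    """
    psz = spec.pixel_size_um
    h, w = spec.template_shape
    x_mid = (spec.exit_cols[0] + spec.exit_cols[1]) / 2
    half = spec.main_channel_width_um / psz / 2
    r_lo, r_hi = (r / psz for r in spec.soma_radius_um)
    x_rng = (x_mid - half + r_hi, x_mid + half - r_hi)
    y_rng = (r_hi + 2, h - r_hi - 2)
    centers, radii = [], []

    def _fits(x, y, r, gap):
        for (cx, cy), cr in zip(centers, radii):
            if (x - cx) ** 2 + (y - cy) ** 2 < (r + cr + gap) ** 2:
                return False
        return True

    n_paired = int(round(spec.touching_fraction * spec.soma_count))
    n_pairs = n_paired // 2
    placed = 0
    attempts = 0
    while placed < spec.soma_count and attempts < 20000:
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        x = rng.uniform(*x_rng)
        y = rng.uniform(*y_rng)
        if not _fits(x, y, r, gap=2.0):
            continue
        if n_pairs > 0 and placed + 2 <= spec.soma_count:
            r2 = rng.uniform(r_lo, r_hi)
            ang = rng.uniform(0, 2 * math.pi)
            sep = 0.95 * (r + r2)
            x2, y2 = x + sep * math.cos(ang), y + sep * math.sin(ang)
            if (x_rng[0] <= x2 <= x_rng[1] and y_rng[0] <= y2 <= y_rng[1]
                    and _fits(x2, y2, r2, gap=-2 * r2)):
                centers.append((x, y)); radii.append(r)
                centers.append((x2, y2)); radii.append(r2)
                placed += 2
                n_pairs -= 1
                continue
        centers.append((x, y)); radii.append(r)
        placed += 1
    return centers, radii


def _render_somata(spec: SyntheticSpec, centers, radii) -> np.ndarray:
    h, w = spec.template_shape
    img = np.zeros((h, w), dtype=float)
    for (x, y), r in zip(centers, radii):
        rr, cc = draw_disk((y, x), r, shape=(h, w))
        img[rr, cc] = 1.0
    img = ndimage.gaussian_filter(img, 1.5)
    return spec.background + spec.soma_amplitude * np.clip(img, 0, 1)


# ---------------------------------------------------------------------------
# top-level generator


def generate_chamber(spec: SyntheticSpec):
    """Render a synthetic chamber and return ``(ChamberImage, SyntheticTruth)``.

    Randomness flows from ``spec.seed`` through one seed sequence with
    independent sub-streams for axons, somata and noise, so toggling the
    noise does not change the geometry.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_axons, rng_somata, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    polylines = sample_axon_polylines(spec, rng_axons)
    centers, radii = sample_soma_centers(spec, rng_somata)

    channels = {
        "phase": _render_phase(spec),
        "axon_fluor": _render_axons(spec, polylines),
        "soma_marker": _render_somata(spec, centers, radii),
    }
    if spec.rotation_deg % 360.0 != 0.0:
        channels = {k: ndimage.rotate(v, spec.rotation_deg, reshape=True,
                                      order=1, mode="constant", cval=0.0)
                    for k, v in channels.items()}
    for k, v in channels.items():
        if spec.shot_noise:
            v = rng_noise.poisson(np.clip(v, 0, None)).astype(float)
        if spec.noise_sd > 0:
            v = v + rng_noise.normal(0.0, spec.noise_sd, size=v.shape)
        channels[k] = np.clip(v, 0, 65535).astype(np.uint16)

    image = ChamberImage(channels=channels, pixel_size_um=spec.pixel_size_um)
    truth = SyntheticTruth(
        rotation_deg=spec.rotation_deg,
        pixel_size_um=spec.pixel_size_um,
        template_shape=spec.template_shape,
        exit_cols=spec.exit_cols,
        wall_cols=spec.wall_cols,
        polylines=polylines,
        soma_centers=centers,
        soma_count=len(centers),
        spec=spec,
    )
    return image, truth
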