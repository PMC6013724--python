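"""Counting neuronal somata in the main channel for profile normalization.

The intersection profile is normalized by the number of marker-positive
neurons in the main channel. Automatic counting (smooth → Otsu threshold →
connected components → area gate → marker-controlled split of touching
blobs) is a pragmatic default; a manual count is a first-class override
because normalization correctness matters more than detection elegance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .errors import ConfigurationError, ValidationError
from .segmentation import CONNECTIVITY_8


@dataclass
class SomaCountResult:
    """Soma count plus provenance (auto detections or manual override)."""

    count: int
    method: str
    detections: list = field(default_factory=list)
    params_used: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.count < 0:
            raise ValidationError("soma count must be non-negative")
        if self.method == "auto" and self.count != len(self.detections):
            raise ValidationError("auto count must equal the number of detections")


def manual_count(n: int) -> SomaCountResult:
    """Wrap a manually determined neuron count."""
    if int(n) != n or n < 1:
        raise ValidationError(f"manual soma count must be a positive integer, got {n}")
    return SomaCountResult(count=int(n), method="manual")


def count_somata(soma_channel, smoothing_um: float = 5.0,
                 min_area_um2: float = 80.0, max_area_um2: float = 800.0,
                 pixel_size_um: float = 1.3,
                 nuclei_channel=None) -> SomaCountResult:
    """Detect and count marker-positive somata in the main-channel raster.

    Pipeline: Gaussian smoothing (``smoothing_um``) → Otsu threshold →
    connected components; blobs are split by watershed seeded at local
    maxima of the smoothed intensity, then gated to ``[min_area_um2,
    max_area_um2]``. Adding a constant offset to the raster does not change
    the result. A constant raster returns count 0 with a warning.

    When ``nuclei_channel`` is given, a detection is kept only if a nuclear
    detection (same procedure on that channel) falls inside its blob.
    """
    img = np.asarray(soma_channel, dtype=float)
    if img.ndim != 2:
        raise ConfigurationError("soma channel must be a 2-D raster")
    if not (0 < min_area_um2 < max_area_um2):
        raise ConfigurationError("area bounds must satisfy 0 < min < max")
    params = {"smoothing_um": smoothing_um, "min_area_um2": min_area_um2,
              "max_area_um2": max_area_um2, "pixel_size_um": pixel_size_um}
    if np.ptp(img) == 0:
        warnings.warn("constant soma channel: reporting count 0", stacklevel=2)
        return SomaCountResult(count=0, method="auto", detections=[], params_used=params)

    sigma_px = max(smoothing_um / pixel_size_um, 0.5)
    smooth = ndimage.gaussian_filter(img, sigma_px)
    mask = smooth > threshold_otsu(smooth)
    if not mask.any():
        warnings.warn("no foreground above the Otsu threshold", stacklevel=2)
        return SomaCountResult(count=0, method="auto", detections=[], params_used=params)

    min_px = min_area_um2 / pixel_size_um ** 2
    max_px = max_area_um2 / pixel_size_um ** 2
    # minimum seed separation: the radius of the smallest acceptable soma
    r_px = max(2, int(round(np.sqrt(min_px / np.pi))))
    dist = ndimage.distance_transform_edt(mask)
    seeds = peak_local_max(dist, min_distance=r_px, labels=mask,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=int)
    for i, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(mask, structure=CONNECTIVITY_8)
    else:
        labels = watershed(-dist, markers=markers, mask=mask)

    detections = []
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(areas >= min_px) & (areas <= max_px)]
    if keep.size:
        centroids = ndimage.center_of_mass(mask, labels, keep)
        detections = [(float(c), float(r)) for r, c in centroids]

    if nuclei_channel is not None and detections:
        nuc = count_somata(np.asarray(nuclei_channel, dtype=float),
                           smoothing_um=smoothing_um / 2,
                           min_area_um2=min_area_um2 / 4,
                           max_area_um2=max_area_um2,
                           pixel_size_um=pixel_size_um)
        kept = []
        for soma_id, (x, y) in zip(keep, detections):
            gated = any(labels[int(round(ny)), int(round(nx))] == soma_id
                        for nx, ny in nuc.detections)
            if gated:
                kept.append((x, y))
        detections = kept

    return SomaCountResult(count=len(detections), method="auto",
                           detections=detections, params_used=params)
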