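"""Reading chamber images and writing/reading Sholl profiles.

Images are plain single- or multi-plane TIFF files; profiles are CSV with a
fixed header whose column order is part of the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .sholl import ShollProfile

CHANNEL_ROLES = ("phase", "axon_fluor", "soma_marker", "nuclei")

PROFILE_COLUMNS = ["chamber_id", "side", "distance_um", "intersections",
                   "normalized", "soma_count", "intersection_mode"]


@dataclass
class ChamberImage:
    """Multi-channel chamber raster with its physical pixel size.

    ``channels`` maps role labels (phase, axon_fluor, soma_marker, nuclei)
    to 2-D intensity arrays; all channels share one shape. Intensities are
    kept exactly as stored — no rescaling, no dtype conversion.
    """

    channels: dict
    pixel_size_um: float

    def __post_init__(self):
        if not self.channels:
            raise ConfigurationError("ChamberImage needs at least one channel")
        shapes = set()
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ConfigurationError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}")
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ConfigurationError(f"channel {role!r} is not a 2-D raster")
            self.channels[role] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ConfigurationError(f"channels differ in shape: {sorted(shapes)}")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ConfigurationError("pixel_size_um must be finite and > 0")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


def read_chamber_image(path, channel_map: dict, pixel_size_um: float) -> ChamberImage:
    """Read a single- or multi-plane TIFF into a :class:`ChamberImage`.

    ``channel_map`` maps role labels to plane indices of the stored stack.
    Planes are returned bit-identical to what is on disk; the pixel size must
    come from the caller's configuration (TIFF resolution tags are only used
    to warn on gross mismatch, never to override).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if not (np.isfinite(pixel_size_um) and pixel_size_um > 0):
        raise ConfigurationError("pixel_size_um must be finite and > 0")
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        tag_size = _pixel_size_from_tags(tif)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ConfigurationError(
            f"{path}: expected a 2-D image or a stack of planes, got shape {data.shape}")
    n_planes = data.shape[0]
    channels = {}
    for role, idx in channel_map.items():
        if not (0 <= int(idx) < n_planes):
            raise ConfigurationError(
                f"channel {role!r} maps to plane {idx}, but {path} has {n_planes} plane(s)")
        channels[role] = data[int(idx)]
    if tag_size is not None and abs(tag_size - pixel_size_um) / pixel_size_um > 0.05:
        warnings.warn(
            f"{path}: TIFF resolution tag implies {tag_size:.4g} um/px but config says "
            f"{pixel_size_um:.4g} um/px; the config value is used", stacklevel=2)
    return ChamberImage(channels=channels, pixel_size_um=float(pixel_size_um))


def _pixel_size_from_tags(tif) -> float | None:
    """Best-effort pixel size (μm/px) from TIFF resolution tags, else None."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None or unit is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        px_per_unit = num / den
        unit = getattr(unit.value, "value", unit.value)
        if unit == 3:       # centimetre
            return 1e4 / px_per_unit
        if unit == 2:       # inch
            return 25400.0 / px_per_unit
        return None
    except Exception:
        return None


def write_chamber_image(path, image: ChamberImage, order=None) -> list:
    """Write channels as a multi-plane TIFF; returns the plane order used."""
    order = list(order) if order is not None else list(image.channels)
    stack = np.stack([image.channels[r] for r in order])
    tifffile.imwrite(str(path), stack, photometric="minisblack")
    return order


def write_profile(profile: ShollProfile, path) -> None:
    """Append-free write of one profile as CSV (one row per grid line)."""
    write_profiles([profile], path)


def write_profiles(profiles, path) -> None:
    """Write one or more profiles into a single CSV with the fixed header.

    Floats are written with ``repr`` precision so a read→write→read cycle is
    lossless.
    """
    rows = []
    for p in profiles:
        for d, k, v in zip(p.distances_um, p.intersections, p.normalized):
            rows.append({
                "chamber_id": p.chamber_id,
                "side": p.side,
                "distance_um": float(d),
                "intersections": int(k),
                "normalized": float(v),
                "soma_count": int(p.soma_count),
                "intersection_mode": p.intersection_mode,
            })
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(",".join(PROFILE_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(",".join(_fmt(x) for x in row) + "\n")


def _fmt(x) -> str:
    if isinstance(x, float):
        return repr(x)
    return str(x)


def read_profiles(path) -> list:
    """Read a profile CSV back into a list of :class:`ShollProfile`."""
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"profile file {path} lacks columns {missing}")
    profiles = []
    for (cid, side), grp in df.groupby(["chamber_id", "side"], sort=False):
        grp = grp.sort_values("distance_um")
        soma = int(grp["soma_count"].iloc[0])
        mode = str(grp["intersection_mode"].iloc[0])
        profiles.append(ShollProfile(
            distances_um=grp["distance_um"].to_numpy(dtype=float),
            intersections=grp["intersections"].to_numpy(dtype=int),
            soma_count=soma,
            side=str(side),
            intersection_mode=mode,
            chamber_id=str(cid),
        ))
    return profiles
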