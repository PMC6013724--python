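"""End-to-end chamber analysis: align → segment → skeletonize → count.

One call takes a multi-channel chamber image to a pair of Sholl profiles
(left and right compartment), normalized by the soma count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import alignment as al
from . import segmentation as seg
from . import sholl
from . import soma as soma_mod
from .config import PipelineConfig, um_to_px
from .errors import ConfigurationError
from .image_io import ChamberImage


@dataclass
class ChamberAnalysis:
    """Everything one chamber run produced."""

    chamber_id: str
    alignment: al.AlignmentResult
    soma: soma_mod.SomaCountResult
    profiles: list
    skeletons: dict = None


def analyze_chamber(image: ChamberImage, config: PipelineConfig,
                    chamber_id: str = "chamber", manual_soma: int = None,
                    keep_intermediates: bool = False) -> ChamberAnalysis:
    """Run the full pipeline on one chamber image.

    The soma count comes from ``manual_soma`` when given, otherwise from
    automatic detection on the ``soma_marker`` channel.
    """
    if "phase" not in image.channels or "axon_fluor" not in image.channels:
        raise ConfigurationError(
            "a full pipeline run needs 'phase' and 'axon_fluor' channels")
    angle = al.estimate_rotation(
        image.channels["phase"],
        search_half_range_deg=config.rotation_half_range_deg,
        resolution_deg=config.rotation_resolution_deg,
        edge_quantile=config.edge_quantile)
    aligned = al.rotate_channels(image, angle, order=1)
    result = al.locate_zones(aligned.channels["phase"], config, angle_deg=angle)

    if manual_soma is not None:
        soma_res = soma_mod.manual_count(manual_soma)
    elif "soma_marker" in aligned.channels:
        soma_res = soma_mod.count_somata(
            aligned.channels["soma_marker"],
            smoothing_um=config.soma_smoothing_um,
            min_area_um2=config.soma_min_area_um2,
            max_area_um2=config.soma_max_area_um2,
            pixel_size_um=config.pixel_size_um)
        if soma_res.count < 1:
            raise ConfigurationError(
                "automatic soma detection found no neuron; supply a manual count")
    else:
        raise ConfigurationError(
            "no soma_marker channel and no manual soma count given")

    h = aligned.shape[0]
    margin_px = int(round(um_to_px(config.vertical_margin_um, config.pixel_size_um)))
    rows = slice(margin_px, h - margin_px if margin_px else h)

    profiles, skeletons = [], {}
    axon = aligned.channels["axon_fluor"]
    for side in ("left", "right"):
        x0, x1 = result.left_zone if side == "left" else result.right_zone
        zone = np.asarray(axon[rows, x0:x1], dtype=float)
        mask = seg.segment_axons(
            zone, block_size_um=config.seg_block_size_um,
            offset_frac=config.seg_offset_frac,
            min_area_um2=config.seg_min_area_um2,
            pixel_size_um=config.pixel_size_um,
            presmooth_um=config.seg_presmooth_um,
            side=side, chamber_id=chamber_id)
        skel = seg.skeletonize_mask(mask)
        columns, dists = sholl.grid_columns(result, side, config)
        counts = sholl.count_intersections(skel.pixels, columns - x0,
                                           mode=config.intersection_mode)
        profiles.append(sholl.normalize_profile(
            dists, counts, soma_res.count, side,
            intersection_mode=config.intersection_mode, chamber_id=chamber_id))
        if keep_intermediates:
            skeletons[side] = skel
    return ChamberAnalysis(chamber_id=chamber_id, alignment=result,
                           soma=soma_res, profiles=profiles,
                           skeletons=skeletons if keep_intermediates else None)
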