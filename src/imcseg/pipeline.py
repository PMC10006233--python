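"""End-to-end single-ROI pipeline: preprocess → segment → type → quantify.

Stage order follows the acquisition-analysis procedure: hot pixels are
removed from every channel; each segmentation channel (Vimentin, CD31, CD68)
is background-subtracted, weight-transformed and density-clustered, and
clusters are split at the local maxima of the background-corrected channel;
CD31/Vimentin regions are typed with the overlap-discard rule; typed cells
are eroded, area-filtered, and quantified (raw means of LYN/THBS1 on the
cleaned channels, arcsinh with cofactor 5). Per-stage region counts are
logged so cell attrition is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .celltyping import assign_cell_types, erode_region, filter_by_area, TypedRegion
from .core import ChannelImage, LabelMap, PipelineConfig, Region, RoiImage, TypedCell
from .preprocess import compute_weights, remove_hot_pixels, subtract_background
from .quantify import build_cell_table, quantify_cells
from .segmentation import (
    detect_local_maxima,
    regions_from_labels,
    segment_weight_map,
    split_clusters,
)

logger = logging.getLogger("imcseg")

__all__ = ["PipelineResult", "run_pipeline", "run_cohort"]


@dataclass(frozen=True)
class PipelineResult:
    """Output of one ROI run: cells, the per-ROI table, label maps, counters."""

    roi_id: str
    cells: tuple[TypedCell, ...]
    table: pd.DataFrame
    label_maps: Mapping[str, LabelMap]
    untyped_regions: tuple[Region, ...]
    stage_counts: Mapping[str, int]


def _segment_channel(
    cleaned: ChannelImage, config: PipelineConfig
) -> tuple[list[Region], LabelMap]:
    bc = subtract_background(cleaned, config.blur_sigma)
    weights = compute_weights(
        bc,
        config.low_percentile,
        config.high_percentile,
        population=config.percentile_population,
    )
    labels = segment_weight_map(weights, config.dbscan_eps, config.dbscan_min_weight)
    maxima = detect_local_maxima(bc, config.maxima_footprint_radius)
    split = split_clusters(labels, maxima)
    return regions_from_labels(split, cleaned.name), split


def run_pipeline(roi: RoiImage, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full segmentation/typing/quantification procedure on one ROI.

    Deterministic: identical input and config always give identical output.
    Raises ``KeyError`` naming any required channel missing from the ROI.
    """
    config = config if config is not None else PipelineConfig()
    required = set(config.segmentation_channels) | set(config.quantification_channels)
    missing = sorted(required - set(roi.channel_names))
    if missing:
        raise KeyError(f"ROI {roi.roi_id!r} is missing required channels: {missing}")

    cleaned = {
        ch.name: remove_hot_pixels(ch, config.hot_pixel_threshold)
        for ch in roi.channels
    }

    counts: dict[str, int] = {}
    regions_by_marker: dict[str, list[Region]] = {}
    label_maps: dict[str, LabelMap] = {}
    for name in config.segmentation_channels:
        regions, labels = _segment_channel(cleaned[name], config)
        regions_by_marker[name] = regions
        label_maps[name] = labels
        counts[f"regions_{name}"] = len(regions)
        logger.info("ROI %s: %d %s regions after splitting", roi.roi_id, len(regions), name)

    typed = assign_cell_types(
        regions_by_marker.get(config.fibroblast_marker, []),
        regions_by_marker.get(config.endothelial_marker, []),
        roi.shape,
        config.overlap_discard_fraction,
    )
    counts["endothelial_typed"] = len(typed["endothelial"])
    counts["fibroblast_typed"] = len(typed["fibroblast"])
    counts["vimentin_discarded"] = len(typed["discarded"])
    logger.info(
        "ROI %s: %d endothelial, %d fibroblast, %d Vimentin regions discarded",
        roi.roi_id,
        counts["endothelial_typed"],
        counts["fibroblast_typed"],
        counts["vimentin_discarded"],
    )

    # CD31-derived cells first, then Vimentin-derived, each in region-id order
    ordered = list(typed["endothelial"]) + list(typed["fibroblast"])
    eroded = [
        TypedRegion(
            erode_region(
                tr.region, config.erosion_iterations, roi.shape, config.erosion_structure
            ),
            tr.cell_type,
        )
        for tr in ordered
    ]
    counts["nonempty_after_erosion"] = sum(1 for tr in eroded if tr.region.area > 0)
    kept = filter_by_area(eroded, config.min_area, config.max_area)
    counts["cells_after_area_filter"] = len(kept)
    logger.info(
        "ROI %s: %d cells survive erosion + [%d, %d] px^2 area filter",
        roi.roi_id,
        len(kept),
        config.min_area,
        config.max_area,
    )

    cells = quantify_cells(kept, roi, config, cleaned_channels=cleaned)
    table = build_cell_table([(roi, cells)], config)

    untyped = tuple(
        reg
        for name, regs in regions_by_marker.items()
        if name not in (config.fibroblast_marker, config.endothelial_marker)
        for reg in regs
    )

    return PipelineResult(
        roi_id=roi.roi_id,
        cells=tuple(cells),
        table=table,
        label_maps=label_maps,
        untyped_regions=untyped,
        stage_counts=counts,
    )


def run_cohort(
    rois: Sequence[RoiImage], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, list[PipelineResult]]:
    """Run the pipeline on every ROI and pool the cell tables."""
    config = config if config is not None else PipelineConfig()
    results = [run_pipeline(roi, config) for roi in rois]
    tables = [res.table for res in results if len(res.table)]
    if tables:
        pooled = pd.concat(tables, ignore_index=True)
        pooled = pooled.sort_values(["roi_id", "cell_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        pooled = build_cell_table([], config)
    return pooled, results
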