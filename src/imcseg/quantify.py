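"""Per-cell marker quantification: raw mean intensities and arcsinh transform.

Marker intensities are measured on the hot-pixel-cleaned *raw* channels (the
Gaussian-blur subtraction and weight transform are segmentation aids only)
and variance-stabilised with asinh(x / cofactor), the standard mass-cytometry
transform, using a cofactor of 5 counts by default.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ChannelImage, PipelineConfig, RoiImage, TypedCell

__all__ = ["mean_intensity", "arcsinh_transform", "quantify_cells", "build_cell_table"]

CELL_TABLE_META_COLUMNS = ["roi_id", "sample_id", "group", "cell_id", "cell_type", "area"]


def mean_intensity(pixels: Iterable[tuple[int, int]], channel: ChannelImage) -> float:
    """Arithmetic mean of the channel over the cell's (eroded) pixels."""
    pix = list(pixels)
    if not pix:
        raise ValueError("cannot quantify an empty pixel set")
    H, W = channel.shape
    total = 0.0
    for r, c in pix:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"pixel ({r}, {c}) outside channel of shape {channel.shape}")
        total += channel.data[r, c]
    return total / len(pix)


def arcsinh_transform(x: float, cofactor: float) -> float:
    """asinh(x / cofactor) = ln(x/c + sqrt((x/c)² + 1))."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return math.asinh(x / cofactor)


def quantify_cells(
    typed_regions: Sequence,
    roi: RoiImage,
    config: PipelineConfig,
    cleaned_channels: dict[str, ChannelImage] | None = None,
) -> list[TypedCell]:
    """Build :class:`TypedCell` records from typed, eroded, area-filtered regions.

    ``cleaned_channels`` maps channel name to the hot-pixel-cleaned raw
    channel to quantify on; when omitted the ROI's channels are used as-is.
    Cells are numbered 1..N in the order given.
    """
    cells: list[TypedCell] = []
    for cell_id, tr in enumerate(typed_regions, start=1):
        means: dict[str, float] = {}
        arcs: dict[str, float] = {}
        for name in config.quantification_channels:
            ch = cleaned_channels[name] if cleaned_channels else roi.channel(name)
            means[name] = mean_intensity(tr.region.pixels, ch)
            arcs[name] = arcsinh_transform(means[name], config.arcsinh_cofactor)
        cells.append(
            TypedCell(
                cell_id=cell_id,
                cell_type=tr.cell_type,
                pixels=tr.region.pixels,
                mean_intensity=means,
                arcsinh_intensity=arcs,
            )
        )
    return cells


def build_cell_table(
    rois: Iterable[tuple[RoiImage, Sequence[TypedCell]]],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Assemble the flat per-cell table across ROIs.

    One row per cell with ROI metadata, cell type, eroded area, and raw plus
    arcsinh mean intensities for every quantification channel
    (columns ``{channel}_mean`` / ``{channel}_arcsinh``). Rows are ordered by
    ``(roi_id, cell_id)`` and that pair must be unique.
    """
    rows = []
    for roi, cells in rois:
        for cell in cells:
            row = {
                "roi_id": roi.roi_id,
                "sample_id": roi.sample_id,
                "group": roi.group,
                "cell_id": cell.cell_id,
                "cell_type": cell.cell_type,
                "area": cell.area,
            }
            for name in config.quantification_channels:
                row[f"{name}_mean"] = cell.mean_intensity[name]
                row[f"{name}_arcsinh"] = cell.arcsinh_intensity[name]
            rows.append(row)

    columns = list(CELL_TABLE_META_COLUMNS)
    for name in config.quantification_channels:
        columns += [f"{name}_mean", f"{name}_arcsinh"]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        if table.duplicated(subset=["roi_id", "cell_id"]).any():
            raise ValueError("duplicate (roi_id, cell_id) in cell table")
        table = table.sort_values(["roi_id", "cell_id"], kind="mergesort").reset_index(
            drop=True
        )
    return table
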