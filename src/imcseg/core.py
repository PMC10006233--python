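"""Shared domain types and configuration for the IMC segmentation pipeline.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` tuples;
* areas are pixel counts (px²);
* 1 px corresponds to 1 µm unless :attr:`RoiImage.pixel_size_um` says otherwise;
* intensity values are raw detector counts (unitless, nonnegative).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ChannelImage",
    "RoiImage",
    "WeightMap",
    "LabelMap",
    "Region",
    "TypedCell",
    "PipelineConfig",
    "GroupSummary",
    "GroupComparison",
]


def _as_float_2d(data, what: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{what} must have at least one row and column")
    return arr


@dataclass(frozen=True)
class ChannelImage:
    """A single marker channel: H×W nonnegative intensities in detector counts."""

    name: str
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_2d(self.data, f"channel {self.name!r}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"channel {self.name!r} contains non-finite values")
        if arr.min() < 0:
            raise ValueError(f"channel {self.name!r} contains negative values")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiImage:
    """One laser-ablated region of interest: a stack of same-shaped channels.

    The default pixel size of 1 µm/px matches Hyperion ROIs of
    750 µm × 750 µm acquired as 750×750 px images.
    """

    roi_id: str
    sample_id: str
    group: str
    channels: tuple[ChannelImage, ...]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        if not channels:
            raise ValueError("RoiImage needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shape = channels[0].shape
        for ch in channels:
            if ch.shape != shape:
                raise ValueError(
                    f"channel {ch.name!r} shape {ch.shape} != {shape}"
                )
        names = [ch.name for ch in channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names in ROI {self.roi_id!r}")
        object.__setattr__(self, "channels", channels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels)

    def channel(self, name: str) -> ChannelImage:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"ROI {self.roi_id!r} has no channel {name!r}")

    def with_channels(self, channels: Iterable[ChannelImage]) -> "RoiImage":
        return dataclasses.replace(self, channels=tuple(channels))


@dataclass(frozen=True)
class WeightMap:
    """Per-pixel DBSCAN weights in [0, 1]; max is exactly 1 unless all-zero."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_2d(self.data, "weight map")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        mx = arr.max()
        if mx != 0.0 and mx != 1.0:
            raise ValueError("a non-empty weight map must have maximum exactly 1")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class LabelMap:
    """Integer region map: 0 = background/noise, region ids are contiguous 1..K."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("labels must be >= 0")
        ids = np.unique(arr)
        ids = ids[ids > 0]
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("region ids must form a contiguous range 1..K")
        object.__setattr__(self, "data", arr)

    @property
    def n_regions(self) -> int:
        return int(self.data.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Region:
    """A marker-positive pixel region produced by segmentation.

    Erosion may empty a region, so ``area == 0`` is permitted; empty regions
    are discarded later by the area filter.
    """

    region_id: int
    marker: str
    pixels: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.region_id < 1:
            raise ValueError("region_id must be >= 1")
        object.__setattr__(self, "pixels", frozenset(self.pixels))

    @property
    def area(self) -> int:
        return len(self.pixels)

    def centroid(self) -> tuple[float, float]:
        if not self.pixels:
            raise ValueError("empty region has no centroid")
        rows, cols = zip(*self.pixels)
        return float(np.mean(rows)), float(np.mean(cols))


@dataclass(frozen=True)
class TypedCell:
    """A typed, eroded, area-filtered cell with per-channel mean intensities."""

    cell_id: int
    cell_type: str
    pixels: frozenset[tuple[int, int]]
    mean_intensity: Mapping[str, float]
    arcsinh_intensity: Mapping[str, float]

    @property
    def area(self) -> int:
        return len(self.pixels)

    def centroid(self) -> tuple[float, float]:
        rows, cols = zip(*self.pixels)
        return float(np.mean(rows)), float(np.mean(cols))


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric constant of the segmentation/quantification procedure.

    Parameters
    ----------
    hot_pixel_threshold
        Counts by which a pixel must exceed its 8-neighbour maximum to be
        replaced by that maximum (default 50).
    blur_sigma
        Sigma (px) of the Gaussian blur subtracted to remove uneven
        background (default 40).
    low_percentile, high_percentile
        Pixels below the low percentile of the background-corrected channel
        are zeroed; values are clipped at the high percentile before
        normalising the maximum weight to 1 (defaults 30 and 99.5).
    dbscan_eps, dbscan_min_weight, dbscan_metric, dbscan_leaf_size
        Density clustering parameters: eps in px under the Manhattan metric,
        core condition = neighbourhood weight sum >= min_weight (defaults
        2 and 4). ``leaf_size`` is a tree-search performance parameter of the
        original implementation with no effect on clustering output; it is
        kept for configuration fidelity only.
    maxima_footprint_radius
        Chebyshev radius of the local-maximum neighbourhood used for cluster
        splitting (default 4, i.e. 9×9). Splitting should only separate
        intensity peaks that could be distinct cells, so the footprint is
        set to roughly the cell-blob scale; on count data a 3×3 footprint
        (radius 1) detects a maximum at nearly every counting-noise spike
        and shatters the clusters.
    erosion_iterations, erosion_structure
        Binary erosion passes applied to each typed cell (default 3) and the
        structuring element ("cross" = 4-connected, or "square").
    min_area, max_area
        Inclusive post-erosion area bounds in px² (defaults 10 and 800).
    overlap_discard_fraction
        A Vimentin region overlapping CD31-positive pixels by strictly more
        than this fraction of its own area is discarded (default 0.30).
    arcsinh_cofactor
        Divisor c of the variance-stabilising asinh(x / c) (default 5).
    percentile_population
        Whether weight-transform percentiles are computed over "all" pixels
        (default) or "nonzero" pixels only.
    """

    hot_pixel_threshold: float = 50.0
    blur_sigma: float = 40.0
    low_percentile: float = 30.0
    high_percentile: float = 99.5
    dbscan_eps: float = 2.0
    dbscan_min_weight: float = 4.0
    dbscan_metric: str = "manhattan"
    dbscan_leaf_size: int = 3
    maxima_footprint_radius: int = 4
    erosion_iterations: int = 3
    erosion_structure: str = "cross"
    min_area: int = 10
    max_area: int = 800
    overlap_discard_fraction: float = 0.30
    arcsinh_cofactor: float = 5.0
    segmentation_channels: tuple[str, ...] = ("Vimentin", "CD31", "CD68")
    quantification_channels: tuple[str, ...] = ("LYN", "THBS1")
    fibroblast_marker: str = "Vimentin"
    endothelial_marker: str = "CD31"
    percentile_population: str = "all"

    def __post_init__(self) -> None:
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValueError("need 0 <= low_percentile < high_percentile <= 100")
        if self.min_area > self.max_area:
            raise ValueError("min_area must be <= max_area")
        for name in ("hot_pixel_threshold", "arcsinh_cofactor"):
            if getattr(self, name) <= 0 and name == "arcsinh_cofactor":
                raise ValueError("arcsinh_cofactor must be positive")
        if self.blur_sigma <= 0 or self.dbscan_eps <= 0 or self.dbscan_min_weight <= 0:
            raise ValueError("blur_sigma, dbscan_eps, dbscan_min_weight must be positive")
        if self.hot_pixel_threshold < 0:
            raise ValueError("hot_pixel_threshold must be >= 0")
        if self.erosion_iterations < 0:
            raise ValueError("erosion_iterations must be >= 0")
        if self.dbscan_metric != "manhattan":
            raise ValueError("only the manhattan metric is supported")
        if self.erosion_structure not in ("cross", "square"):
            raise ValueError("erosion_structure must be 'cross' or 'square'")
        if self.percentile_population not in ("all", "nonzero"):
            raise ValueError("percentile_population must be 'all' or 'nonzero'")
        object.__setattr__(self, "segmentation_channels", tuple(self.segmentation_channels))
        object.__setattr__(
            self, "quantification_channels", tuple(self.quantification_channels)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation_channels"] = list(self.segmentation_channels)
        d["quantification_channels"] = list(self.quantification_channels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class GroupSummary:
    """Tukey box-plot summary of one group's per-cell arcsinh intensities."""

    group: str
    n: int
    median: float
    q1: float
    q3: float
    adjacent_low: float
    adjacent_high: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-group per-cell comparison of one marker within one cell type.

    ``t_statistic`` is signed as group_a minus group_b, where ``group_a`` and
    ``group_b`` follow the order given to :func:`imcseg.stats.compare_groups`
    (lexicographic by default).
    """

    channel: str
    cell_type: str
    group_a: GroupSummary
    group_b: GroupSummary
    t_statistic: float
    degrees_of_freedom: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        for g in (self.group_a, self.group_b):
            if not (g.adjacent_low <= g.q1 <= g.median <= g.q3 <= g.adjacent_high):
                raise ValueError(f"inconsistent summary statistics for group {g.group!r}")

    def to_row(self) -> dict:
        row = {"channel": self.channel, "cell_type": self.cell_type}
        for tag, g in (("a", self.group_a), ("b", self.group_b)):
            row[f"group_{tag}"] = g.group
            row[f"n_{tag}"] = g.n
            row[f"median_{tag}"] = g.median
            row[f"q1_{tag}"] = g.q1
            row[f"q3_{tag}"] = g.q3
            row[f"adjacent_low_{tag}"] = g.adjacent_low
            row[f"adjacent_high_{tag}"] = g.adjacent_high
        row["t_statistic"] = self.t_statistic
        row["degrees_of_freedom"] = self.degrees_of_freedom
        row["p_value"] = self.p_value
        return row
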