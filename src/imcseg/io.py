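"""File formats: multi-page TIFF + channel manifest, CSV tables, run manifests.

A ROI is stored as a multi-page TIFF (one page per channel) with a sidecar
channel manifest, a small CSV with rows ``page_index,channel_name`` plus
optional metadata rows ``roi_id,<value>`` / ``sample_id,<value>`` /
``group,<value>`` / ``pixel_size_um,<value>``. The manifest keeps the TIFF
dialect minimal and bit-exact; OME-TIFF parsing is a possible extension
point, not implemented here.
"""

from __future__ import annotations

import csv
import importlib.metadata
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ChannelImage, GroupComparison, LabelMap, PipelineConfig, RoiImage
from .simulate import SimulationConfig, SyntheticGroundTruth

__all__ = [
    "read_roi_tiff",
    "write_roi_tiff",
    "read_label_mask",
    "write_label_mask",
    "write_outputs",
    "read_cell_table",
    "read_fold_change_table",
    "load_pipeline_config",
    "save_pipeline_config",
    "load_simulation_config",
    "save_simulation_config",
    "write_truth",
]

_META_KEYS = ("roi_id", "sample_id", "group", "pixel_size_um")


def _package_version() -> str:
    try:
        return importlib.metadata.version("imcseg")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_roi_tiff(roi: RoiImage, image_path, manifest_path) -> None:
    """Write a ROI as a float32 multi-page TIFF plus its channel manifest."""
    stack = np.stack([ch.data.astype(np.float32) for ch in roi.channels])
    # minisblack keeps 3/4-channel stacks as pages rather than RGB samples
    tifffile.imwrite(str(image_path), stack, photometric="minisblack")
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh)
        for i, ch in enumerate(roi.channels):
            w.writerow([i, ch.name])
        w.writerow(["roi_id", roi.roi_id])
        w.writerow(["sample_id", roi.sample_id])
        w.writerow(["group", roi.group])
        w.writerow(["pixel_size_um", roi.pixel_size_um])


def read_roi_tiff(image_path, manifest_path) -> RoiImage:
    """Read a multi-page TIFF and its channel manifest into a :class:`RoiImage`.

    Integer and floating-point pixel types are both accepted and converted to
    real counts. Errors if the page count disagrees with the manifest or a
    channel name repeats.
    """
    pages = tifffile.imread(str(image_path))
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2-D pages, got shape {pages.shape}")

    channel_rows: list[tuple[int, str]] = []
    meta: dict[str, str] = {}
    with open(manifest_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            key = row[0].strip()
            if key in _META_KEYS:
                meta[key] = row[1].strip() if len(row) > 1 else ""
                continue
            try:
                idx = int(key)
            except ValueError as err:
                raise ValueError(f"unrecognised manifest row: {row}") from err
            if len(row) < 2 or not row[1].strip():
                raise ValueError(f"manifest page {idx} has no channel name")
            channel_rows.append((idx, row[1].strip()))

    if len(channel_rows) != pages.shape[0]:
        raise ValueError(
            f"manifest lists {len(channel_rows)} channels but TIFF has "
            f"{pages.shape[0]} pages"
        )
    names = [name for _, name in channel_rows]
    if len(set(names)) != len(names):
        raise ValueError("duplicate channel names in manifest")
    indices = [i for i, _ in channel_rows]
    if sorted(indices) != list(range(pages.shape[0])):
        raise ValueError("manifest page indices must cover 0..n_pages-1")

    channels = tuple(
        ChannelImage(name, np.asarray(pages[idx], dtype=float))
        for idx, name in channel_rows
    )
    return RoiImage(
        roi_id=meta.get("roi_id", Path(str(image_path)).stem),
        sample_id=meta.get("sample_id", ""),
        group=meta.get("group", ""),
        channels=channels,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )


def write_label_mask(labels: LabelMap, path, allow_32bit: bool = False) -> None:
    """Write a label map as an integer TIFF (region id as pixel value).

    Uses 16-bit pixels; more than 65535 regions overflows that range and is
    an error unless ``allow_32bit`` enables the documented 32-bit fallback.
    """
    mx = labels.n_regions
    if mx > np.iinfo(np.uint16).max:
        if not allow_32bit:
            raise ValueError(
                f"{mx} regions overflow a 16-bit mask; pass allow_32bit=True"
            )
        tifffile.imwrite(str(path), labels.data.astype(np.uint32))
    else:
        tifffile.imwrite(str(path), labels.data.astype(np.uint16))


def read_label_mask(path) -> LabelMap:
    return LabelMap(np.asarray(tifffile.imread(str(path)), dtype=np.int64))


def write_outputs(
    table: pd.DataFrame,
    comparisons: Sequence[GroupComparison],
    label_maps: Mapping[tuple[str, str], LabelMap],
    out_dir,
    config: PipelineConfig,
    allow_32bit: bool = False,
) -> dict[str, Path]:
    """Write cells.csv, comparisons.csv, per-ROI/per-marker masks and a manifest.

    ``label_maps`` is keyed by ``(roi_id, marker)``. The run manifest is a
    YAML file capturing the full pipeline configuration and the package
    version, re-loadable into an identical :class:`PipelineConfig`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cells_path = out / "cells.csv"
    table.to_csv(cells_path, index=False)
    paths["cells"] = cells_path

    comp_path = out / "comparisons.csv"
    pd.DataFrame([c.to_row() for c in comparisons]).to_csv(comp_path, index=False)
    paths["comparisons"] = comp_path

    for (roi_id, marker), labels in label_maps.items():
        mask_path = out / f"{roi_id}__{marker}_mask.tif"
        write_label_mask(labels, mask_path, allow_32bit=allow_32bit)
        paths[f"mask:{roi_id}:{marker}"] = mask_path

    manifest_path = out / "run_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(
            {
                "package": "imcseg",
                "version": _package_version(),
                "pipeline_config": config.to_dict(),
            },
            fh,
            sort_keys=True,
        )
    paths["manifest"] = manifest_path
    return paths


def read_cell_table(path) -> pd.DataFrame:
    """Read a cells.csv written by :func:`write_outputs` (lossless round trip)."""
    return pd.read_csv(path, dtype={"roi_id": str, "sample_id": str, "group": str})


def read_fold_change_table(path) -> pd.Series:
    """Read a two-column (id, log2fc) CSV into a Series keyed by identifier."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("fold-change table needs two columns: id, log2fc")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))


def save_pipeline_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def save_simulation_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def write_truth(truth: SyntheticGroundTruth, out_dir) -> dict[str, Path]:
    """Write simulated ground truth: cells CSV plus per-marker label masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cells_path = out / f"{truth.roi_id}__truth_cells.csv"
    truth.cells.to_csv(cells_path, index=False)
    paths["cells"] = cells_path
    for marker, mask in truth.label_masks.items():
        p = out / f"{truth.roi_id}__truth_{marker}_mask.tif"
        write_label_mask(mask, p)
        paths[f"mask:{marker}"] = p
    return paths
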