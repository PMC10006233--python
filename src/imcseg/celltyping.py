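"""Lineage assignment, overlap-based discarding, erosion, and area filtering.

CD31-positive regions are endothelial cells. Vimentin-positive regions that
overlap the union of CD31-positive pixels by strictly more than 30% of their
own area are discarded (Vimentin⁺CD31⁺ vessels); the remainder are
fibroblasts. Typed regions are then shrunk by binary erosion to avoid signal
contamination from neighbouring cells, and implausibly small or large areas
are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import Region

__all__ = ["TypedRegion", "assign_cell_types", "erode_region", "filter_by_area"]

ENDOTHELIAL = "endothelial"
FIBROBLAST = "fibroblast"

_STRUCTURES = {
    "cross": ndimage.generate_binary_structure(2, 1),
    "square": np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class TypedRegion:
    region: Region
    cell_type: str


def assign_cell_types(
    vimentin_regions: Sequence[Region],
    cd31_regions: Sequence[Region],
    shape: tuple[int, int],
    overlap_discard_fraction: float = 0.30,
) -> dict[str, list]:
    """Type regions as endothelial/fibroblast and discard overlapping vessels.

    Every CD31 region becomes an endothelial cell. Each Vimentin region whose
    overlap with the union of all CD31-positive pixels exceeds
    ``overlap_discard_fraction`` of its own area (strictly) is discarded; the
    rest become fibroblasts.

    Returns a dict with keys ``"endothelial"``, ``"fibroblast"`` (lists of
    :class:`TypedRegion`) and ``"discarded"`` (list of :class:`Region`).
    """
    if not (0 <= overlap_discard_fraction <= 1):
        raise ValueError("overlap_discard_fraction must lie in [0, 1]")
    H, W = shape
    cd31_union = np.zeros((H, W), dtype=bool)
    for reg in cd31_regions:
        for r, c in reg.pixels:
            if not (0 <= r < H and 0 <= c < W):
                raise ValueError(
                    f"CD31 region {reg.region_id} pixel ({r}, {c}) outside shape {shape}"
                )
            cd31_union[r, c] = True

    out: dict[str, list] = {
        ENDOTHELIAL: [TypedRegion(reg, ENDOTHELIAL) for reg in cd31_regions],
        FIBROBLAST: [],
        "discarded": [],
    }
    for reg in vimentin_regions:
        if reg.area == 0:
            continue
        overlap = 0
        for r, c in reg.pixels:
            if not (0 <= r < H and 0 <= c < W):
                raise ValueError(
                    f"Vimentin region {reg.region_id} pixel ({r}, {c}) outside shape {shape}"
                )
            if cd31_union[r, c]:
                overlap += 1
        if overlap / reg.area > overlap_discard_fraction:
            out["discarded"].append(reg)
        else:
            out[FIBROBLAST].append(TypedRegion(reg, FIBROBLAST))
    return out


def erode_region(
    region: Region,
    iterations: int,
    shape: tuple[int, int],
    structure: str = "cross",
) -> Region:
    """Binary-erode a region's pixel mask; may return an empty region.

    Each pass uses the chosen 3×3 structuring element (``"cross"`` =
    4-connected, the default; or ``"square"``). Pixels outside the image
    border count as background, so regions touching the border erode inwards
    from the border too.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or region.area == 0:
        return region
    mask = np.zeros(shape, dtype=bool)
    rows, cols = zip(*region.pixels)
    mask[list(rows), list(cols)] = True
    eroded = ndimage.binary_erosion(
        mask, structure=_STRUCTURES[structure], iterations=iterations, border_value=0
    )
    pix = frozenset((int(r), int(c)) for r, c in np.argwhere(eroded))
    return Region(region.region_id, region.marker, pix)


def filter_by_area(
    cells: Sequence[TypedRegion], min_area: int, max_area: int
) -> list[TypedRegion]:
    """Keep cells with ``min_area <= area <= max_area`` (both bounds inclusive)."""
    if min_area > max_area:
        raise ValueError("min_area must be <= max_area")
    return [c for c in cells if min_area <= c.region.area <= max_area]
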