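"""Per-channel image cleaning and conversion into density-clustering weights.

The preprocessing chain applied to each segmentation channel is

1. hot-pixel removal (isolated detector spikes replaced by their
   8-neighbour maximum),
2. background subtraction (channel minus a sigma-40 Gaussian blur of
   itself, clamped at zero),
3. weight transform (zero below the 30th percentile, clip at the 99.5th
   percentile, divide by the new maximum so weights lie in [0, 1]).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import ChannelImage, WeightMap

__all__ = ["remove_hot_pixels", "subtract_background", "compute_weights"]

_NEIGHBOR8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)


def remove_hot_pixels(img: ChannelImage, threshold: float) -> ChannelImage:
    """Replace isolated spikes by their 8-neighbour maximum.

    A pixel whose value exceeds the maximum of its existing 8-neighbours by
    strictly more than ``threshold`` counts is set to that maximum. The rule
    is evaluated in a single pass over the original image (no cascading) and
    is idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    a = img.data
    # -inf fill means border pixels only compete against existing neighbours
    nbr_max = ndimage.maximum_filter(
        a, footprint=_NEIGHBOR8, mode="constant", cval=-np.inf
    )
    # a 1×1 image has no neighbours at all; leave it untouched
    out = np.where(np.isfinite(nbr_max) & (a - nbr_max > threshold), nbr_max, a)
    return ChannelImage(img.name, out)


def subtract_background(
    img: ChannelImage, sigma: float, truncate: float = 4.0
) -> ChannelImage:
    """Remove uneven background by subtracting a Gaussian blur of the channel.

    The blur uses reflective boundary handling and a kernel truncated at
    ``truncate`` sigmas; negative residuals are clamped to zero so the result
    can feed the nonnegative weight transform.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    blur = ndimage.gaussian_filter(img.data, sigma=sigma, mode="reflect", truncate=truncate)
    return ChannelImage(img.name, np.clip(img.data - blur, 0.0, None))


def compute_weights(
    img_bc: ChannelImage,
    low_percentile: float,
    high_percentile: float,
    population: str = "all",
) -> WeightMap:
    """Turn a background-corrected channel into DBSCAN pixel weights.

    Pixels strictly below the ``low_percentile`` of the pixel population are
    set to 0, values are clipped at the ``high_percentile``, and the result is
    divided by its new maximum so the largest weight is exactly 1. An all-zero
    input (or one whose every pixel falls below the low cut) yields an
    all-zero map.

    ``population`` selects the pixels over which percentiles are estimated:
    ``"all"`` (default) or ``"nonzero"`` only.
    """
    if not (0 <= low_percentile < high_percentile <= 100):
        raise ValueError("need 0 <= low_percentile < high_percentile <= 100")
    a = img_bc.data
    if population == "all":
        pop = a.ravel()
    elif population == "nonzero":
        pop = a[a > 0].ravel()
    else:
        raise ValueError("population must be 'all' or 'nonzero'")
    if pop.size == 0:
        return WeightMap(np.zeros_like(a))
    p_low = np.percentile(pop, low_percentile)
    p_high = np.percentile(pop, high_percentile)
    v = np.minimum(a, p_high)
    v[a < p_low] = 0.0
    mx = v.max()
    if mx <= 0:
        return WeightMap(np.zeros_like(a))
    return WeightMap(v / mx)
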