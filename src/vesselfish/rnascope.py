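"""Low-plex smFISH (RNAscope) image quantification.

Each channel of an 8-bit image passes a three-step background-removal
chain — subtraction of a wide Gaussian blur, rolling-ball background
subtraction, and an intensity floor — before the region of interest is
tiled into square bins with the per-channel maximum intensity recorded
per bin.  Marker co-expression fractions are then computed on the
binarized bins after excluding double-positive bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import restoration
from skimage.measure import block_reduce

__all__ = [
    "RnascopeParams",
    "preprocess_channel",
    "bin_roi_max",
    "coexpression_fractions",
    "CoexpressionResult",
]


@dataclass(frozen=True)
class RnascopeParams:
    """Background-removal and binning parameters (8-bit images).

    Defaults: Gaussian blur sigma 50 px, rolling-ball radius 50 px,
    intensity floor 40 of 255.
    """

    gaussian_sigma: float = 50.0
    rolling_ball_radius: int = 50
    intensity_floor: int = 40
    bin_px: int = 50

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if not (0 <= self.intensity_floor <= 255):
            raise ValueError("intensity_floor must be an 8-bit value")
        if self.bin_px < 1:
            raise ValueError("bin_px must be >= 1")


def preprocess_channel(image: np.ndarray, params: RnascopeParams = RnascopeParams()) -> np.ndarray:
    """Three-step background removal on a single 8-bit channel.

    (1) subtract a Gaussian blur (sigma ``gaussian_sigma``) of the raw
    image, clipping negatives to zero; (2) subtract the rolling-ball
    background (radius ``rolling_ball_radius``); (3) zero every pixel
    below ``intensity_floor``.  The output is uint8 and contains no
    value strictly between 0 and the floor.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    raw = image.astype(float)
    blurred = ndimage.gaussian_filter(raw, sigma=params.gaussian_sigma)
    step1 = np.clip(raw - blurred, 0, None)
    background = restoration.rolling_ball(step1, radius=params.rolling_ball_radius)
    step2 = np.clip(step1 - background, 0, 255)
    out = np.where(step2 < params.intensity_floor, 0.0, step2)
    return np.round(out).astype(np.uint8)


def bin_roi_max(
    channels: dict[str, np.ndarray],
    bin_px: int,
    roi: tuple[int, int, int, int] | None = None,
) -> pd.DataFrame:
    """Tile the ROI into ``bin_px`` squares; record per-channel maxima.

    ``roi`` is (x0, y0, x1, y1) in pixels (half-open; None = full
    image).  Returns one row per bin with columns ``bin_x``/``bin_y``
    (tile indices within the ROI), a max-intensity column per channel,
    and a boolean ``<channel>_pos`` column (max > 0).  A bin size
    exceeding the ROI yields a single bin.
    """
    if not channels:
        raise ValueError("no channels given")
    shapes = {im.shape for im in channels.values()}
    if len(shapes) > 1:
        raise ValueError("channel shapes differ")
    h, w = shapes.pop()
    if roi is None:
        roi = (0, 0, w, h)
    x0, y0, x1, y1 = roi
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError("ROI outside the image")

    per_channel = {}
    for name, im in channels.items():
        crop = np.asarray(im)[y0:y1, x0:x1]
        per_channel[name] = block_reduce(crop, (bin_px, bin_px), np.max, cval=0)

    any_grid = next(iter(per_channel.values()))
    ny, nx = any_grid.shape
    jj, ii = np.mgrid[0:ny, 0:nx]
    table = pd.DataFrame({"bin_x": ii.ravel(), "bin_y": jj.ravel()})
    for name, grid in per_channel.items():
        table[name] = grid.ravel()
        table[f"{name}_pos"] = grid.ravel() > 0
    return table


@dataclass
class CoexpressionResult:
    """Fractions of single-positive marker bins co-expressing the target.

    ``frac_a`` is the fraction of A-only (A⁺B⁻) bins that are
    target-positive, over ``n_a_only`` bins; likewise ``frac_b``.
    Fractions are NaN (``defined_* = False``) when the denominator is
    empty.  ``n_double_positive`` bins were excluded up front.
    """

    frac_a: float
    frac_b: float
    n_a_only: int
    n_b_only: int
    n_double_positive: int
    defined_a: bool
    defined_b: bool


def coexpression_fractions(
    bin_table: pd.DataFrame, markers: tuple[str, str, str]
) -> CoexpressionResult:
    """Co-expression of two mutually exclusive markers with a target gene.

    Double-positive (A⁺ and B⁺) bins are removed; among the remaining
    A-only and B-only bins the fraction positive for the target channel
    is reported for each marker.
    """
    a, b, target = markers
    for m in markers:
        if f"{m}_pos" not in bin_table.columns:
            raise KeyError(f"missing expression column {m}_pos")
    ap = bin_table[f"{a}_pos"].to_numpy(dtype=bool)
    bp = bin_table[f"{b}_pos"].to_numpy(dtype=bool)
    tp = bin_table[f"{target}_pos"].to_numpy(dtype=bool)

    double = ap & bp
    a_only = ap & ~bp & ~double
    b_only = bp & ~ap & ~double

    frac_a = float(tp[a_only].mean()) if a_only.any() else float("nan")
    frac_b = float(tp[b_only].mean()) if b_only.any() else float("nan")
    return CoexpressionResult(
        frac_a,
        frac_b,
        int(a_only.sum()),
        int(b_only.sum()),
        int(double.sum()),
        bool(a_only.any()),
        bool(b_only.any()),
    )
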