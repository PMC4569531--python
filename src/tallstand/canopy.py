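"""Canopy cover from hemispherical photographs.

Each plot carries a 4x4 grid of fixed photo stations at 20-m spacing.
A photo is segmented into canopy and sky by a fixed intensity cut-off
(default 125 on the 0-255 scale): pixels strictly below the threshold
are canopy, pixels at or above it are sky. Plot cover is the unweighted
mean of the per-station canopy fractions.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

#: Default canopy/sky intensity cut-off on the 0-255 scale.
DEFAULT_THRESHOLD = 125.0

#: Channel used to reduce colour photos to intensity. Blue gives the
#: strongest canopy/sky contrast in hemispherical photography.
DEFAULT_CHANNEL = "blue"

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class CanopyImage:
    """A grayscale canopy photo tied to a plot and station."""

    pixels: np.ndarray  # 2-D, intensities in [0, 255]
    station_id: int = 1
    plot_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)


def load_canopy_image(
    path,
    station_id: int = 1,
    plot_id: str = "",
    channel: str = DEFAULT_CHANNEL,
) -> CanopyImage:
    """Read a PNG/TIFF photo; colour images are reduced by ``channel``."""
    img = Image.open(Path(path))
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[:, :, _CHANNEL_INDEX[channel]]
    return CanopyImage(pixels=arr.astype(float), station_id=station_id, plot_id=plot_id)


def circular_mask(shape: tuple[int, int], radius: float | None = None) -> np.ndarray:
    """Boolean fisheye mask centred on the image; True = keep."""
    h, w = shape
    if radius is None:
        radius = min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def canopy_fraction(
    image: CanopyImage,
    threshold: float = DEFAULT_THRESHOLD,
    mask_radius: float | None = None,
) -> float:
    """Percent canopy cover: share of pixels strictly below ``threshold``.

    A pixel exactly at the threshold counts as sky. ``mask_radius``
    optionally restricts the count to a centred fisheye circle.
    """
    px = image.pixels
    if mask_radius is not None:
        keep = circular_mask(px.shape, mask_radius)
        px = px[keep]
    return 100.0 * float(np.count_nonzero(px < threshold)) / px.size


def plot_canopy_cover(
    images,
    threshold: float = DEFAULT_THRESHOLD,
    mask_radius: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Plot-level cover: unweighted mean over stations, plus per-station table."""
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    plot_ids = {im.plot_id for im in images}
    if len(plot_ids) > 1:
        raise ValueError(f"images span multiple plots: {sorted(plot_ids)}")
    rows = [
        {
            "plot_id": im.plot_id,
            "station_id": im.station_id,
            "canopy_cover_pct": canopy_fraction(im, threshold, mask_radius),
        }
        for im in images
    ]
    table = pd.DataFrame(rows).sort_values("station_id").reset_index(drop=True)
    return float(table["canopy_cover_pct"].mean()), table
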