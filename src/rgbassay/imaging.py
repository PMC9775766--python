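"""Disc-image reading, ROI handling and mean channel intensities.

Coordinates are raster convention: (x, y) with origin at the top-left
pixel, 0-based, y increasing downward. A pixel belongs to a circular ROI
when its center lies strictly inside the radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import measure

__all__ = [
    "RoiSpec",
    "ChannelIntensities",
    "DiscDetectionError",
    "RoiError",
    "read_image",
    "detect_disc",
    "mean_channel_intensities",
]


class DiscDetectionError(RuntimeError):
    """No disc-like component could be located in the image."""


class RoiError(ValueError):
    """The ROI is outside the image or covers too few pixels."""


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest.

    ``shrink_fraction`` scales the radius before pixels are collected, to
    stay inside the uniformly coloured center of the disc and away from
    rim artifacts. Default 0.8.
    """

    center: tuple[float, float]  # (x, y), pixels
    radius: float                # pixels
    shrink_fraction: float = 0.8
    mode: str = "fixed-circle"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 < self.shrink_fraction <= 1.0):
            raise ValueError("shrink_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class ChannelIntensities:
    """Mean 8-bit intensities of the three colour channels over an ROI."""

    mean_red: float
    mean_green: float
    mean_blue: float
    pixel_count: int
    saturation_fraction: float

    def __post_init__(self) -> None:
        for m in (self.mean_red, self.mean_green, self.mean_blue):
            if not (0.0 <= m <= 255.0):
                raise ValueError("channel means must lie in [0, 255]")
        if self.pixel_count <= 0:
            raise ValueError("pixel_count must be positive")
        if not (0.0 <= self.saturation_fraction <= 1.0):
            raise ValueError("saturation_fraction must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mean_red, self.mean_green, self.mean_blue)


def read_image(path: str | Path) -> np.ndarray:
    """Load an image as an 8-bit RGB array (H, W, 3).

    Alpha channels are discarded; grayscale images are promoted to RGB by
    channel replication with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I", "I;16", "F"):
                warnings.warn(
                    f"{path.name}: grayscale image promoted to RGB by "
                    "channel replication", stacklevel=2)
            arr = np.asarray(im.convert("RGB"))
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a decodable image: {path}") from exc
    except OSError as exc:
        raise ValueError(f"corrupt or truncated image: {path}") from exc
    return arr.astype(np.uint8)


def detect_disc(
    image: np.ndarray,
    threshold: float = 8.0,
    shrink_fraction: float = 0.8,
) -> RoiSpec:
    """Locate the reaction disc automatically.

    The background level is estimated per channel from the image border;
    pixels deviating from it by more than ``threshold`` (max over
    channels) are foreground. The largest connected component is taken as
    the disc and summarised by its centroid and area-equivalent radius.
    This also finds blank discs, which differ from the paper background in
    level even without developed colour.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    border = np.concatenate([
        img[0, :, :], img[-1, :, :], img[:, 0, :], img[:, -1, :]])
    background = np.median(border, axis=0)
    deviation = np.abs(img - background).max(axis=2)
    fg = deviation > threshold
    if not fg.any():
        raise DiscDetectionError("no pixels deviate from the background")
    labels = measure.label(fg)
    props = measure.regionprops(labels)
    disc = max(props, key=lambda p: p.area)
    if disc.area < 50:
        raise DiscDetectionError("largest component too small to be a disc")
    cy, cx = disc.centroid
    radius = float(np.sqrt(disc.area / np.pi))
    return RoiSpec(center=(float(cx), float(cy)), radius=radius,
                   shrink_fraction=shrink_fraction, mode="auto-detect")


def mean_channel_intensities(
    image: np.ndarray, roi: RoiSpec, min_pixels: int = 50
) -> ChannelIntensities:
    """Arithmetic per-channel mean over the (shrunken) circular ROI.

    The effective radius is ``roi.radius * roi.shrink_fraction``; a pixel
    counts when its center is strictly inside it. Saturated pixels (any
    channel at 255) are included in the means but reported through
    ``saturation_fraction``, with a warning above 1%.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    h, w = img.shape[:2]
    cx, cy = roi.center
    if not (0 <= cx < w and 0 <= cy < h):
        raise RoiError(f"ROI center {roi.center} outside image bounds")
    r_eff = roi.radius * roi.shrink_fraction
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r_eff**2
    count = int(mask.sum())
    if count < min_pixels:
        raise RoiError(
            f"ROI covers {count} pixels; at least {min_pixels} required")
    pixels = img[mask].astype(float)
    saturated = float(np.mean((img[mask] == 255).any(axis=1)))
    if saturated > 0.01:
        warnings.warn(
            f"{saturated:.1%} of ROI pixels are saturated; means may be "
            "biased", stacklevel=2)
    means = pixels.mean(axis=0)
    return ChannelIntensities(
        mean_red=float(means[0]), mean_green=float(means[1]),
        mean_blue=float(means[2]), pixel_count=count,
        saturation_fraction=saturated)
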