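"""Image containers, TIFF I/O and tiling.

All image operations in the package run on :class:`RasterImage` — a 2D
intensity grid carrying its physical pixel size in micrometres — or on
:class:`BinaryMask`.  Coordinates are 0-based, row-major, origin at the
top-left; every micrometre/pixel conversion goes through :func:`um_to_px`
and :func:`px_to_um`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile


def um_to_px(length_um: float, pixel_size: float) -> float:
    """Convert a physical length in micrometres to pixels."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return length_um / pixel_size


def px_to_um(length_px: float, pixel_size: float) -> float:
    """Convert a pixel length to micrometres."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return length_px * pixel_size


@dataclass
class RasterImage:
    """A single-channel 2D image with a physical scale.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities.  The dtype is kept
        as given so that integer images round-trip exactly through TIFF.
    pixel_size
        Micrometres per pixel (> 0).
    channel_label
        Free-text channel description (e.g. ``"SHG collagen"``).
    """

    pixels: np.ndarray
    pixel_size: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def side_um(self) -> tuple[float, float]:
        """(height, width) of the field in micrometres."""
        h, w = self.pixels.shape
        return (px_to_um(h, self.pixel_size), px_to_um(w, self.pixel_size))

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)


@dataclass
class BinaryMask:
    """A boolean foreground mask sharing the shape contract of its source image."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={self.pixels.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def complement(self) -> "BinaryMask":
        return BinaryMask(~self.pixels, self.pixel_size)


def _pixel_size_from_tiff(path: str) -> float | None:
    """Best-effort pixel size (um/px) from TIFF resolution tags; None if absent."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            tags = page.tags
            xres = tags.get("XResolution")
            unit = tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value
            if num == 0:
                return None
            px_per_unit = num / den
            # ResolutionUnit: 2 = inch, 3 = centimetre
            unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", None), None)
            if unit_um is None:
                return None
            return unit_um / px_per_unit
    except Exception:
        return None


def load_image(
    path: str,
    pixel_size: float | None = None,
    channel: int | None = None,
    channel_label: str = "",
) -> RasterImage:
    """Load one channel of a TIFF file as a :class:`RasterImage`.

    ``pixel_size`` (um/px) is mandatory in practice: TIFF pixel-size metadata
    dialects vary, so file metadata is only a fallback when ``pixel_size`` is
    None.  Multi-channel files may be stored as (C, H, W) or (H, W, C);
    ``channel`` selects the plane (required when more than one is present).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        if channel not in (None, 0):
            raise IndexError(f"channel {channel} out of range for single-channel image")
        plane = data
    elif data.ndim == 3:
        # smaller axis is the channel axis; (C, H, W) preferred on ties
        c_axis = 0 if data.shape[0] <= data.shape[2] else 2
        n_chan = data.shape[c_axis]
        idx = 0 if channel is None else channel
        if not (0 <= idx < n_chan):
            raise IndexError(f"channel {idx} out of range (n_channels={n_chan})")
        plane = np.take(data, idx, axis=c_axis)
    else:
        raise ValueError(f"unsupported TIFF dimensionality: {data.ndim}")
    if pixel_size is None:
        pixel_size = _pixel_size_from_tiff(path)
    if pixel_size is None:
        raise ValueError(
            "pixel_size not given and no usable resolution metadata in the file"
        )
    return RasterImage(plane, pixel_size, channel_label=channel_label)


def save_image(path: str, img: RasterImage) -> None:
    """Write an image to TIFF, preserving its dtype."""
    tifffile.imwrite(path, img.pixels)


def save_mask(path: str, mask: BinaryMask) -> None:
    """Write a mask as 8-bit TIFF (background 0, foreground 255)."""
    tifffile.imwrite(path, (mask.pixels.astype(np.uint8) * 255))


def tile_image(img: RasterImage, tile_side: float) -> list[RasterImage]:
    """Split a field into non-overlapping square tiles of ``tile_side`` um.

    Tiles are returned in row-major order and inherit the pixel size.
    Partial tiles at the right/bottom border are dropped rather than padded:
    padding would contaminate FFT spectra with artificial edges.
    """
    tile_px = int(round(um_to_px(tile_side, img.pixel_size)))
    h, w = img.pixels.shape
    if tile_px <= 0 or tile_px > min(h, w):
        raise ValueError(
            f"tile_side {tile_side} um ({tile_px} px) exceeds image extent {img.side_um} um"
        )
    tiles = []
    for i in range(h // tile_px):
        for j in range(w // tile_px):
            sub = img.pixels[i * tile_px:(i + 1) * tile_px, j * tile_px:(j + 1) * tile_px]
            tiles.append(
                RasterImage(sub.copy(), img.pixel_size, channel_label=img.channel_label)
            )
    return tiles
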