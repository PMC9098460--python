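"""Calibrated image containers and TIFF I/O.

All pipeline stages operate on :class:`RasterImage` (one calibrated plane)
or :class:`ImageStack` (planes indexed by ``(z, channel)``).  Pixels are
held in floating point; 16-bit TIFF is the on-disk interchange format,
with the float->uint16 scaling recorded so thresholds defined on
histograms stay well defined across round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["RasterImage", "ImageStack", "LabelMask", "write_tiff", "read_tiff"]

UINT16_MAX = 65535


@dataclass(frozen=True)
class RasterImage:
    """A single calibrated image plane.

    Parameters
    ----------
    pixels : ndarray, shape (h, w)
        Intensities in arbitrary units; must be finite.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    bit_depth : int
        Nominal bit depth of the acquisition (informational; pixels are
        stored as float64 regardless).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D plane, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size ** 2


@dataclass(frozen=True)
class ImageStack:
    """Planes indexed by ``(z, channel)`` sharing shape and calibration."""

    planes: np.ndarray  # (z, c, h, w)
    channel_names: tuple[str, ...]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.planes, dtype=np.float64)
        if arr.ndim == 3:  # single z
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError("planes must have shape (z, channel, h, w)")
        if arr.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match channel axis")
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack contains non-finite intensities")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "planes", arr)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_z(self) -> int:
        return self.planes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.planes.shape[1]

    def plane(self, z: int = 0, channel: int | str = 0) -> RasterImage:
        if isinstance(channel, str):
            channel = self.channel_names.index(channel)
        return RasterImage(self.planes[z, channel], self.pixel_size)


@dataclass(frozen=True)
class LabelMask:
    """Integer instance labels, 0 = background.

    ``provenance`` names the operation that produced the mask so output
    tables can state where each region came from.
    """

    labels: np.ndarray
    pixel_size: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", lab.astype(np.int32))

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    def region(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


def write_tiff(path, data: np.ndarray, pixel_size: float | None = None,
               scale_to_uint16: bool = True) -> None:
    """Write an array as TIFF, deterministically (no timestamps).

    Float data is min-max scaled to the full uint16 range; the scaling is
    stored in the ImageDescription so it can be undone on read.  Integer
    data is written verbatim.
    """
    data = np.asarray(data)
    meta = {}
    if pixel_size is not None:
        meta["pixel_size_um"] = float(pixel_size)
    if scale_to_uint16 and np.issubdtype(data.dtype, np.floating):
        lo, hi = float(data.min()), float(data.max())
        scale = (hi - lo) / UINT16_MAX if hi > lo else 1.0
        out = np.round((data - lo) / scale).astype(np.uint16) if hi > lo \
            else np.zeros(data.shape, np.uint16)
        meta.update({"offset": lo, "scale": scale})
        tifffile.imwrite(path, out, metadata=meta, photometric="minisblack")
    else:
        tifffile.imwrite(path, data, metadata=meta, photometric="minisblack")


def read_tiff(path, pixel_size: float | None = None,
              channel_names: tuple[str, ...] | None = None):
    """Read a TIFF written by :func:`write_tiff` (or any plain TIFF).

    Returns a :class:`RasterImage` for 2-D files and an
    :class:`ImageStack` for 3-/4-D files (leading axes interpreted as
    ``(z, channel)`` or ``channel`` when `channel_names` is given).
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if "scale" in meta:
        arr = arr * float(meta["scale"]) + float(meta["offset"])
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size_um", 1.0))
    if arr.ndim == 2:
        return RasterImage(arr, pixel_size)
    if arr.ndim == 3:
        names = channel_names or tuple(f"ch{i}" for i in range(arr.shape[0]))
        return ImageStack(arr[None], names, pixel_size)
    names = channel_names or tuple(f"ch{i}" for i in range(arr.shape[1]))
    return ImageStack(arr, names, pixel_size)
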