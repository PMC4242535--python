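"""Raster I/O for hemispherical canopy photographs.

Binarization operates on a single 8-bit gray plane — by convention the blue
channel of an RGB photograph, where the contrast between foliage and sky is
highest because leaves scatter little blue light.  This module reads rasters,
extracts that plane, restricts analysis to the circular fisheye field of view,
and builds the 256-bin gray-value histograms every histogram-based threshold
algorithm consumes.

Pixel coordinates are 0-based ``(x=column, y=row)`` with the origin at the
top-left corner; arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import imageio.v3 as iio
import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .thresholding import BinaryMap

__all__ = [
    "GrayImage",
    "GrayHistogram",
    "read_image",
    "circular_mask",
    "histogram",
    "write_binary_mask",
    "read_binary_mask",
]

#: Sentinel gray value used on disk for pixels outside the analyzed circle.
OUTSIDE_SENTINEL = 128
#: On-disk gray value for vegetation pixels in a written binary mask.
VEGETATION_VALUE = 0
#: On-disk gray value for sky pixels in a written binary mask.
SKY_VALUE = 255


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit gray raster with a validity mask for the fisheye circle.

    Attributes
    ----------
    values
        ``(height, width)`` uint8 array of gray levels in [0, 255].
    mask
        Boolean array of identical shape; ``True`` marks pixels inside the
        analyzed circular field of view.  Defaults to all-true (full frame).
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError(f"gray image must be 2-D, got shape {values.shape}")
        if values.dtype != np.uint8:
            if not np.issubdtype(values.dtype, np.integer):
                raise ValueError(f"gray values must be integer, got {values.dtype}")
            if values.size and (values.min() < 0 or values.max() > 255):
                raise ValueError("gray values outside [0, 255]")
            values = values.astype(np.uint8)
        mask = self.mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValueError(
                    f"mask shape {mask.shape} does not match image shape {values.shape}"
                )
        if not mask.any():
            raise ValueError("mask excludes every pixel")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def n_masked(self) -> int:
        """Number of pixels inside the analyzed area."""
        return int(self.mask.sum())


@dataclass(frozen=True)
class GrayHistogram:
    """256-bin gray-value histogram of the masked pixels of a :class:`GrayImage`."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError(f"histogram must have exactly 256 bins, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        total = int(counts.sum())
        if total <= 0:
            raise ValueError("histogram is empty")
        if total != int(self.total):
            raise ValueError(
                f"declared total {self.total} does not match counts sum {total}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total", total)

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "GrayHistogram":
        counts = np.asarray(counts, dtype=np.int64)
        return cls(counts=counts, total=int(counts.sum()))

    def to_csv(self, path: str | Path) -> None:
        """Export as a 256-row ``gray_value,count`` table."""
        lines = ["gray_value,count"]
        lines += [f"{g},{int(c)}" for g, c in enumerate(self.counts)]
        Path(path).write_text("\n".join(lines) + "\n")


def read_image(path: str | Path, channel: str = "blue") -> GrayImage:
    """Read a raster and extract one 8-bit gray plane.

    Parameters
    ----------
    path
        PNG, TIFF or JPEG file.  Higher bit depths are accepted only when all
        values already fit in [0, 255] (lossless reduction).
    channel
        ``"blue"`` extracts the blue plane of an RGB(A) image; ``"gray"``
        passes a single-channel raster through unchanged (a multi-channel
        input is rejected so no silent luma conversion happens).
    """
    path = Path(path)
    if channel not in ("blue", "gray"):
        raise ValueError(f"unknown channel {channel!r}; expected 'blue' or 'gray'")
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize backend errors
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        if channel == "blue":
            raise ValueError(f"{path}: single-channel image has no blue plane")
        plane = arr
    elif arr.ndim == 3:
        if channel == "gray":
            raise ValueError(
                f"{path}: channel='gray' requires a single-channel raster; "
                "use channel='blue' for RGB input"
            )
        if arr.shape[2] < 3:
            raise ValueError(f"{path}: image has {arr.shape[2]} channels, no blue plane")
        plane = arr[:, :, 2]
    else:
        raise ValueError(f"{path}: unsupported raster shape {arr.shape}")
    if plane.dtype != np.uint8:
        if not np.issubdtype(plane.dtype, np.integer):
            raise ValueError(f"{path}: non-integer bit depth {plane.dtype} not supported")
        if plane.max(initial=0) > 255 or plane.min(initial=0) < 0:
            raise ValueError(
                f"{path}: bit depth {plane.dtype} cannot be losslessly reduced to 8-bit"
            )
        plane = plane.astype(np.uint8)
    return GrayImage(values=plane)


def circular_mask(
    image: GrayImage, center: tuple[float, float], radius: float
) -> GrayImage:
    """Restrict an image's mask to the circular fisheye field of view.

    The new mask is true where ``(px - x)**2 + (py - y)**2 <= radius**2``
    (intersected with any pre-existing mask); pixel values are unchanged.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    cx, cy = center
    yy, xx = np.ogrid[0 : image.height, 0 : image.width]
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    new_mask = image.mask & disc
    if not new_mask.any():
        raise ValueError(
            f"circle center={center} radius={radius} does not intersect the image"
        )
    return GrayImage(values=image.values, mask=new_mask)


def histogram(image: GrayImage) -> GrayHistogram:
    """256-bin histogram over mask-true pixels only.

    Out-of-circle pixels never enter the histogram: they are not part of the
    hemisphere being analyzed and would otherwise distort every
    histogram-based threshold.
    """
    counts = np.bincount(image.values[image.mask].ravel(), minlength=256)
    return GrayHistogram.from_counts(counts)


def write_binary_mask(binary: "BinaryMap", path: str | Path) -> None:
    """Write a vegetation/sky map as a lossless 8-bit PNG.

    Encoding: vegetation=0, sky=255, outside-mask pixels=128.  The convention
    is also recorded in a JSON sidecar next to the raster so the file is
    self-describing.
    """
    from .thresholding import OUTSIDE, SKY, VEGETATION

    path = Path(path)
    out = np.full(binary.classes.shape, OUTSIDE_SENTINEL, dtype=np.uint8)
    out[binary.classes == VEGETATION] = VEGETATION_VALUE
    out[binary.classes == SKY] = SKY_VALUE
    iio.imwrite(path, out, extension=".png")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "format": "hemibin binary mask",
                "vegetation": VEGETATION_VALUE,
                "sky": SKY_VALUE,
                "outside": OUTSIDE_SENTINEL,
            },
            indent=2,
        )
        + "\n"
    )


def read_binary_mask(path: str | Path) -> "BinaryMap":
    """Read a binary mask written by :func:`write_binary_mask` (bit-exact)."""
    from .thresholding import OUTSIDE, SKY, VEGETATION, BinaryMap

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # grayscale PNG re-read as RGB by some backends
        arr = arr[:, :, 0]
    classes = np.full(arr.shape, OUTSIDE, dtype=np.int8)
    classes[arr == VEGETATION_VALUE] = VEGETATION
    classes[arr == SKY_VALUE] = SKY
    unknown = (arr != VEGETATION_VALUE) & (arr != SKY_VALUE) & (arr != OUTSIDE_SENTINEL)
    if unknown.any():
        raise ValueError(
            f"{path}: {int(unknown.sum())} pixels with values outside the "
            f"0/128/255 binary-mask convention"
        )
    return BinaryMap(classes=classes)
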