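"""Reading raw images and probability maps into canonical 2D planes.

Raw input is single- or multi-page grayscale TIFF (8- or 16-bit). Multi-plane
stacks are reduced to a single plane by maximum intensity projection (MIP),
the standard flattening step for confocal z-stacks of nuclear markers.
Per-image intensity features (mean, SD, min, max, mode, mean background) are
exposed for quality control, to quantify staining and acquisition variability
across samples and experimenters before any counting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from skimage.draw import polygon2mask


class UnsupportedPixelTypeError(ValueError):
    """Raised for RGB, float or otherwise non-grayscale-integer input."""


_BIT_DEPTH = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass(frozen=True)
class ImageStack:
    """A z-stack of grayscale planes, shape (z, y, x), native bit depth."""

    planes: np.ndarray
    bit_depth: int
    name: str = ""
    pixel_size: Optional[float] = None  # microns per pixel, if known

    def __post_init__(self) -> None:
        if self.planes.ndim != 3 or self.planes.size == 0:
            raise ValueError("stack must be a non-empty (z, y, x) array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]


@dataclass(frozen=True)
class Image2D:
    """A single grayscale plane, shape (y, x)."""

    pixels: np.ndarray
    bit_depth: int
    name: str = ""
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty (y, x) array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def dynamic_max(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class IntensityFeatures:
    """Per-image intensity summary used to assess staining variability.

    ``mode`` is the most frequent integer intensity (smallest value on ties).
    ``mean_background`` is the mean inside a user polygon when one is given,
    otherwise the image mode — background dominates tissue fields, so the
    histogram mode is a reasonable stand-in for a hand-drawn background ROI.
    """

    mean: float
    sd: float
    min: int
    max: int
    mode: int
    mean_background: float


def read_image(path: str | Path) -> ImageStack:
    """Read a grayscale 8/16-bit TIFF into an :class:`ImageStack`.

    A single-page file yields z = 1; page order is preserved. RGB, multi-sample
    and float TIFFs are rejected: one channel per file is required.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page0 = tif.pages[0]
        if getattr(page0, "samplesperpixel", 1) != 1:
            raise UnsupportedPixelTypeError(
                f"{path.name}: unsupported pixel type (multi-sample/RGB); "
                "supply one grayscale channel per file"
            )
        arr = tif.asarray()
    if arr.dtype not in _BIT_DEPTH:
        raise UnsupportedPixelTypeError(
            f"{path.name}: unsupported pixel type {arr.dtype}; "
            "expected uint8 or uint16 grayscale"
        )
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3 or arr.size == 0:
        raise ValueError(f"{path.name}: zero-size or non-2D/3D image")
    return ImageStack(planes=arr, bit_depth=_BIT_DEPTH[arr.dtype], name=path.stem)


def max_intensity_projection(stack: ImageStack) -> Image2D:
    """Collapse a stack to its per-pixel maximum over z (MIP).

    A one-plane stack is returned unchanged (bit-exact), so the projection is
    idempotent.
    """
    return Image2D(
        pixels=stack.planes.max(axis=0),
        bit_depth=stack.bit_depth,
        name=stack.name,
        pixel_size=stack.pixel_size,
    )


def load_plane(path: str | Path) -> Image2D:
    """Read a TIFF and reduce it to one plane (MIP when multi-page)."""
    return max_intensity_projection(read_image(path))


def _mode(pixels: np.ndarray) -> int:
    counts = np.bincount(pixels.ravel())
    return int(np.argmax(counts))  # argmax returns the smallest index on ties


def extract_intensity_features(
    image: Image2D,
    background_region: Optional[Sequence[Sequence[float]]] = None,
) -> IntensityFeatures:
    """Compute mean/SD/min/max/mode and mean background intensity.

    Parameters
    ----------
    image:
        The plane to summarize.
    background_region:
        Optional polygon of (y, x) vertices delimiting a background patch;
        when omitted the image mode is used as the background estimate.

    SD uses the sample (n−1) denominator, matching ImageJ's Measure "StdDev".
    """
    px = image.pixels
    flat = px.ravel().astype(np.float64)
    mode = _mode(px)
    if background_region is not None:
        verts = np.asarray(background_region, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3:
            raise ValueError("background_region needs >= 3 (y, x) vertices")
        mask = polygon2mask(px.shape, verts)
        if not mask.any():
            raise ValueError("background_region covers no pixels")
        mean_background = float(px[mask].mean())
    else:
        mean_background = float(mode)
    sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
    return IntensityFeatures(
        mean=float(flat.mean()),
        sd=sd,
        min=int(px.min()),
        max=int(px.max()),
        mode=mode,
        mean_background=mean_background,
    )
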