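"""Candidate-cell segmentation and per-cell measurement.

Three routes produce a label image (0 = background, 1..L = cells):

* ``ingest_label_image`` — a pre-made label image from an external convex-object
  segmenter (e.g. a StarDist nuclei model run outside this tool);
* ``segment_probability_map`` — a pixel-classifier probability map (e.g. from
  ilastik), binarized with the iterative intermeans ("Default" in ImageJ)
  auto-threshold and connected-component labeled;
* ``builtin_segment`` — a self-contained Gaussian + threshold + watershed
  fixture segmenter for images with well-separated convex cells.

Whatever the route, downstream intensity statistics are always measured on the
raw image, never on the probability map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .imageio import Image2D

logger = logging.getLogger(__name__)


class ConstantImageError(ValueError):
    """No threshold exists: the image has a single intensity value."""


@dataclass(frozen=True)
class LabelImage:
    """Integer label image; 0 is background, labels run 1..L consecutively."""

    labels: np.ndarray
    source: str  # external_label | probability_map | builtin | synthetic

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: the unit every later stage operates on.

    ``mean_intensity`` is the cell's mean raw intensity (the per-cell x_i that
    the z-score cutoff standardizes); ``sd_intensity`` is the sample SD of the
    raw pixels under the label (0 for single-pixel cells).
    """

    label_id: int
    mean_intensity: float
    sd_intensity: float
    area: int
    centroid: Tuple[float, float]  # (y, x), 0-based pixel coordinates


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map the positive labels present to 1..L, preserving their order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


def ingest_label_image(path: str | Path, raw: Image2D) -> LabelImage:
    """Load an externally produced label TIFF and normalize its ids.

    Labels are relabeled to consecutive 1..L (ascending original id) while
    keeping the pixel partition identical.
    """
    arr = tifffile.imread(str(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{Path(path).name}: label image must be integer-valued")
    if arr.ndim != 2 or arr.shape != raw.pixels.shape:
        raise ValueError(
            f"{Path(path).name}: label shape {arr.shape} does not match "
            f"raw shape {raw.pixels.shape}"
        )
    return LabelImage(labels=_relabel_consecutive(arr.astype(np.int64)), source="external_label")


def default_threshold(image: Image2D | np.ndarray) -> int:
    """Iterative intermeans (IsoData-variant) threshold, ImageJ's "Default".

    Starting from the overall mean, iterate

        t_{k+1} = floor((mean of values <= t_k + mean of values > t_k) / 2)

    to its fixed point and return the converged integer threshold t.
    Foreground is defined as pixels strictly greater than t. The update map is
    monotone on [min, max-1], so a fixed point always exists and the iteration
    terminates.
    """
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image)
    if not np.issubdtype(px.dtype, np.integer):
        raise ValueError("threshold requires an integer-valued image")
    vmin, vmax = int(px.min()), int(px.max())
    if vmin == vmax:
        raise ConstantImageError("constant image: no threshold exists")

    counts = np.bincount(px.ravel().astype(np.int64) - vmin)
    values = np.arange(vmin, vmax + 1, dtype=np.float64)
    csum_n = np.cumsum(counts)
    csum_v = np.cumsum(counts * values)
    total_n, total_v = csum_n[-1], csum_v[-1]

    def step(t: int) -> int:
        i = t - vmin
        lo = csum_v[i] / csum_n[i]
        hi = (total_v - csum_v[i]) / (total_n - csum_n[i])
        return int(np.clip(np.floor((lo + hi) / 2.0), vmin, vmax - 1))

    t = int(np.clip(np.floor(total_v / total_n), vmin, vmax - 1))
    while True:
        t_next = step(t)
        if t_next == t:
            return t
        t = t_next


def _connectivity_arg(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError("connectivity must be 4 or 8")


def _rescale_prob(prob: Image2D) -> np.ndarray:
    """Probability maps may be float 0–1 or 8/16-bit; floats become 8-bit."""
    px = prob.pixels
    if np.issubdtype(px.dtype, np.floating):
        return np.round(np.clip(px, 0.0, 1.0) * 255.0).astype(np.uint8)
    return px


def segment_probability_map(
    prob: Image2D,
    raw: Image2D,
    connectivity: int = 8,
    area_preview: Optional[Tuple[float, float]] = None,
) -> LabelImage:
    """Binarize a probability map with the intermeans threshold and label it.

    ``area_preview`` is an optional (lo, hi) pixel-area window; components
    outside it are dropped before relabeling.
    """
    if prob.pixels.shape != raw.pixels.shape:
        raise ValueError("probability map and raw image shapes differ")
    binarizable = _rescale_prob(prob)
    t = default_threshold(binarizable)
    mask = binarizable > t
    labels = cc_label(mask, connectivity=_connectivity_arg(connectivity))
    if area_preview is not None:
        lo, hi = area_preview
        areas = np.bincount(labels.ravel())
        drop = np.flatnonzero((areas < lo) | (areas > hi))
        labels[np.isin(labels, drop[drop > 0])] = 0
    return LabelImage(labels=_relabel_consecutive(labels), source="probability_map")


def builtin_segment(
    raw: Image2D,
    smoothing_radius: float = 2.0,
    min_distance: int = 5,
    connectivity: int = 8,
) -> LabelImage:
    """Fixture-grade segmenter: Gaussian smooth, auto-threshold, watershed.

    Touching cells are split by a distance-transform watershed whose markers
    are local maxima at least ``min_distance`` pixels apart. Intended for
    synthetic or high-contrast fields with roughly convex cells, not as a
    replacement for a trained segmentation model.
    """
    px = raw.pixels
    if px.min() == px.max():
        raise ConstantImageError("constant image: nothing to segment")
    smoothed = ndi.gaussian_filter(px.astype(np.float64), sigma=smoothing_radius)
    smoothed_int = np.round(smoothed).astype(np.int64)
    if smoothed_int.min() == smoothed_int.max():
        raise ConstantImageError("image is constant after smoothing")
    t = default_threshold(smoothed_int)
    mask = smoothed_int > t
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask,
                       connectivity=_connectivity_arg(connectivity))
    return LabelImage(labels=_relabel_consecutive(labels), source="builtin")


def remove_border_labels(labels: LabelImage) -> LabelImage:
    """Drop cells touching the image boundary and relabel consecutively.

    Mirrors the manual-counting convention of excluding cells on the XY
    boundary; off by default in the pipeline.
    """
    arr = labels.labels
    border = np.unique(
        np.concatenate([arr[0, :], arr[-1, :], arr[:, 0], arr[:, -1]])
    )
    border = border[border > 0]
    if border.size == 0:
        return labels
    out = arr.copy()
    out[np.isin(out, border)] = 0
    return LabelImage(labels=_relabel_consecutive(out), source=labels.source)


def extract_cell_records(
    labels: LabelImage,
    raw: Image2D,
    intensity_weighted_centroid: bool = False,
) -> List[CellRecord]:
    """Measure every labeled cell on the raw image.

    Returns one record per label, ordered by label id. Mean intensity is the
    mean of raw pixels under the label; SD uses the sample (n−1) denominator
    and is 0 for single-pixel cells. The centroid is the unweighted mean of
    member pixel coordinates unless ``intensity_weighted_centroid`` is set.
    """
    arr = labels.labels
    if arr.shape != raw.pixels.shape:
        raise ValueError("label image and raw image shapes differ")
    n = labels.n_labels
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    raw_f = raw.pixels.astype(np.float64)
    areas = ndi.sum_labels(np.ones_like(arr), arr, index=ids)
    sums = ndi.sum_labels(raw_f, arr, index=ids)
    sq_sums = ndi.sum_labels(raw_f**2, arr, index=ids)
    means = sums / areas
    # sample variance from the sufficient statistics; clamp tiny negatives
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sq_sums - sums**2 / areas) / (areas - 1)
    sds = np.sqrt(np.maximum(var, 0.0))
    sds[areas < 2] = 0.0
    weights = raw_f if intensity_weighted_centroid else np.ones_like(arr, dtype=float)
    centroids = ndi.center_of_mass(weights, arr, index=ids)
    return [
        CellRecord(
            label_id=int(i),
            mean_intensity=float(means[k]),
            sd_intensity=float(sds[k]),
            area=int(areas[k]),
            centroid=(float(centroids[k][0]), float(centroids[k][1])),
        )
        for k, i in enumerate(ids)
    ]
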