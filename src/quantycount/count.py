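"""Classify cells against the cutoff and orchestrate the counting pipeline.

``classify_cells`` partitions each image's cells into positive / negative /
area-excluded. ``run_pipeline`` ties the stages together: list the input
TIFFs in lexicographic order, segment each (external labels, probability map
or the built-in segmenter), estimate the intensity cutoff on the first f
"optimization" images (batch mode) or per image (non-batch), apply the area
filter, and count — per image and, when polygons are supplied, per sub-region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Literal, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Point, Polygon

from . import cutoff as co
from .imageio import Image2D, load_plane
from .segment import (
    CellRecord,
    LabelImage,
    builtin_segment,
    extract_cell_records,
    ingest_label_image,
    remove_border_labels,
    segment_probability_map,
)
from .imageio import read_image, max_intensity_projection

logger = logging.getLogger(__name__)

Mode = Literal["auto", "manual", "allcells"]
Detector = Literal["labels", "probmap", "builtin"]


@dataclass(frozen=True)
class CountResult:
    """One image's classification: disjoint positive/negative/excluded sets."""

    image_name: str
    positive_ids: FrozenSet[int]
    negative_ids: FrozenSet[int]
    area_excluded_ids: FrozenSet[int]
    cutoff_used: Optional[float]
    area_bounds: Optional[co.AreaBounds]
    mode: Mode

    def __post_init__(self) -> None:
        if (
            self.positive_ids & self.negative_ids
            or self.positive_ids & self.area_excluded_ids
            or self.negative_ids & self.area_excluded_ids
        ):
            raise ValueError("positive/negative/excluded sets must be disjoint")

    @property
    def n_positive(self) -> int:
        return len(self.positive_ids)

    @property
    def n_negative(self) -> int:
        return len(self.negative_ids)

    @property
    def n_area_excluded(self) -> int:
        return len(self.area_excluded_ids)

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative + self.n_area_excluded


@dataclass(frozen=True)
class SubRegion:
    """A named simple polygon, vertices as ordered (y, x) pixel coordinates."""

    name: str
    polygon: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError(f"region {self.name!r}: polygon needs >= 3 vertices")
        if not self.shape.is_valid:
            raise ValueError(f"region {self.name!r}: polygon is self-intersecting")

    @property
    def shape(self) -> Polygon:
        return Polygon([(x, y) for y, x in self.polygon])


def classify_cells(
    cells: Sequence[CellRecord],
    cutoff: Optional[float],
    bounds: Optional[co.AreaBounds] = None,
    mode: Mode = "auto",
    image_name: str = "",
) -> CountResult:
    """Partition cells: area filter first, then the intensity cutoff.

    A cell whose mean intensity equals the cutoff exactly counts as positive
    (>=), so boundary cells are never silently dropped. ``cutoff=None`` is
    all-cells mode: every in-bounds cell is positive.
    """
    positive, negative, excluded = set(), set(), set()
    for c in cells:
        if bounds is not None and not bounds.contains(c.area):
            excluded.add(c.label_id)
        elif cutoff is None or c.mean_intensity >= cutoff:
            positive.add(c.label_id)
        else:
            negative.add(c.label_id)
    return CountResult(
        image_name=image_name,
        positive_ids=frozenset(positive),
        negative_ids=frozenset(negative),
        area_excluded_ids=frozenset(excluded),
        cutoff_used=cutoff,
        area_bounds=bounds,
        mode=mode,
    )


@dataclass(frozen=True)
class RegionCounts:
    n_positive: int
    n_negative: int


OUTSIDE_REGION = "outside"


def count_in_regions(
    result: CountResult,
    cells: Sequence[CellRecord],
    regions: Sequence[SubRegion],
) -> Dict[str, RegionCounts]:
    """Count positives/negatives per sub-region by centroid membership.

    A cell belongs to the first listed region whose polygon covers its
    centroid (boundary counts as inside); cells in no region are tallied
    under the reserved name "outside". A centroid on a shared edge therefore
    goes to the earlier region, which is logged.
    """
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    if OUTSIDE_REGION in names:
        raise ValueError(f"region name {OUTSIDE_REGION!r} is reserved")
    shapes = [r.shape for r in regions]
    pos: Dict[str, int] = {n: 0 for n in names + [OUTSIDE_REGION]}
    neg: Dict[str, int] = {n: 0 for n in names + [OUTSIDE_REGION]}
    for c in cells:
        if c.label_id in result.area_excluded_ids:
            continue
        pt = Point(c.centroid[1], c.centroid[0])
        hits = [n for n, s in zip(names, shapes) if s.covers(pt)]
        if len(hits) > 1:
            logger.info(
                "cell %d centroid on shared boundary of %s; assigned to %r",
                c.label_id, hits, hits[0],
            )
        target = hits[0] if hits else OUTSIDE_REGION
        if c.label_id in result.positive_ids:
            pos[target] += 1
        else:
            neg[target] += 1
    return {n: RegionCounts(pos[n], neg[n]) for n in names + [OUTSIDE_REGION]}


@dataclass
class RunConfig:
    """Everything one counting run needs; echoed verbatim into the Log."""

    input_dir: Path
    output_dir: Path
    detector: Detector = "builtin"
    mode: Mode = "auto"
    batch: bool = True
    optimization_steps: int = 1
    sigma: float = 2.0
    sigma_source: co.SigmaSource = "within_cell"
    size_cutoff: Optional[float] = None
    connectivity: int = 8
    exclude_border: bool = False
    labels_dir: Optional[Path] = None
    probmap_dir: Optional[Path] = None
    manual_thresholds: Dict[str, float] = field(default_factory=dict)
    regions: List[SubRegion] = field(default_factory=list)
    area_bounds: Optional[co.AreaBounds] = None  # manual override of the filter
    smoothing_radius: float = 2.0
    min_distance: int = 5
    intensity_weighted_centroid: bool = False
    per_image_sigma: Dict[str, float] = field(default_factory=dict)

    def validate(self, n_images: int) -> None:
        if n_images == 0:
            raise ValueError("input_dir: no TIFF images found")
        if self.mode == "allcells":
            if self.size_cutoff is None:
                raise ValueError("size_cutoff: required in allcells mode")
            if not self.batch:
                raise ValueError("batch: allcells mode requires batch analysis")
        elif self.batch and not 1 <= self.optimization_steps <= n_images:
            raise ValueError(
                f"optimization_steps: {self.optimization_steps} not in "
                f"[1, {n_images}] (number of input images)"
            )
        if self.detector == "labels" and self.labels_dir is None:
            raise ValueError("labels_dir: required with the labels detector")
        if self.detector == "probmap" and self.probmap_dir is None:
            raise ValueError("probmap_dir: required with the probmap detector")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity: must be 4 or 8")
        if self.sigma <= 0:
            raise ValueError("sigma: must be > 0")


@dataclass
class ImageAnalysis:
    """Per-image intermediate products kept for output writing."""

    name: str
    raw: Image2D
    labels: LabelImage
    cells: List[CellRecord]
    cutoff_result: Optional[co.CutoffResult] = None
    count: Optional[CountResult] = None
    region_counts: Optional[Dict[str, RegionCounts]] = None


@dataclass
class PipelineResult:
    """The full outcome of one run: per-image results plus the Log lines."""

    config: RunConfig
    images: List[ImageAnalysis]
    ic_a: Optional[float]
    log_lines: List[str]

    @property
    def counts(self) -> List[CountResult]:
        return [im.count for im in self.images if im.count is not None]


def list_input_images(input_dir: Path) -> List[Path]:
    """TIFFs in lexicographic filename order — the optimization-set order."""
    paths = [
        p
        for p in sorted(input_dir.iterdir())
        if p.suffix.lower() in (".tif", ".tiff") and p.is_file()
    ]
    return paths


def _matching_file(directory: Path, stem: str) -> Path:
    for suffix in (".tif", ".tiff"):
        p = directory / f"{stem}{suffix}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no TIFF for image {stem!r} in {directory}")


def _segment_one(path: Path, config: RunConfig) -> ImageAnalysis:
    raw = max_intensity_projection(read_image(path))
    if config.detector == "labels":
        labels = ingest_label_image(_matching_file(config.labels_dir, path.stem), raw)
    elif config.detector == "probmap":
        prob = load_plane(_matching_file(config.probmap_dir, path.stem))
        labels = segment_probability_map(prob, raw, connectivity=config.connectivity)
    else:
        labels = builtin_segment(
            raw,
            smoothing_radius=config.smoothing_radius,
            min_distance=config.min_distance,
            connectivity=config.connectivity,
        )
    if config.exclude_border:
        labels = remove_border_labels(labels)
    cells = extract_cell_records(
        labels, raw, intensity_weighted_centroid=config.intensity_weighted_centroid
    )
    return ImageAnalysis(name=path.stem, raw=raw, labels=labels, cells=cells)


def _image_sigma(config: RunConfig, name: str) -> float:
    return config.per_image_sigma.get(name, config.sigma)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a full counting run and return every per-image result.

    Batch mode freezes one cutoff (IcA) and one area window, estimated on the
    first f images, and applies them to all images; non-batch mode estimates
    both per image (per-image sigma overrides allowed). The manual mode reads
    user-chosen thresholds keyed by image stem; all-cells mode skips the
    intensity cutoff entirely and applies only the [cutoff, 5×cutoff] size
    window.
    """
    paths = list_input_images(Path(config.input_dir))
    config.validate(len(paths))
    log: List[str] = [
        f"mode = {config.mode}",
        f"batch = {config.batch}",
        f"detector = {config.detector}",
        f"sigma (S) = {config.sigma}",
        f"sigma_source = {config.sigma_source}",
        f"optimization_steps (f) = {config.optimization_steps}",
        f"size_cutoff = {config.size_cutoff}",
        f"connectivity = {config.connectivity}",
        f"exclude_border = {config.exclude_border}",
        f"images = {len(paths)}",
    ]

    images = [_segment_one(p, config) for p in paths]
    ic_a: Optional[float] = None

    if config.mode == "allcells":
        bounds = co.allcells_area_bounds(config.size_cutoff)
        log.append(f"area_bounds = [{bounds.lo}, {bounds.hi}] (rule {bounds.rule})")
        for im in images:
            im.count = classify_cells(
                im.cells, None, bounds, mode="allcells", image_name=im.name
            )
    elif config.batch:
        opt = images[: config.optimization_steps]
        if config.mode == "auto":
            for im in opt:
                im.cutoff_result = co.image_cutoff(
                    im.cells, _image_sigma(config, im.name), config.sigma_source
                )
                log.append(f"IcS[{im.name}] = {im.cutoff_result.ic_s!r}")
            applied = co.batch_cutoff([im.cutoff_result for im in opt]).ic_a
            ic_a = applied
            log.append(f"IcA = {ic_a!r}")
        else:  # manual
            values = []
            for im in opt:
                if im.name not in config.manual_thresholds:
                    raise ValueError(f"manual_thresholds: missing value for {im.name!r}")
                values.append(config.manual_thresholds[im.name])
                log.append(f"manual threshold[{im.name}] = {values[-1]!r}")
            applied = co.manual_cutoff(values, bit_depth=opt[0].raw.bit_depth)
            ic_a = applied
            log.append(f"IcA = {ic_a!r}")
        bounds = config.area_bounds
        if bounds is None and config.mode == "auto":
            pooled = [c for im in opt for c in im.cells]
            bounds = co.auto_area_bounds(pooled)
        if bounds is not None:
            log.append(f"area_bounds = [{bounds.lo!r}, {bounds.hi!r}] (rule {bounds.rule})")
        else:
            log.append("area_bounds = none")
        for im in images:
            im.count = classify_cells(
                im.cells, applied, bounds, mode=config.mode, image_name=im.name
            )
    else:  # non-batch: per-image cutoff and bounds
        for im in images:
            if config.mode == "auto":
                im.cutoff_result = co.image_cutoff(
                    im.cells, _image_sigma(config, im.name), config.sigma_source
                )
                applied = im.cutoff_result.ic_s
                log.append(f"IcS[{im.name}] = {applied!r}")
            else:  # manual, one user value per image
                if im.name not in config.manual_thresholds:
                    raise ValueError(f"manual_thresholds: missing value for {im.name!r}")
                applied = config.manual_thresholds[im.name]
                log.append(f"manual threshold[{im.name}] = {applied!r}")
            bounds = config.area_bounds
            if bounds is None and config.mode == "auto":
                bounds = co.auto_area_bounds(im.cells)
            im.count = classify_cells(
                im.cells, applied, bounds, mode=config.mode, image_name=im.name
            )

    if config.regions:
        log.append(f"sub_regions = {[r.name for r in config.regions]}")
        if config.batch:
            log.append(
                "note: sub-region counting in batch mode extends the original "
                "non-batch-only behavior"
            )
        for im in images:
            im.region_counts = count_in_regions(im.count, im.cells, config.regions)

    for im in images:  # partition invariant, asserted on every run
        assert im.count.n_total == len(im.cells)
    return PipelineResult(config=config, images=images, ic_a=ic_a, log_lines=log)


def preview_cutoffs(config: RunConfig) -> List[Tuple[str, co.CutoffResult, Optional[co.AreaBounds]]]:
    """Dry-run: the per-image IcS and area bounds for the first f images.

    Nothing is written; the same values appear in a subsequent counting run's
    Log. Also serves as the suggested defaults for manual optimization.
    """
    paths = list_input_images(Path(config.input_dir))
    config.validate(len(paths))
    f = config.optimization_steps if config.batch else len(paths)
    out = []
    for p in paths[:f]:
        im = _segment_one(p, config)
        res = co.image_cutoff(im.cells, _image_sigma(config, im.name), config.sigma_source)
        bounds = config.area_bounds or co.auto_area_bounds(im.cells)
        out.append((im.name, res, bounds))
    return out
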