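"""The z-score intensity cutoff separating marker-positive from negative cells.

Given per-cell mean intensities x_i, the cohort statistics are

    mu    = mean over cells of x_i
    sigma = mean over cells of the per-cell intensity SD   (default), or
            the sample SD across the x_i themselves        (``across_cells``)

and each cell's z-score is Z_i = (x_i − mu) / sigma. Cells inside the
two-sided range |Z_i| <= S — the "typical" cells, with outliers in either
tail excluded — have their mean intensities averaged to give the per-image
cutoff IcS. In batch mode the cutoffs of the first f ("optimization step")
images are averaged into IcA, which is then frozen and applied to every
remaining image. Cells at or above the cutoff are counted positive.

The within-cell sigma reading follows the method's printed definition; it can
make every |Z_i| exceed a small S when populations are widely separated, so
the across-cells alternative is offered as a configuration choice and the
active one is always written to the Log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Literal, Optional, Sequence

import numpy as np

from .segment import CellRecord

SigmaSource = Literal["within_cell", "across_cells"]


class NoCellsError(ValueError):
    """No cells segmented: cohort statistics are undefined."""


class SigmaTooSmallError(ValueError):
    """No cell falls inside |Z| <= S; carries the smallest |Z| observed."""

    def __init__(self, min_abs_z: float) -> None:
        self.min_abs_z = min_abs_z
        super().__init__(
            f"no cell satisfies |Z| <= S; smallest |Z| is {min_abs_z:.4g} — "
            "widen the sigma range"
        )


class DegenerateCohortError(ValueError):
    """sigma = 0: z-scores are undefined for this cohort."""


@dataclass(frozen=True)
class CohortStats:
    """mu and sigma of one image's (or cohort's) cells."""

    mu: float
    sigma_cell: float
    n_cells: int


@dataclass(frozen=True)
class CutoffResult:
    """Per-image cutoff IcS with the included-cell set that produced it."""

    ic_s: float
    sigma_range: float
    included_ids: FrozenSet[int]
    n_included: int
    zscores: Dict[int, float]


@dataclass(frozen=True)
class BatchCutoff:
    """IcA: the mean of IcS over the f optimization images."""

    ic_a: float
    per_image: List[CutoffResult]
    f: int


@dataclass(frozen=True)
class AreaBounds:
    """Inclusive pixel-area window [lo, hi] for cell-size filtering."""

    lo: float
    hi: float
    rule: Literal["auto_2sd", "manual", "allcells_5x"]

    def __post_init__(self) -> None:
        if not 0 <= self.lo <= self.hi:
            raise ValueError("require 0 <= lo <= hi")

    def contains(self, area: float) -> bool:
        return self.lo <= area <= self.hi


def cohort_stats(
    cells: Sequence[CellRecord], sigma_source: SigmaSource = "within_cell"
) -> CohortStats:
    """mu = mean of per-cell means; sigma per the chosen source."""
    if len(cells) == 0:
        raise NoCellsError("no cells segmented")
    means = np.array([c.mean_intensity for c in cells], dtype=np.float64)
    if sigma_source == "within_cell":
        sigma = float(np.mean([c.sd_intensity for c in cells]))
    elif sigma_source == "across_cells":
        sigma = float(means.std(ddof=1)) if len(cells) > 1 else 0.0
    else:
        raise ValueError(f"unknown sigma_source {sigma_source!r}")
    return CohortStats(mu=float(means.mean()), sigma_cell=sigma, n_cells=len(cells))


def zscore(cell: CellRecord, stats: CohortStats) -> float:
    """Z_i = (x_i − mu) / sigma."""
    if stats.sigma_cell <= 0:
        raise DegenerateCohortError("sigma = 0: z-score undefined")
    return (cell.mean_intensity - stats.mu) / stats.sigma_cell


def image_cutoff(
    cells: Sequence[CellRecord],
    sigma_range: float = 2.0,
    sigma_source: SigmaSource = "within_cell",
) -> CutoffResult:
    """Compute IcS: the mean intensity of cells with |Z_i| <= S (inclusive).

    A degenerate cohort (sigma = 0, e.g. all cells identical) includes every
    cell, so IcS = mu — continuous with the S → ∞ limit.
    """
    if sigma_range <= 0:
        raise ValueError("sigma_range must be > 0")
    stats = cohort_stats(cells, sigma_source)
    means = np.array([c.mean_intensity for c in cells], dtype=np.float64)
    ids = [c.label_id for c in cells]
    if stats.sigma_cell <= 0:
        zs = {i: 0.0 for i in ids}
        return CutoffResult(
            ic_s=stats.mu,
            sigma_range=sigma_range,
            included_ids=frozenset(ids),
            n_included=len(ids),
            zscores=zs,
        )
    z = (means - stats.mu) / stats.sigma_cell
    inside = np.abs(z) <= sigma_range
    if not inside.any():
        raise SigmaTooSmallError(float(np.abs(z).min()))
    included = frozenset(i for i, keep in zip(ids, inside) if keep)
    return CutoffResult(
        ic_s=float(means[inside].mean()),
        sigma_range=sigma_range,
        included_ids=included,
        n_included=int(inside.sum()),
        zscores={i: float(zi) for i, zi in zip(ids, z)},
    )


def batch_cutoff(results: Sequence[CutoffResult]) -> BatchCutoff:
    """IcA = unweighted mean of the per-image IcS values."""
    if len(results) == 0:
        raise ValueError("no per-image cutoffs to average")
    ic_a = float(np.mean([r.ic_s for r in results]))
    return BatchCutoff(ic_a=ic_a, per_image=list(results), f=len(results))


def manual_cutoff(
    user_values: Sequence[float], bit_depth: Optional[int] = None
) -> float:
    """Average the user-chosen per-image thresholds into one cutoff.

    The suggested default shown per image is that image's automated IcS;
    here only the user's final choices are combined.
    """
    if len(user_values) == 0:
        raise ValueError("no manual threshold values given")
    if bit_depth is not None:
        hi = 2**bit_depth - 1
        for v in user_values:
            if not 0 <= v <= hi:
                raise ValueError(f"threshold {v} outside dynamic range [0, {hi}]")
    return float(np.mean(user_values))


def auto_area_bounds(cells: Sequence[CellRecord]) -> Optional[AreaBounds]:
    """Area window mean ± 2·SD (sample SD) of the cell areas.

    With fewer than two cells the SD is undefined; the filter is disabled
    (returns None) with a warning rather than guessing a window.
    """
    if len(cells) < 2:
        warnings.warn(
            "fewer than 2 cells: area bounds undefined, no area filter applied",
            stacklevel=2,
        )
        return None
    areas = np.array([c.area for c in cells], dtype=np.float64)
    mean, sd = float(areas.mean()), float(areas.std(ddof=1))
    return AreaBounds(lo=max(0.0, mean - 2 * sd), hi=mean + 2 * sd, rule="auto_2sd")


def allcells_area_bounds(size_cutoff: float) -> AreaBounds:
    """All-cells-mode size filter: keep areas in [cutoff, 5 × cutoff]."""
    if size_cutoff <= 0:
        raise ValueError("size_cutoff must be > 0")
    return AreaBounds(lo=float(size_cutoff), hi=5.0 * size_cutoff, rule="allcells_5x")
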