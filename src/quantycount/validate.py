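"""Manual-vs-automated count comparison.

Automated per-image positive-cell counts are compared with counts from human
annotators over the same image series: each series is standardized to
z-scores, image pairs where either series exceeds the chosen SD range
(default 2) are flagged as outliers, Pearson's r is computed over the
retained pairs, and each raw series' least-squares slope against image index
(its "counting slope") is reported. Agreement between the automated slope
and the average-manual slope, together with a strong correlation inside the
two-SD range, is the validation criterion for the automated cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd


class ConstantSeriesError(ValueError):
    """A count series with zero variance: correlation is undefined."""


@dataclass(frozen=True)
class CountSeries:
    """Per-image positive-cell counts from one source (tool or annotator)."""

    names: tuple
    counts: np.ndarray
    source: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if len(self.names) != counts.size:
            raise ValueError("names and counts lengths differ")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(float))

    @classmethod
    def from_csv(cls, path: str | Path, source: str | None = None) -> "CountSeries":
        """Read an (image, n_positive) CSV as written by annotation tools."""
        df = pd.read_csv(path, comment="#")
        if not {"image", "n_positive"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns image, n_positive")
        return cls(
            names=tuple(df["image"].astype(str)),
            counts=df["n_positive"].to_numpy(),
            source=source or Path(path).stem,
        )


@dataclass(frozen=True)
class CorrelationReport:
    pearson_r: float
    slope_a: float
    slope_b: float
    outlier_flags: np.ndarray  # True where a pair was excluded
    n_retained: int
    source_a: str
    source_b: str


def _standardize(counts: np.ndarray, label: str) -> np.ndarray:
    sd = counts.std(ddof=1)
    if sd == 0:
        raise ConstantSeriesError(f"series {label!r} is constant")
    return (counts - counts.mean()) / sd


def _slope(counts: np.ndarray) -> float:
    idx = np.arange(counts.size, dtype=float)
    return float(np.polyfit(idx, counts, 1)[0])


def zscore_correlation(
    a: CountSeries, b: CountSeries, sd_range: float = 2.0
) -> CorrelationReport:
    """Pearson correlation on z-standardized counts with outlier exclusion.

    Pairs where either series' |z| exceeds ``sd_range`` are flagged and
    excluded from r; slopes are fit on the full raw series. Flagging is
    symmetric in the two series.
    """
    if a.names != b.names:
        raise ValueError("series are not aligned on the same images")
    if len(a.names) < 3:
        raise ValueError("need >= 3 paired images")
    za = _standardize(a.counts, a.source)
    zb = _standardize(b.counts, b.source)
    flags = (np.abs(za) > sd_range) | (np.abs(zb) > sd_range)
    keep = ~flags
    if keep.sum() < 2:
        raise ValueError("fewer than 2 pairs inside the SD range")
    ra, rb = a.counts[keep], b.counts[keep]
    if ra.std() == 0 or rb.std() == 0:
        raise ConstantSeriesError("retained pairs are constant in one series")
    r = float(np.corrcoef(ra, rb)[0, 1])
    return CorrelationReport(
        pearson_r=r,
        slope_a=_slope(a.counts),
        slope_b=_slope(b.counts),
        outlier_flags=flags,
        n_retained=int(keep.sum()),
        source_a=a.source,
        source_b=b.source,
    )


@dataclass(frozen=True)
class ManualComparisonReport:
    correlation: CorrelationReport  # automated vs. manual average
    table: pd.DataFrame  # image x source absolute counts
    per_annotator_r: pd.Series  # each annotator vs. automated


def average_series(series: Sequence[CountSeries], source: str = "manual_average") -> CountSeries:
    names = series[0].names
    for s in series[1:]:
        if s.names != names:
            raise ValueError("manual series are not aligned on the same images")
    counts = np.mean([s.counts for s in series], axis=0)
    return CountSeries(names=names, counts=counts, source=source)


def compare_to_manual(
    automated: CountSeries,
    manual: Sequence[CountSeries],
    sd_range: float = 2.0,
) -> ManualComparisonReport:
    """Compare automated counts with one or more manual annotators.

    The manual series are averaged per image; the automated series is then
    correlated against that average within the SD range, and the per-source
    absolute counts are tabulated for inspection.
    """
    if len(manual) == 0:
        raise ValueError("need at least one manual series")
    avg = average_series(manual)
    report = zscore_correlation(automated, avg, sd_range=sd_range)
    table = pd.DataFrame(
        {automated.source: automated.counts,
         **{m.source: m.counts for m in manual},
         avg.source: avg.counts},
        index=pd.Index(automated.names, name="image"),
    )
    per_r = pd.Series(
        {
            m.source: zscore_correlation(automated, m, sd_range=sd_range).pearson_r
            for m in manual
        },
        name="pearson_r_vs_automated",
    )
    return ManualComparisonReport(correlation=report, table=table, per_annotator_r=per_r)


def plot_comparison(report: ManualComparisonReport, path: str | Path) -> None:
    """Save a per-image count plot (automated vs. annotators and average)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for column in report.table.columns:
        style = "-o" if column in (report.correlation.source_a,) else "--"
        ax.plot(report.table[column].to_numpy(), style, label=column, alpha=0.8)
    ax.set_xlabel("image index")
    ax.set_ylabel("positive cells")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
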