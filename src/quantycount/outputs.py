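"""Write the structured output bundle of a counting run.

Layout (root output directory):

    <root>/
      <image stem>/
        positive_labels.tif   # label image restricted to positive cells
        negative_labels.tif   # label image restricted to negative cells
        cells.csv             # per-cell class, centroid, area, intensities
      Summary.csv             # one row per processed image
      Regions.csv             # per-region counts (only when regions given)
      Log.txt                 # every applied parameter, per-image cutoffs, IcA

All CSVs are comma-separated UTF-8 with a header row and "." decimals, and
carry a comment line stating that coordinates are 0-based (row=y, col=x).
Label TIFFs are 16-bit and keep the original label ids, so centroids can be
recomputed from them and checked against cells.csv.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .count import CountResult, ImageAnalysis, PipelineResult, RegionCounts
from .segment import CellRecord, LabelImage

COORD_COMMENT = "# coordinates are 0-based pixel indices, row=y, col=x\n"

SUMMARY_COLUMNS = [
    "image", "mode", "cutoff", "sigma", "area_lo", "area_hi",
    "n_total", "n_positive", "n_negative", "n_area_excluded",
]

CELL_COLUMNS = ["label_id", "class", "y", "x", "area", "mean_intensity", "sd_intensity"]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(COORD_COMMENT)
        df.to_csv(fh, index=False)


def _class_label_image(labels: LabelImage, keep_ids: Sequence[int]) -> np.ndarray:
    out = np.where(np.isin(labels.labels, list(keep_ids)), labels.labels, 0)
    return out.astype(np.uint16)


def write_image_outputs(
    result: CountResult,
    labels: LabelImage,
    cells: Sequence[CellRecord],
    subdir: Path,
) -> None:
    """Write one image's positive/negative label TIFFs and cells.csv.

    cells.csv lists every segmented cell with its class (positive, negative
    or area_excluded), ordered by label id, so the full classification can be
    reconstructed from the bundle alone.
    """
    subdir = Path(subdir)
    subdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        subdir / "positive_labels.tif", _class_label_image(labels, result.positive_ids)
    )
    tifffile.imwrite(
        subdir / "negative_labels.tif", _class_label_image(labels, result.negative_ids)
    )
    rows = []
    for c in cells:
        if c.label_id in result.positive_ids:
            klass = "positive"
        elif c.label_id in result.negative_ids:
            klass = "negative"
        else:
            klass = "area_excluded"
        rows.append(
            {
                "label_id": c.label_id,
                "class": klass,
                "y": c.centroid[0],
                "x": c.centroid[1],
                "area": c.area,
                "mean_intensity": c.mean_intensity,
                "sd_intensity": c.sd_intensity,
            }
        )
    df = pd.DataFrame(rows, columns=CELL_COLUMNS)
    _write_csv(df, subdir / "cells.csv")


def summary_frame(results: Sequence[CountResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        bounds = r.area_bounds
        rows.append(
            {
                "image": r.image_name,
                "mode": r.mode,
                "cutoff": r.cutoff_used if r.cutoff_used is not None else "",
                "sigma": "",
                "area_lo": bounds.lo if bounds else "",
                "area_hi": bounds.hi if bounds else "",
                "n_total": r.n_total,
                "n_positive": r.n_positive,
                "n_negative": r.n_negative,
                "n_area_excluded": r.n_area_excluded,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary_and_log(
    results: Sequence[CountResult],
    log_lines: Sequence[str],
    root: Path,
    sigma: float,
) -> None:
    """Write Summary.csv and Log.txt at the bundle root.

    Summary.csv is deterministic for a fixed config and inputs; the Log's
    first line is a timestamp, everything below it is reproducible.
    """
    if len(results) == 0:
        raise ValueError("no results to summarize")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    df = summary_frame(results)
    df["sigma"] = sigma
    _write_csv(df, root / "Summary.csv")
    with open(root / "Log.txt", "w", encoding="utf-8") as fh:
        fh.write(f"# timestamp: {_dt.datetime.now().isoformat()}\n")
        fh.write(f"quantycount version {__version__}\n")
        for line in log_lines:
            fh.write(line + "\n")


def write_region_counts(
    per_image: Dict[str, Dict[str, RegionCounts]], root: Path
) -> None:
    rows = [
        {"image": image, "region": region, "n_positive": rc.n_positive,
         "n_negative": rc.n_negative}
        for image, regions in per_image.items()
        for region, rc in regions.items()
    ]
    df = pd.DataFrame(rows, columns=["image", "region", "n_positive", "n_negative"])
    _write_csv(df, Path(root) / "Regions.csv")


def write_bundle(result: PipelineResult, root: str | Path) -> Path:
    """Write the complete output bundle for a pipeline run; returns the root."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for im in result.images:
        write_image_outputs(im.count, im.labels, im.cells, root / im.name)
    write_summary_and_log(
        result.counts, result.log_lines, root, sigma=result.config.sigma
    )
    region_tables = {
        im.name: im.region_counts for im in result.images if im.region_counts
    }
    if region_tables:
        write_region_counts(region_tables, root)
    return root


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    """Parse a cells.csv written by :func:`write_image_outputs`."""
    return pd.read_csv(path, comment="#")


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    """Parse a Summary.csv written by :func:`write_summary_and_log`."""
    return pd.read_csv(path, comment="#")
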