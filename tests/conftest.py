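from typing import List, Sequence

import numpy as np
import pytest

from quantycount.segment import CellRecord
from quantycount.synthetic import SynthConfig


def make_cells(
    means: Sequence[float],
    sds: Sequence[float] | float = 20.0,
    areas: Sequence[int] | int = 100,
) -> List[CellRecord]:
    """Build cell records directly, bypassing segmentation."""
    n = len(means)
    if np.isscalar(sds):
        sds = [float(sds)] * n
    if np.isscalar(areas):
        areas = [int(areas)] * n
    return [
        CellRecord(
            label_id=i + 1,
            mean_intensity=float(m),
            sd_intensity=float(s),
            area=int(a),
            centroid=(float(i), float(i)),
        )
        for i, (m, s, a) in enumerate(zip(means, sds, areas))
    ]


def random_cell_table(rng: np.random.Generator, n: int | None = None) -> List[CellRecord]:
    n = n or int(rng.integers(2, 51))
    means = rng.uniform(5, 250, size=n)
    sds = rng.uniform(0.5, 40, size=n)
    areas = rng.integers(5, 200, size=n)
    return make_cells(means, sds, areas)


@pytest.fixture
def four_cell_table() -> List[CellRecord]:
    """The worked micro-example: means 100/110/120/250, per-cell SD 20."""
    return make_cells([100, 110, 120, 250], 20.0, 100)


@pytest.fixture
def clean_synth_config() -> SynthConfig:
    """Noise-free field with both populations well above background, so the
    built-in segmenter can recover every generated cell exactly."""
    return SynthConfig(
        image_shape=(256, 256),
        n_positive=10,
        n_negative=10,
        neg_intensity_mean=120.0,
        pos_intensity_mean=200.0,
        pos_intensity_sd=0.0,
        neg_intensity_sd=0.0,
        background_mean=5.0,
        background_sd=0.0,
        within_cell_sd=0.0,
        drift_sd=0.0,
        radius_range=(4, 5),
        min_center_distance=16.0,
        seed=0,
    )


# --- independent oracles (deliberately naive; used across test modules) ---


def brute_force_image_cutoff(cells, sigma_range):
    """Explicit-loop reimplementation of the z-range cutoff."""
    mu = sum(c.mean_intensity for c in cells) / len(cells)
    sigma = sum(c.sd_intensity for c in cells) / len(cells)
    if sigma == 0:
        return mu, {c.label_id for c in cells}
    included = []
    for c in cells:
        z = (c.mean_intensity - mu) / sigma
        if abs(z) <= sigma_range:
            included.append(c)
    if not included:
        raise ValueError("no cell inside the range")
    ic = sum(c.mean_intensity for c in included) / len(included)
    return ic, {c.label_id for c in included}


def intermeans_fixed_points(pixels: np.ndarray) -> set[int]:
    """All integer t in [min, max-1] with t == floor((mean<=t + mean>t)/2)."""
    values = np.asarray(pixels).ravel()
    out = set()
    for t in range(int(values.min()), int(values.max())):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size and hi.size and int(np.floor((lo.mean() + hi.mean()) / 2)) == t:
            out.add(t)
    return out
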