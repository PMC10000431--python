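from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest
import tifffile

from quantycount.count import (
    OUTSIDE_REGION,
    RunConfig,
    SubRegion,
    classify_cells,
    count_in_regions,
    preview_cutoffs,
    run_pipeline,
)
from quantycount.cutoff import AreaBounds
from quantycount.synthetic import SynthConfig, generate_cohort

from conftest import make_cells


def write_synth_inputs(root: Path, config: SynthConfig, n_images: int):
    """Materialize a synthetic cohort as raw + true-label TIFF directories."""
    input_dir, labels_dir = root / "raw", root / "labels"
    input_dir.mkdir()
    labels_dir.mkdir()
    truths = {}
    for image, truth, labels in generate_cohort(config, n_images):
        tifffile.imwrite(input_dir / f"{image.name}.tif", image.pixels)
        tifffile.imwrite(labels_dir / f"{image.name}.tif",
                         labels.labels.astype(np.uint16))
        truths[image.name] = truth
    return input_dir, labels_dir, truths


SEPARATED = SynthConfig(
    image_shape=(256, 256),
    n_positive=15,
    n_negative=15,
    neg_intensity_mean=2000.0,
    pos_intensity_mean=8000.0,
    pos_intensity_sd=50.0,
    neg_intensity_sd=50.0,
    background_mean=500.0,
    background_sd=30.0,
    within_cell_sd=50.0,
    drift_sd=40.0,
    bit_depth=16,
    seed=0,
)


class TestClassifyCells:
    def test_partition_at_worked_cutoff(self, four_cell_table):
        res = classify_cells(four_cell_table, cutoff=115.0)
        assert res.positive_ids == frozenset({3, 4})  # means 120 and 250
        assert res.negative_ids == frozenset({1, 2})
        assert res.n_total == 4

    def test_zero_cutoff_makes_everything_positive(self, four_cell_table):
        res = classify_cells(four_cell_table, cutoff=0.0)
        assert res.n_positive == 4 and res.n_negative == 0

    def test_boundary_cell_counts_positive(self):
        res = classify_cells(make_cells([115.0]), cutoff=115.0)
        assert res.n_positive == 1

    def test_area_excluded_cells_in_neither_count(self):
        cells = make_cells([100, 200], areas=[3, 50])
        bounds = AreaBounds(lo=10, hi=100, rule="manual")
        res = classify_cells(cells, cutoff=150.0, bounds=bounds)
        assert res.area_excluded_ids == frozenset({1})
        assert res.n_positive == 1 and res.n_negative == 0

    def test_allcells_mode_counts_all_in_bounds_positive(self):
        cells = make_cells([10, 20, 30], areas=[5, 20, 120])
        bounds = AreaBounds(lo=10, hi=100, rule="allcells_5x")
        res = classify_cells(cells, cutoff=None, bounds=bounds, mode="allcells")
        assert res.n_positive == 1 and res.n_negative == 0
        assert res.area_excluded_ids == frozenset({1, 3})

    def test_empty_input_gives_zero_counts(self):
        res = classify_cells([], cutoff=100.0)
        assert res.n_total == 0


SQUARE_LEFT = SubRegion("left", ((0, 0), (0, 50), (100, 50), (100, 0)))
SQUARE_RIGHT = SubRegion("right", ((0, 50), (0, 100), (100, 100), (100, 50)))


class TestCountInRegions:
    def _cells_and_result(self):
        cells = make_cells([200, 200, 50, 50])
        # centroids at x = 0..3 (from make_cells), all in "left"
        res = classify_cells(cells, cutoff=100.0)
        return cells, res

    def test_whole_image_region_matches_image_counts(self):
        cells, res = self._cells_and_result()
        whole = SubRegion("all", ((0, 0), (0, 100), (100, 100), (100, 0)))
        counts = count_in_regions(res, cells, [whole])
        assert counts["all"].n_positive == res.n_positive
        assert counts["all"].n_negative == res.n_negative
        assert counts[OUTSIDE_REGION].n_positive == 0

    def test_disjoint_tiling_sums_to_image_counts(self):
        rng = np.random.default_rng(5)
        means = rng.uniform(10, 250, 30)
        cells = [
            replace_centroid(c, (float(rng.uniform(0, 100)), float(rng.uniform(0, 100))))
            for c in make_cells(means)
        ]
        res = classify_cells(cells, cutoff=120.0)
        counts = count_in_regions(res, cells, [SQUARE_LEFT, SQUARE_RIGHT])
        assert (
            counts["left"].n_positive
            + counts["right"].n_positive
            + counts[OUTSIDE_REGION].n_positive
            == res.n_positive
        )
        assert (
            counts["left"].n_negative
            + counts["right"].n_negative
            + counts[OUTSIDE_REGION].n_negative
            == res.n_negative
        )

    def test_shared_edge_assigned_to_first_listed_region(self):
        cells = [replace_centroid(make_cells([200])[0], (50.0, 50.0))]
        res = classify_cells(cells, cutoff=100.0)
        counts = count_in_regions(res, cells, [SQUARE_LEFT, SQUARE_RIGHT])
        assert counts["left"].n_positive == 1
        assert counts["right"].n_positive == 0
        flipped = count_in_regions(res, cells, [SQUARE_RIGHT, SQUARE_LEFT])
        assert flipped["right"].n_positive == 1

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            SubRegion("bowtie", ((0, 0), (10, 10), (0, 10), (10, 0)))

    def test_excluded_cells_not_counted_in_regions(self):
        cells = make_cells([200, 200], areas=[1, 50])
        bounds = AreaBounds(lo=10, hi=100, rule="manual")
        res = classify_cells(cells, cutoff=100.0, bounds=bounds)
        whole = SubRegion("all", ((0, 0), (0, 100), (100, 100), (100, 0)))
        counts = count_in_regions(res, cells, [whole])
        assert counts["all"].n_positive == 1


def replace_centroid(cell, centroid):
    from dataclasses import replace as dc_replace

    return dc_replace(cell, centroid=centroid)


class TestRunPipeline:
    def _config(self, input_dir, labels_dir, tmp_path, **kw):
        base = dict(
            input_dir=input_dir,
            output_dir=tmp_path / "out",
            detector="labels",
            labels_dir=labels_dir,
            mode="auto",
            batch=True,
            optimization_steps=2,
            sigma=2.0,
            sigma_source="across_cells",
        )
        base.update(kw)
        return RunConfig(**base)

    def test_full_optimization_shares_one_cutoff(self, tmp_path):
        input_dir, labels_dir, _ = write_synth_inputs(tmp_path, SEPARATED, 3)
        cfg = self._config(input_dir, labels_dir, tmp_path, optimization_steps=3)
        result = run_pipeline(cfg)
        cutoffs = {c.cutoff_used for c in result.counts}
        assert cutoffs == {result.ic_a}

    def test_counts_frozen_under_permutation_of_later_images(self, tmp_path):
        input_dir, labels_dir, _ = write_synth_inputs(tmp_path, SEPARATED, 5)
        cfg = self._config(input_dir, labels_dir, tmp_path, optimization_steps=2)
        baseline = {c.image_name: (c.n_positive, c.n_negative)
                    for c in run_pipeline(cfg).counts}
        # permute the images after the optimization set by renaming them
        files = sorted(input_dir.glob("*.tif"))
        tail = files[2:]
        tmp = tail[0].read_bytes()
        tail[0].write_bytes(tail[-1].read_bytes())
        tail[-1].write_bytes(tmp)
        lab = sorted(labels_dir.glob("*.tif"))[2:]
        tmp = lab[0].read_bytes()
        lab[0].write_bytes(lab[-1].read_bytes())
        lab[-1].write_bytes(tmp)
        permuted = {c.image_name: (c.n_positive, c.n_negative)
                    for c in run_pipeline(cfg).counts}
        # same multiset of per-image counts, cutoff frozen from first 2 images
        assert sorted(baseline.values()) == sorted(permuted.values())
        swapped = {files[2].stem, files[-1].stem}
        for name in set(baseline) - swapped:
            assert baseline[name] == permuted[name]

    def test_separated_cohort_classification_matches_ground_truth(self, tmp_path):
        input_dir, labels_dir, truths = write_synth_inputs(tmp_path, SEPARATED, 4)
        cfg = self._config(input_dir, labels_dir, tmp_path, optimization_steps=2)
        result = run_pipeline(cfg)
        for im in result.images:
            truth = truths[im.name]
            true_pos = set(truth.loc[truth.true_class == "positive", "cell_id"])
            assert set(im.count.positive_ids) == true_pos

    def test_allcells_mode_ignores_intensity(self, tmp_path):
        input_dir, labels_dir, truths = write_synth_inputs(tmp_path, SEPARATED, 2)
        cfg = self._config(
            input_dir, labels_dir, tmp_path, mode="allcells", size_cutoff=10.0
        )
        result = run_pipeline(cfg)
        for im in result.images:
            assert im.count.n_negative == 0
            assert im.count.n_positive + im.count.n_area_excluded == len(truths[im.name])

    def test_config_validation_errors(self, tmp_path):
        input_dir, labels_dir, _ = write_synth_inputs(tmp_path, SEPARATED, 2)
        with pytest.raises(ValueError, match="optimization_steps"):
            run_pipeline(
                self._config(input_dir, labels_dir, tmp_path, optimization_steps=5)
            )
        with pytest.raises(ValueError, match="size_cutoff"):
            run_pipeline(self._config(input_dir, labels_dir, tmp_path, mode="allcells"))

    def test_preview_matches_pipeline_cutoffs(self, tmp_path):
        input_dir, labels_dir, _ = write_synth_inputs(tmp_path, SEPARATED, 3)
        cfg = self._config(input_dir, labels_dir, tmp_path, optimization_steps=2)
        previews = preview_cutoffs(cfg)
        result = run_pipeline(cfg)
        ics = [im.cutoff_result.ic_s for im in result.images[:2]]
        assert [p[1].ic_s for p in previews] == ics

    def test_partition_invariant_on_every_image(self, tmp_path):
        input_dir, labels_dir, _ = write_synth_inputs(tmp_path, SEPARATED, 3)
        result = run_pipeline(self._config(input_dir, labels_dir, tmp_path))
        for im in result.images:
            ids = {c.label_id for c in im.cells}
            assert (
                im.count.positive_ids | im.count.negative_ids | im.count.area_excluded_ids
                == ids
            )
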