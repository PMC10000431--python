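# quantycount

Unbiased counting of marker-positive cells in 2D fluorescence images.

Quantifying cells that express an activity marker — Fos protein or *c-fos*
mRNA are the canonical cases — is notoriously sensitive to staining batch,
acquisition settings and the person doing the counting: the same tissue
scored by different experimenters can differ substantially in the absolute
number of "positive" cells. `quantycount` replaces the per-image manual
intensity threshold with a **z-score intensity cutoff** estimated from the
data itself, so that the positive/negative decision is reproducible across
images, samples and users.

## The method

Cells are first segmented (from an external label image, a thresholded
pixel-classifier probability map, or a built-in watershed segmenter for
clean fields). For each segmented cell *i* with mean intensity *x*ᵢ, the
cohort statistics are

- μ = mean over cells of *x*ᵢ
- σ = mean over cells of the per-cell intensity SD (or, optionally, the SD
  across the *x*ᵢ)

and each cell's z-score is **Zᵢ = (xᵢ − μ) / σ**. Cells inside the two-sided
range |Zᵢ| ≤ S (default S = 2) — the typical cells, with both tails
excluded — have their mean intensities averaged into the per-image cutoff

**IcS = (1/n) Σ xᵢ over the n cells with |Zᵢ| ≤ S.**

In batch mode the cutoffs of the first *f* "optimization" images (in
lexicographic filename order) are averaged into **IcA = (1/f) Σ IcS**, which
is frozen and applied to every remaining image. A cell at or above the
cutoff is positive, below is negative. An area filter (mean ± 2·SD of cell
areas in automated mode; [c, 5c] around a user size cutoff in all-cells
mode) removes debris and clumps before classification. Counts can be
restricted to named polygonal sub-regions. A manual-optimization mode
averages user-chosen thresholds instead, with the automated IcS offered as
the per-image suggestion.

## Worked example

```python
>>> import quantycount as q
>>> cells = [q.CellRecord(i, m, 20.0, 100, (0.0, 0.0))
...          for i, m in enumerate([100, 110, 120, 250], start=1)]
>>> stats = q.cohort_stats(cells)
>>> (stats.mu, stats.sigma_cell)
(145.0, 20.0)
>>> res = q.image_cutoff(cells, sigma_range=2.0)
>>> res.zscores
{1: -2.25, 2: -1.75, 3: -1.25, 4: 5.25}
>>> res.ic_s
115.0
>>> counted = q.classify_cells(cells, cutoff=res.ic_s)
>>> (counted.n_positive, counted.n_negative)
(2, 2)
```

Four cells with mean intensities 100/110/120/250 and per-cell SD 20 give
μ = 145 and σ = 20. At S = 2 the dimmest cell (Z = −2.25) and the brightest
(Z = 5.25) fall outside the range, so the cutoff is the mean of 110 and
120, i.e. IcS = 115. Applied back to all four cells, the two cells at 120
and 250 count positive and the two at 100 and 110 negative.

From the shell, a full run on a directory of TIFFs looks like:

```
quantycount count --input-dir raw/ --output-dir results/ \
    --detector labels --labels-dir labels/ \
    --optimization-steps 5 --sigma 2 --sigma-source across_cells
```

which writes, per image, `positive_labels.tif`, `negative_labels.tif` and
`cells.csv`, plus a root `Summary.csv` and a `Log.txt` recording every
applied parameter, the per-image IcS values and IcA. `quantycount synth`
generates ground-truthed synthetic test images, `quantycount features`
extracts per-image intensity QC features, `quantycount preview` dry-runs
the cutoff estimation, and `quantycount validate` correlates automated
counts with manual annotator counts inside a two-SD z-score range.

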