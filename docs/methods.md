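# Methods

## Model and procedure

`quantycount` counts marker-positive cells in 2D grayscale images (or
maximum intensity projections of thin z-stacks) in four stages: input
normalization, segmentation, cutoff estimation, classification/counting.

**Input.** Raw images are 8- or 16-bit grayscale TIFFs, one channel per
file; RGB and float inputs are rejected rather than silently converted.
Multi-page stacks are collapsed by per-pixel maximum over z. The MIP is
idempotent and dominates every plane; both properties are tested.

**Segmentation.** Three interchangeable sources produce a label image
(0 = background, 1..L = cells):

1. *External label image* — the output of a dedicated convex-object
   segmenter (e.g. a StarDist nuclei model) run outside this package.
   Labels are renumbered to consecutive 1..L, preserving the pixel
   partition.
2. *Probability map* — a per-pixel foreground probability from a pixel
   classifier (e.g. ilastik), binarized with the iterative intermeans
   auto-threshold and connected-component labeled (4- or 8-connectivity,
   default 8 to match common particle-analysis behavior). Float maps are
   rescaled to 8-bit before histogram thresholding, since the method needs
   discrete bins. Intensity statistics are always measured on the raw
   image, never the map.
3. *Built-in segmenter* — Gaussian smoothing, intermeans threshold,
   distance-transform watershed with a minimum peak separation. This is a
   fixture-grade fallback for clean, convex, well-separated cells (it
   recovers the exact generated cell count on noise-free synthetic fields);
   it is not a substitute for a trained model on real tissue.

The intermeans ("Default") threshold iterates
t ← ⌊(mean(values ≤ t) + mean(values > t)) / 2⌋ from the overall mean.
The update map is monotone non-decreasing on [min, max−1] and maps that
interval into itself, so a fixed point exists and the iteration terminates;
tests check the result against an exhaustive fixed-point scan.

**Per-cell measurement.** For each label: mean raw intensity xᵢ, sample
(n−1) SD of the raw pixels (0 for single-pixel cells), area in pixels, and
the unweighted geometric centroid (an intensity-weighted variant is a flag;
the unweighted form depends only on the segmentation, which makes the
output round-trip exactly reconstructable from the written label images).
Cells touching the image border are kept by default; `--exclude-border`
drops them, mirroring the usual manual-counting convention.

**Cutoff.** With μ = mean of xᵢ and σ as below, Zᵢ = (xᵢ − μ)/σ. Cells in
the two-sided inclusive range |Zᵢ| ≤ S are averaged into the per-image
cutoff IcS; batch mode averages the first f images' IcS into IcA and
freezes it. A cell with xᵢ exactly at the cutoff counts positive. The range
is taken two-sided and inclusive — the standard z-score reading — since
sidedness is genuinely open; one-sided variants would only shift which
outliers are trimmed from the cutoff average.

**σ (`sigma_source`).** The default, `within_cell`, is the mean of the
per-cell intensity SDs — the method's literal definition. On strongly
bimodal cohorts with tight within-cell texture this σ can be so small that
no cell satisfies |Zᵢ| ≤ S (the error then reports the smallest |Zᵢ| so the
user can widen S). `across_cells` — the sample SD of the xᵢ — is offered
for that regime and is what the synthetic-recovery analyses use. The active
choice is always written to the Log. A degenerate cohort (σ = 0) includes
every cell, IcS = μ, keeping continuity with the S → ∞ limit.

**Area filters.** Automated mode: mean ± 2·(sample SD) of the cell areas,
estimated on the optimization images and frozen in batch mode; with fewer
than two cells the filter is disabled with a warning. All-cells mode: keep
areas in [c, 5c] for a user size cutoff c, count every surviving cell as
positive, ignore optimization steps. Manual mode: optional user-given
bounds. Filters are inclusive at both edges.

**Sub-regions.** Membership is by centroid (boundary inclusive, via
shapely); a centroid on a shared edge goes to the first-listed region and
is logged. Counts over a disjoint tiling therefore add up exactly to the
whole-image counts. Sub-regions work in both batch and non-batch runs; the
Log notes that batch-mode region counting extends the original non-batch
behavior, which was a GUI limitation rather than an algorithmic one.

**Ordering and determinism.** Optimization images are the first f in
lexicographic filename order. Reruns with the same configuration produce
byte-identical CSVs (the Log differs only in its timestamp line).

## Validation analysis

Automated per-image positive counts are compared against manual annotator
series: each series is z-standardized (sample SD), pairs with |z| > 2 in
either series are flagged as outliers and excluded, Pearson's r is computed
over the retained pairs, and each raw series' least-squares slope against
image index is reported. The two-SD exclusion is implemented as a filter;
whether the original analysis used it as a filter or as a test statement is
not determinable, so the filter reading is documented here as this
package's concrete choice. r is invariant to positive-scale affine
transforms of either series, and flagging is symmetric; both are tested.

## Synthetic data

The generator draws disk-shaped cells (radius 3–4 px, i.e. 6–8 µm diameter
at the default 1 µm/px) at rejection-sampled centers ≥ 12 px apart, over
Gaussian background noise, with a bimodal intensity structure: a baseline
population (mean 40, SD 8 on the 8-bit default) and an induced population
(mean 180, SD 8), within-cell texture SD 10, background 12 ± 3, and a
per-image drift offset ~ N(0, 5) emulating between-sample staining and
acquisition variability. Intensities are clipped to the dynamic range after
noise — configured hot, this reproduces the max-saturation QC signature.
Each image returns its true label image and a ground-truth table, so the
cutoff math can be tested in isolation from segmentation error.

Not emulated: optical PSF blur, cytoplasmic/spotty mRNA texture, crowding
and touching nuclei, uneven illumination. Passing the recovery tests
therefore demonstrates correctness of the cutoff and counting logic under
the stated intensity model, not segmentation robustness on real tissue.

## Problem sizes and numerical choices

- Oracle equivalence is checked on 1,000 random cell tables (n ≤ 50) at
  ≤ 1e-9 relative error; observed agreement is at machine precision.
- Ground-truth recovery uses cohorts of 30 images × ~100 cells (default
  generator conditions, separation ≈ 14× the larger of within-cell and
  population SD), S = 2, `across_cells` σ, across 20 seeds in the tests and
  5 cohorts per condition in the acceptance script; the null condition sets
  the two population means equal and lands at chance accuracy.
- The watershed split uses `min_distance` (default 5 px) between distance-
  transform peaks; smoothing radius defaults to 2 px and should be ~half
  the cell radius.
- Thresholding operates on integer histograms; the converged threshold is
  an integer and foreground is strictly greater than it.
- CSVs are comma-separated UTF-8 with "." decimals and a comment line
  stating the 0-based (row=y, col=x) coordinate convention.

## Known limitations

- Strictly 2D; stacks are projected, never segmented in 3D.
- The background estimate without a user polygon is the image mode — a
  documented approximation of a hand-drawn background ROI that is adequate
  when background dominates the field.
- `within_cell` σ (the literal default) is fragile on well-separated
  bimodal data, as discussed above.
- ImageJ `.roi`/`.zip` region files are not parsed; regions are supplied as
  a CSV polygon table.
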