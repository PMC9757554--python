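# Methods

This note documents the models, algorithms and numerical choices behind
`octafsv`, and what the synthetic experiments do and do not demonstrate.

## Scan model and units

An en-face scan is a square 8-bit grayscale raster with 0-based (row,
column) coordinates, row 0 at the top. Acquisition metadata (eye, group,
slab, repeat index, field of view, grid size) travels in a sidecar manifest
CSV, never in image headers, so plain PNG/TIFF files interoperate. The
slab labels (inner choriocapillaris, outer choriocapillaris, choroid —
depth windows 4–20, 29–49 and 64–115 µm below the retinal pigment
epithelium) are descriptive metadata: slab projection is done upstream by
the OCTA device, and inter-scan alignment, projection-artifact removal and
quality gating are likewise out of scope.

Physical pixel pitch is `fov_mm × 1000 / grid_px` µm (12 µm for a 6×6 mm,
500×500 scan) and pixel area is its square (144 µm²). Areas are always
reported in pixels, µm² **and** mm²; published FSV area figures in this
field are frequently printed with ambiguous units, so downstream users
should rely on the pixel counts plus the documented pitch.

## FSV detection

The pipeline is integer-in/integer-out and fully deterministic.

* **Normalization.** `out = round(255·(v − min)/(max − min))` with
  round-half-to-even. A constant image maps to all zeros with a
  `UserWarning`; the subsequent equalization maps a constant image bright,
  so a constant scan yields an empty void mask rather than a full one.
* **CLAHE.** Implemented in `octafsv/_clahe.py` with the integer-LUT
  semantics of the classic C++ implementations: per-tile 256-bin
  histograms; clip cap `clip_limit · tile_area / 256` counts (minimum 1);
  clipped excess redistributed uniformly (`excess // 256` to every bin,
  the remainder one count each to the lowest bins); tile mapping
  `round(255·cdf)`; bilinear interpolation between the four surrounding
  tile mappings with border replication outside the outermost tile
  centers. A 1×1 grid with unbounded clip reduces exactly to global
  histogram equalization, which the tests exploit as an oracle. Defaults:
  8×8 tiles, clip limit 40 (the default of the widely used C++ library,
  since the method that inspired this pipeline left it unstated).
* **Threshold.** Void ⟺ equalized intensity ≤ T, default T = 30. The ≤
  boundary matches inverse-threshold semantics of the same library.
* **Soft dilation.** One iteration of binary dilation with a 3×3 square
  element (both configurable; 0 iterations is the identity; even kernel
  sizes are rejected).
* **Area filter.** Components by 8-connectivity; survivors must have area
  **strictly greater** than `min_area_px` (default 20). Filtering happens
  after dilation, and the stored mask is the dilated, filtered footprint.
  Each surviving component records its pixel count and its external
  contour (holes do not create extra contours), so the contour count
  equals the number of void regions.

Properties guaranteed by construction and covered by tests: byte-identical
reruns; the unfiltered void set is nested (monotone) in T; area and
contour count are non-increasing in `min_area_px`; dilation never removes
void pixels; component sizes sum to the mask area.

### Behaviour on homogeneous backgrounds

Histogram equalization is rank-based: a tile containing only background
speckle is stretched to the full range, so roughly T/256 of its pixels
fall under the threshold no matter how uniform the tile is, unless the
clip limit engages. With the default clip limit 40 this happens whenever
the local histogram is broad (speckle SD above roughly 2 gray levels), and
the surviving darkest-tail clusters then contribute a stable baseline to
the measured area. Consequences:

* detected area overstates true void area on textured backgrounds — the
  repeatability statistics, which compare repeats of the same eye, are
  unaffected by a stable baseline;
* exact blob-count recovery (contour count = planted count) holds on
  high-contrast, low-noise scenes (speckle SD ≲ 1.5 at the defaults);
  above that the count includes noise-tail clusters. The fidelity tests
  run at speckle SD 1.5 with texture disabled for this reason.

## Synthetic data

The generator emulates only the statistical structure the analysis
relies on — it is not a physical OCTA simulator (no real speckle
statistics, no subretinal-fluid shadowing, no motion artifacts).

A **scene** (one eye × slab) is: a bright background (default 170) with
dark discs (default 10) as planted voids, plus a granular Gaussian texture
field (SD `texture_sd`, default 15 gray levels). The texture models true
flow heterogeneity, so the two repeat acquisitions of a scene **share** it
— scans taken two minutes apart image the same perfusion pattern. Each
repeat then receives its own independent additive Gaussian speckle (SD
`speckle_sd`) and an independent global intensity jitter (SD `jitter_sd`).
With speckle and jitter both zero the two repeats are bit-identical.

The shared texture also matters numerically: with a flat two-level scene
the CLAHE tile histograms are near-degenerate and the clip/redistribution
step responds discontinuously to one-count changes, making the measured
area a chaotic function of tiny noise; broad histograms keep the response
smooth, and the end-to-end repeatability then degrades monotonically with
the per-repeat noise, as a measurement model should.

A **cohort** (`CohortSpec`) draws, per eye × slab, a true void-area
fraction from a log-normal around the slab's load (defaults 0.10 / 0.05 /
0.02 for inner CC / outer CC / choroid, mirroring the decreasing void load
with depth window; fellow eyes scaled by 0.9), with between-eye log-SD
`sigma_between` (default 0.25). Disc radii are log-uniform on 2–12 px and
discs are added until the target fraction is covered. `sigma_within` (the
single within-repeat noise dial, default 6 gray levels) sets the
per-repeat speckle SD, with jitter tied to it as `sigma_within / 2`;
jitter mostly cancels under min–max normalization — deliberately so, since
robustness to global brightness shifts is the stated purpose of the
normalization stage. Defaults are 52 eyes per group, two groups, three
slabs, two repeats; all randomness flows from a single integer seed and
identical (spec, seed) reproduce every image and table bit-exactly.

`generate_paired_values` is the image-free counterpart: subject truths
`Normal(mu, σb²)` observed with independent `Normal(0, σw²)` noise per
repeat, so the true single-measures ICC is `σb²/(σb²+σw²)` — used for
parameter-recovery and CI-coverage experiments.

## Repeatability statistics

* **ICC.** Two-way ANOVA mean squares are computed with the residual sum
  of squares formed directly from the two-way residuals (not by
  subtraction of sums of squares), and the grand mean anchored to the
  column means; this keeps MSE and MSC exactly zero for bit-identical
  repeats, so perfect agreement reports ICC exactly 1.0. Estimates are
  not truncated: small cohorts can legitimately produce estimates below
  −1. The 95% CI for the single-measures form uses the standard F
  construction with Satterthwaite degrees of freedom; the average-measures
  estimate and CI are the Spearman–Brown transform of the single-measures
  ones (algebraically identical to the direct formula). For a perfect
  agreement matrix the F construction is degenerate and the CI collapses
  to the estimate. Simulation at the study's size (n = 52, true ICC 0.9)
  puts empirical CI coverage near 95%.
* **CV.** Per-subject `sd/mean` (sample SD, n−1), aggregated as the
  root-mean-square across subjects (the test–retest convention); an
  arithmetic-mean mode is exposed for sensitivity analysis. Zero subject
  means are rejected as degenerate.
* **Bland–Altman.** Differences oriented repeat1 − repeat2; limits of
  agreement at the conventional ±1.96 sample SD; per-subject (mean,
  difference) pairs are emitted for plotting.
* **Report.** One block per group × slab × metric (metrics: area in mm²
  and contour count — both ICC and CV are scale-invariant, so the area
  unit choice does not affect them). Eyes missing a repeat are excluded
  from their block with a logged warning; a block with fewer than two
  complete eyes is a validation error.

## Problem sizes in tests and the acceptance script

Image-cohort experiments run at reduced geometry chosen for desk-scale
runtime while keeping ≥ 16×16-pixel CLAHE tiles: the noise/repeatability
relationship uses single-group cohorts of 6 eyes at 128 px over four noise
levels × 10 seeds; the noise-free full-report check uses 6 eyes per group
at 128 px; detection fidelity runs at the full 500 px geometry. Purely
numerical experiments run at the stated sizes (n = 2000 recovery, 1000
cohorts of n = 52 for coverage).

## Known limitations

* The fixed global threshold after rank-based equalization flags a
  background-dependent dark fraction; absolute FSV areas are therefore
  comparable only within a fixed acquisition/processing protocol.
* Local adaptive thresholding variants (e.g. Phansalkar) and
  compensation for RPE scattering or subretinal-fluid shadowing are not
  implemented.
* The synthetic texture is white Gaussian noise, not correlated OCTA
  speckle; passing tests demonstrate the pipeline's statistical
  machinery, not clinical accuracy on device images.
* ICC assumes the two-way model with no subject–measurement interaction
  identifiability at k = 2; negative estimates are reported as computed.
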