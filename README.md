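# octafsv

Quantification of **flow signal voids (FSV)** in en-face OCT angiography
slabs of the choriocapillaris and choroid, plus the **test–retest
repeatability analysis** used to validate such measurements — intraclass
correlation coefficients (ICC), within-subject coefficients of variation
(CV) and Bland–Altman agreement.

The package is aimed at researchers working with swept-source OCTA en-face
images (e.g. 6×6 mm macular scans, 500×500 pixels, 12 µm pixel pitch) who
need a reproducible, scriptable FSV pipeline and a defensible repeatability
report for paired scans of the same eyes. Because patient scans are rarely
shareable, it ships a synthetic paired-scan generator with known ground
truth, so the entire pipeline is testable end to end without any clinical
data.

## The detection algorithm

For one 8-bit en-face slab image the void mask is computed by five
deterministic stages:

1. **Min–max normalization** — intensities are linearly rescaled so
   min → 0 and max → 255, removing global brightness differences between
   acquisitions.
2. **CLAHE** — contrast-limited adaptive histogram equalization over an
   8×8 tile grid (clip limit 40, bilinear interpolation of tile mappings),
   which amplifies local contrast between perfused speckle and flow voids.
3. **Inverse global threshold** — pixel is a void candidate iff its
   equalized intensity ≤ T (default T = 30).
4. **Soft dilation** — one pass of a 3×3 square structuring element.
5. **Area filter** — connected components (8-connectivity) with area
   **strictly greater than** 20 pixels survive; smaller ones are noise.

Two metrics summarize each scan: the total FSV **area** (pixels, µm², mm²;
one pixel is `(fov_mm·1000/grid_px)²` µm², i.e. 144 µm² at defaults) and
the **number of FSV contours** (one per void region).

## The repeatability statistics

For n eyes measured k = 2 times, the two-way ANOVA mean squares
(rows/subjects MSR, columns/measurements MSC, error MSE) give the
absolute-agreement ICC (McGraw–Wong):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

with 95% confidence intervals from the F construction with Satterthwaite
degrees of freedom. The CV is the root-mean-square of the per-eye
`sd/mean` (arithmetic-mean aggregation available), and Bland–Altman
analysis reports the bias of repeat1 − repeat2 with ±1.96·SD limits of
agreement.

## Worked example

Simulate a small paired cohort, run detection on every scan and build the
repeatability report, entirely in memory:

```python
from octafsv import CohortSpec, generate_cohort, build_report
from octafsv.fsv_core import run_fsv_batch

spec = CohortSpec(n_eyes=8, grid_px=128, sigma_within=4.0, seed=5)
cohort = generate_cohort(spec)
metrics = run_fsv_batch(cohort.scans)
report = build_report(metrics).report
print(report[["group", "slab", "metric", "n", "mean1", "mean2",
              "icc_single", "icc_average", "cv_percent"]].round(4))
```

which prints:

```
 group     slab     metric  n   mean1   mean2  icc_single  icc_average  cv_percent
  CSCR inner_CC       area  8 17.4957 17.5866      0.9232       0.9601      1.1477
  CSCR inner_CC n_contours  8 22.1250 22.6250      0.8852       0.9391      9.5498
  CSCR outer_CC       area  8 18.7287 19.0239      0.9211       0.9589      1.5793
  CSCR outer_CC n_contours  8 20.0000 18.6250      0.6940       0.8194     18.2056
  CSCR  choroid       area  8 21.3497 21.4865      0.7647       0.8667      1.2571
  CSCR  choroid n_contours  8  8.3750 10.5000      0.2268       0.3697     29.2923
fellow inner_CC       area  8 16.8827 16.7904      0.8552       0.9219      2.1553
fellow inner_CC n_contours  8 22.2500 27.6250      0.4686       0.6381     18.8356
fellow outer_CC       area  8 19.3456 19.4126      0.9687       0.9841      0.9870
fellow outer_CC n_contours  8 15.6250 15.7500      0.8210       0.9017     10.3587
fellow  choroid       area  8 21.2344 21.2654      0.9515       0.9751      0.8499
fellow  choroid n_contours  8 11.5000  9.2500      0.3175       0.4819     28.9112
```

Each row is one group × slab × metric block: per-repeat means (area in
mm²), the single- and average-measures absolute-agreement ICC, and the
within-eye CV in percent. Area repeatability is high (ICC 0.76–0.97, CV
≈ 1–2%) while the contour count — dominated by small texture-driven
regions at this noisy setting — is less repeatable, especially where few
true voids exist. Note the detected area includes the darkest fraction of
the granular background texture flagged by the fixed threshold; this
baseline is stable between repeats, which is exactly what the ICC and CV
quantify.

The same pipeline runs from the shell:

```sh
octafsv all --out run --seed 5 --n-eyes 8 --grid-px 128 --sigma-within 4
```

writing `run/cohort/` (images, manifest, ground truth), `run/metrics.csv`,
`run/report.csv` and `run/bland_altman.csv`. Subcommands `simulate`,
`detect` and `repeatability` run the stages individually; see
`octafsv --help`.

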