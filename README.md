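# flowseg

Self-supervised semantic segmentation of live-cell time-lapse microscopy.

Label-free segmentation of cells in phase contrast, DIC, IRM, transmitted
light, or fluorescence time-lapse imagery normally requires either manual
thresholds tuned per modality or a supervised model trained on curated,
hand-annotated data. `flowseg` instead exploits the one phenotypic feature
every live-cell movie has: **motion**. Intracellular dynamics and cell
migration give cell pixels measurable frame-to-frame displacement while a
stable background has essentially none, and that contrast is enough to
train a classifier automatically — no annotations, no manual parameters.
The intended users are cell-biology labs doing time-lapse imaging who want
per-frame cell/background masks without building a training library.

## Method

For every pair of consecutive frames (t−1, t):

1. **Dense optical flow.** A multi-resolution Farneback estimator
   (quadratic polynomial expansion per pixel, coarse-to-fine over a
   Gaussian pyramid) yields a displacement field d(x) and its magnitude
   ‖d(x)‖.
2. **Motion self-labeling.** Pixels above a high quantile of ‖d‖ are
   labeled *cell*; pixels below the median are labeled *background*
   (deliberate over-segmentation of motion makes the complement a safe
   background set); the rest stay unlabeled. Cell seeds are eroded by the
   flow-aggregation halo radius so they sit strictly inside moving
   objects. If the imagery is too low-contrast to yield enough
   well-separated cell seeds, the high threshold is reduced iteratively
   until the cell-pixel entropy distribution is well distinguished from
   the background one.
3. **Static features.** Local Shannon entropy (disk neighborhood, radius
   5, 32 bins) and gradient magnitude (Sobel-type on a σ=1 smoothed frame)
   are computed on frame t.
4. **Classification.** A Gaussian Naïve Bayes model — empirical priors
   π_k, per-class per-feature means μ_kj and variances σ²_kj — is fit to
   the self-labeled pixels and applied to every pixel in log space; the
   mask is P(cell | x) > 1/2.
5. **Post-processing.** Morphological closing with a disk of radius 5 plus
   binary hole filling; then automated size filtering: a stand-alone
   application of the flow estimates the typical moving-cell area, and
   components smaller than 10% of it (static debris, specks) are removed.

The model is retrained from scratch on every frame pair, so it adapts to
drifting illumination and changing phenotypes without any lookahead.
Masks are evaluated pixel-wise against ground truth with

    F1 = TP / (TP + (FP + FN) / 2)

The package also ships a synthetic-movie generator (`flowseg.synth`) that
produces textured moving cells, static inhomogeneous background, and
static debris with exact ground-truth masks, used throughout the test
suite.

## Worked example

```
$ flowseg synth --preset default --seed 1 --out movie
wrote 4-frame 'default' movie (seed 1) -> movie

$ flowseg segment movie/movie.tif --out seg --save-overlays
segmented 3 frame pairs -> seg

$ mkdir pred truth_eval
$ cp seg/mask_*.tif pred/                  # predictions only (no overlays)
$ cp movie/truth/truth_000[1-3].tif truth_eval/   # frame 0 has no mask
$ flowseg eval pred truth_eval --out report.csv
pooled F1 = 0.9232 (3 frames) -> report.csv
```

`report.csv` holds per-frame pixel counts and scores:

```
frame,tp,fp,fn,f1
mask_0001.tif,4675,776,0,0.9234
mask_0002.tif,4666,748,0,0.9258
mask_0003.tif,4673,806,0,0.9206
ALL,14014,2330,0,0.9232
```

Each row counts true-positive, false-positive, and false-negative pixels
for one frame's mask against its ground truth; here every true cell pixel
is recovered (fn = 0) and the errors are a thin halo of background pixels
around each cell boundary, giving per-frame F1 ≈ 0.92. `seg/run_log.csv`
records the self-labeling provenance per frame (chosen flow thresholds,
tuning iterations, components kept, status), e.g. frame 1 used a high
threshold of 2.95 px displacement after 2 tuning iterations and kept 3
components. Frame 0 receives no mask (it has no preceding frame);
`--copy-first-mask` copies mask 1 to it if desired.

All thresholds are derived from the data at run time; a YAML config
(`--config`) can override the estimator and policy settings, but none of
the defaults need touching for routine use.

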