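# Methods

## Radiometric calibration

Per flight and band, reflectance is modeled as r = A·e^{B·DN}. The fit is
ordinary least squares of ln r on DN, so it is closed-form, deterministic,
and exact (to floating-point precision) when the panel samples lie on the
model; the round-trip property — inverting the model at the four panel
reflectances and refitting recovers (A, B) to better than 1e-9 relative —
is tested directly. Two consequences of the log-linear choice:

* r² is the coefficient of determination of the *log-scale* regression.
  Goodness-of-fit numbers computed on the raw reflectance scale will differ
  slightly; users comparing against externally reported r² should check
  which scale was used.
* Reflectance must be a positive fraction (0, 1]; calibration samples
  outside that range are a domain error rather than silently log-transformed.

Panel extraction averages DN over pixels whose centers fall inside the
panel ROI. Pixels at the extremes of the sensor range (0 or the bit-depth
maximum) violate the exponential model — they are censored, not measured —
and are excluded from panel means with a warning. Applied reflectance is
clipped to [0, 1] and the clipped-pixel count reported.

## Chromatic coordinates and indices

All six indices are computed from brightness-normalized chromatic
coordinates, so under the r+g+b = 1 constraint EXG = 3g − 1 and
EXGR = EXG − EXR hold as algebraic identities (asserted to 1e-12), and EXG
and GLI are both strictly increasing functions of g, hence rank pixels
identically. Pixels with R+G+B = 0 carry no color and are flagged invalid;
invalid pixels are excluded from all means and histograms rather than
zero-filled, which would bias plot means toward the background. VARI's
denominator g+r−b can vanish; such pixels are invalid for VARI only.

Indices are computed on *calibrated reflectance* by default (the pipeline
calibrates before index extraction). Because chromatic normalization
removes a common scale factor, a per-band exponential calibration still
changes chroma (it is nonlinear in DN), so the order matters.

## Canopy segmentation

Otsu's threshold on EXG over a 256-bin histogram spanning the observed
range; the returned threshold is the bin edge maximizing between-class
variance, with both classes non-empty, so it is strictly interior. Ties
take the lowest edge, making the result deterministic. The default scope is
one global threshold over the union of plot-ROI pixels per scene — with a
shared background (mulch) a global threshold is better conditioned than 72
per-plot histograms, some of which may be nearly unimodal (a non-germinated
plot has no canopy mode at all). A per-plot mode exists for robustness
studies. A pixel is canopy iff it is valid, inside a plot ROI, and strictly
above the threshold.

## Traits

* Surface area per plant: canopy pixels in the ROI × GSD² / stand count.
  The stand count is the number of plants that actually emerged in that
  plot (recorded in the ROI metadata), not the nominal seeding rate —
  germination in the emulated design is 80–90 %.
* Estimated height: max over ROI pixels of DSM − DTM, floored at zero
  before the max (negative differences are reconstruction noise), m → mm.
* VI means: arithmetic mean over all valid ROI pixels by default; a
  canopy-only mode restricts to segmented pixels. The two differ
  systematically — background dilutes the all-pixel mean — so the mode is a
  recorded configuration choice, not a hidden default.
* Units: areas cm², heights mm, stem diameter mm.

One geometry convention is used everywhere: a pixel belongs to a polygon
iff its *center* is inside. This makes areas additive under ROI splits and
keeps panel means, canopy counts and zonal means mutually consistent.
Plots with zero emerged plants are excluded from the trait table (logged),
so a 24-entry × 3-replicate trial with one failed entry yields 69 rows per
acquisition set.

## Statistics

The analysis layer is rank-based throughout, matching how small replicated
trials (3 replicates per genotype) are analyzed when normality screens
fail. Shapiro–Wilk is reported per trait × set as a gate only; the pipeline
always proceeds nonparametrically.

Kruskal–Wallis uses the tie-corrected H with a chi-square tail on g−1
degrees of freedom. A caveat the test suite documents explicitly: with many
groups of only three replicates the chi-square approximation is
*conservative* — under a 20-group × 3-replicate null the measured rejection
rate at α = 0.05 is ≈ 0.023, not 0.05 (the rank statistic's discrete
permutation distribution is poorly approximated by chi-square at n_i = 3;
scipy's implementation agrees bit-for-bit). Significance claims at this
design are therefore cautious rather than inflated.

Dunn's post hoc z uses pooled mean ranks with the tie-corrected variance,
two-sided normal p, Bonferroni over all g(g−1)/2 pairs (capped at 1). The
compact letter display assigns one letter per maximal clique of the
non-significance graph, ordered deterministically — the fixed point of the
insert-and-absorb construction: two groups share a letter iff their
difference is not significant, verified exhaustively for up to five groups.

Spearman matrices are mid-rank Pearson correlations with the t
approximation (n−2 df), pairwise-complete over missing values. PCA is an
eigendecomposition of the correlation matrix of listwise-complete,
standardized traits (covariance PCA available behind a flag); EXR is folded
to |EXR| before standardization by default because it is the one index that
rises with *red*, and on the raw sign it dominates loadings without adding
information. Component signs are fixed so each component's
largest-magnitude loading is positive. α = 0.05 with the conventional
star codes (0.05 / 0.01 / 0.001).

## The synthetic field generator

The generator emulates the study design the pipeline targets: 24 entries ×
3 replicates = 72 plots (4 m × 1 m, 0.5 m paths), up to 15 plants per plot
sown 25 cm apart, black mulch background, four calibration panels
(3/12/36/56 %), two acquisition sets, nominal GSD 1.461 cm/px from the
camera geometry (72.3° HFOV, 4000 px, 40 m). One entry fails to germinate;
the rest emerge per-seed-position with probability 0.85.

Design choices where the emulated reality is underdetermined:

* **DN synthesis.** DN is produced by inverting the calibration model per
  band (default coefficients: published per-flight fits for an early and a
  late season flight), adding Gaussian DN noise (default sd 0.5 DN), and
  quantizing to 8 bits (16-bit option). Clipping at the top of the range
  warns. An unquantized float-DN mode exists because integer rounding
  limits calibration round-trip accuracy to ~B/2 per DN — the exactness
  properties are only testable without quantization.
* **Canopy rendering.** Plants are hard-edged overlapping disks of
  per-plot color; hard edges keep the pixel-count area oracle exact.
  Within-plot variation comes from per-plant radius jitter (±10 %) and
  height factors (0.70–0.95 of the plot height, one plant at exactly the
  plot height). Plant stems snap to pixel centers so the dome apex is
  sampled exactly and the height oracle is exact.
* **Greenness.** Canopy color is a chromatic green fraction g per plot
  (mean 0.45 early, 0.48 late), clipped to [0.42, 0.60]. The floor keeps
  the dimmest canopy distinctly greener than the spectrally neutral mulch
  (g = 1/3): a live canopy that is chromatically indistinguishable from
  black plastic is not a scene this instrumentation could or should
  resolve.
* **Terrain.** The DTM is a gentle linear gradient (0.30 m across the
  field over a 50 m datum) so height extraction is tested against a
  non-flat ground model; DSM = DTM + canopy height, with optional Gaussian
  elevation noise (default off).
* **Trait structure.** Ground-truth traits (height, per-plant area, stem
  diameter, node count, greenness) are generated from one standard-normal
  latent growth factor per plot and set. Late-stage loadings are 0.85,
  giving pairwise population Spearman correlations ≈ 0.71 among traits —
  the strong late-season coupling of growth and greenness; early-stage
  loadings are 0.15 (traits nearly independent). Sixty percent of the
  latent variance sits at the entry level, so replicates of a vigorous
  genotype are all vigorous and entry effects are detectable late but not
  early. Recorded truth areas are measured from the rendered mask (overlap
  reduces union area below the per-plant target), so the area oracle is the
  rendering itself.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: structure-from-motion reconstruction artifacts,
lens distortion and mosaicking seams, mixed border pixels and soft canopy
edges, within-canopy texture and shadow, illumination gradients across the
field, weeds, and lodging. Tests against the generator validate the
*computational* contracts (calibration, segmentation, zonal statistics,
rank tests) under a controlled forward model, not the photogrammetric front
end, which is out of scope.

## Problem sizes and numerical notes

The default simulated trial renders two 3-band ~3800 × 870 rasters at
1.461 cm/px plus surface models (a few seconds each); unit tests run on a
4-entry × 2-replicate field at 4 cm/px. The null-calibration study of the
Kruskal–Wallis test uses 2000 replicates of a 20 × 3 design; the
latent-model Monte-Carlo oracle uses 10⁶ draws. Degenerate inputs are
first-class: constant samples, empty ROIs, zero-variance columns,
all-identical groups (H = 0, p = 1), and non-germinated plots all have
defined, tested behavior rather than NaN propagation.
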