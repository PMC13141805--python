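# Methods

## Problem and scope

Macrovesicular steatosis (MaS) — hepatocellular fat stored as large droplets
— is graded as the percentage of tissue area occupied by lipid vacuoles on
H&E-stained liver sections. On H&E, lipid is washed out during processing,
so vacuoles appear as bright, round, unstained holes in eosin-pink tissue.
`steatoquant` quantifies MaS with a transparent, feature-based pipeline:
no training data, no color calibration, every decision inspectable as a
geometric threshold. It also implements the rater-agreement statistics used
to compare automated scores against pathologist readings, and a seeded
synthetic-slide generator so the entire system can be validated without any
clinical images.

## Quantification pipeline

The pipeline is grayscale-driven (Rec. 601 luminance) and geometry-driven;
it deliberately avoids stain-specific color models so batches with staining
drift are processed identically.

1. **Tissue mask.** Luminance image, 5×5 mean filter, Otsu threshold.
   Stained tissue is the darker class. Components smaller than 2000 µm² are
   removed as debris, and an `edge_crop` (default 100 px) border band of the
   frame is excluded to suppress scan-edge artifacts. The crop is specified
   in pixels at working resolution, not microns, so it follows the scanner's
   artifact geometry rather than tissue scale.
2. **Artifact suppression.** Closing with a disk of radius `bridge_span/2`
   (default span 10 px) bridges narrow tears and folds; this closing plus
   the selective hole handling below realizes convex-hull-style bridging
   without swallowing deep genuine concavities of the section. Interior
   holes are then filled back into the tissue mask — unstained vacuoles and
   vessel lumina are tissue and must stay in the denominator — **except**
   holes larger than 1.5×10⁶ µm² or with solidity below 0.85, which indicate
   folds/tears and remain excluded. Finally, coverslip glare — pixels with
   HSV saturation < 0.10 and value ≥ 0.995 (essentially maximal brightness
   with no color) — is removed from the mask, and fragments stranded below
   the debris threshold are dropped. Glare handling is polarity-configurable
   (`glare_keep_low_saturation`) because "intersect with a low-saturation
   mask" can be read either way; the default removes low-saturation,
   near-maximal pixels, which is the reading that actually eliminates glare.
   The value gate at 0.995 distinguishes glare (channel at 255) from
   vacuoles (bright but a few gray levels below maximum).
3. **Candidate detection.** A dynamic threshold against the local mean:
   a pixel is a vacuole candidate iff its gray value exceeds the mean of a
   `dyn_window`×`dyn_window` neighborhood (default 31 px) by at least
   `dyn_offset` gray levels (default 5), restricted to the tissue mask.
   This adapts to local staining intensity with no global normalization.
   For vacuoles wider than the window only an annulus near the rim passes
   the test; hole filling at region extraction recovers the full droplet.
4. **Feature classification.** Connected components (8-connected, holes
   filled) are described by area, roundness, circularity, compactness,
   convexity and anisometry (definitions below) and accepted iff every
   descriptor is within bounds. Defaults: area 50–12 000 µm² (macrovesicular
   scale, ~8–120 µm equivalent diameter), roundness ≥ 0.55, circularity
   ≥ 0.45, compactness ≤ 2.0, convexity ≥ 0.80, anisometry ≤ 2.5. Rejected
   regions carry the first failing criterion in the fixed order (area,
   roundness, circularity, compactness, convexity, anisometry) so reports
   are deterministic. Regions touching the image border are excluded by
   default (the edge crop makes this nearly moot).
5. **Quantification.** steatosis % = 100 × Σ accepted vacuole area /
   tissue area, both in µm². The denominator includes vacuole pixels
   (vacuoles are tissue), which bounds the fraction by 100 and matches the
   area-fraction convention. The percentage is additionally reported as an
   ordinal grade over the bins {0}, (0,5], (5,10], (10,15], (15,20],
   (20,30], (30,100] — the binning used for ordinal agreement statistics.
   The boundary convention (upper edge inclusive) is ours.

The descriptor thresholds are the kind of settings a pathologist tunes
interactively against overlays; the defaults here were calibrated once
against the synthetic generator and are not canonical. Every value is a
`PipelineConfig` field, settable from a YAML/JSON file, and the effective
configuration is echoed into each report.

All physical thresholds are converted to pixels via the slide's
microns-per-pixel (mpp), read from SVS/TIFF metadata (Aperio `MPP` tag,
else TIFF resolution tags) and scaled by the pyramid level's downsample
factor; when metadata is absent a default of 0.249 µm/px (40× Aperio
maximum resolution) is assumed and flagged. This makes results
scale-consistent: running at downsample 2 moves estimates by well under a
percentage point on synthetic slides.

## Shape descriptors

For a region with pixel count F, pixel centroid c, sub-pixel contour points
p_i (distances d_i = ‖p_i − c‖), contour polygon length L and polygon area A:

* area = F·mpp², equivalent diameter = 2·mpp·√(F/π)
* roundness = 1 − σ_d/d̄ (radial uniformity; disc → 1)
* circularity = A/(π·max d_i²) (how fully the region fills its
  circumscribed circle; disc → 1)
* compactness = L²/(4πA) (inverse isoperimetric quotient; disc → 1,
  larger = less compact)
* convexity = A / area(convex hull of contour) (1 for convex regions)
* anisometry = axis ratio of the second-moment equivalent ellipse (≥ 1;
  high for vessels)

Two numerical choices matter. First, the contour is the 0.5 iso-level of
the Gaussian-smoothed binary patch, with σ = 0.01·√F (floored at 0.5 px):
the raw iso-line of a binary raster is a 45° staircase whose length
overestimates the perimeter by several percent and breaks the
compactness = 1 disc anchor, while a *fixed* smoothing scale would make
descriptors scale-dependent for shapes with corners or cusps. Scaling σ
with region size keeps descriptors invariant under uniform rescaling
(within raster tolerance) at the cost of a corner rounding of order σ.
Second, ratio descriptors use the contour polygon area A in both numerator
and denominator rather than mixing pixel counts with polygon perimeters;
µm² areas are reported from pixel counts. Degenerate regions (single
pixels, collinear contours) take the disc values for all ratio descriptors;
the area filter removes them from quantification regardless. The
second-moment covariance adds the 1/12 per-pixel variance term so
single-row regions have finite axis ratio.

## Synthetic slides

The generator renders, on a white background: an eosin-pink tissue disc or
blob (RGB anchor (230,160,180), multiplicative texture noise SD 2% plus
additive channel noise SD 3); near-white, slightly irregular,
non-overlapping discs as vacuoles (anchor (244,242,243), diameters 15–100
µm — the macrovesicular range); elongated bright ellipses as vessel lumina
(axis ratio 3–6); thin background-colored bands as tears; and zero-
saturation, maximal-value patches as glare. Vacuoles are placed by
rejection sampling with a 3-px clearance until the vacuole/tissue area
ratio is within ±0.3 percentage points of the target, capping each new
radius by the remaining area so the target is never overshot; an
unreachable target raises a generation error rather than silently
under-filling. Ground-truth masks are exact by construction: the truth
tissue mask contains vacuoles and vessels and excludes tears and glare.
Identical spec + seed reproduces slides bit for bit; cohorts derive child
seeds from one master seed.

What the generator does *not* emulate — nuclei, sinusoids, stain spectra,
microvesicular droplets, confluent merging of vacuoles at high grades,
scanner compression artifacts — bounds what passing tests show: they
validate the geometry and statistics machinery end to end, not clinical
accuracy on real slides. In particular the confluent >30% regime, where
droplet merging breaks the disc-likeness assumption and causes
underestimation on real tissue, is intentionally absent at default
settings (non-overlap can be disabled to study it).

## Agreement statistics

Continuous agreement: Pearson r with Fisher-z 95% CI and R² = r² (exact
identity for bivariate correlation), Spearman ρ on mid-ranks, RMSE,
Bland–Altman bias ± 1.96·SD limits of agreement (differences paired with
the two-measurement mean), and the fraction of cases where the automated
score falls within ±5 percentage points (absolute, boundary-inclusive) of
the mean available-rater score. Range classification counts cases above,
below, or within (inclusive) the rater range. Averaging n independent
raters shrinks the reference's error SD by √(1/n) (≈ 0.58 for three),
which is why consensus correlations legitimately exceed single-rater ones.

Ordinal agreement: Cohen's κ with quadratic disagreement weights
w_ij = (i−j)²/(k−1)² over the steatosis bins; continuous scores are binned
first. κ = 1 − Σw·O/Σw·E with O the observed joint proportions and E the
marginal products. The 95% CI uses the large-sample Fleiss–Cohen–Everitt
variance by default; a seeded 2000-resample case bootstrap is available
(`ci_method="bootstrap"`) and is preferable for sparse tables where
asymptotics are doubtful. κ is reported with Landis–Koch verbal bands
(≤0.20 slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial, else almost
perfect; negative = poor). A constant rater makes κ undefined and raises
an explicit error. Raters covering different case subsets are handled by
pairwise deletion.

Shapiro–Wilk (via scipy) is exposed for checking score normality, which
motivates reporting both parametric and rank statistics for right-skewed
clinical cohorts.

## Validation strategy and problem sizes

The test suite validates each stage against independent oracles:
closed-form descriptor values for discs, squares and 2:1 ellipses;
flood-fill component counting; brute-force reimplementations of every
agreement statistic (1e-12 agreement on random inputs, with
scikit-learn's quadratic kappa as an additional cross-check); and
generator ground truth for masks and fractions. End-to-end, parameter
recovery is measured on 50 seeded 1024×1024 px slides (mpp 1.0, fractions
spanning 1–35%, all artifact types present) — Pearson r(true, estimated)
≥ 0.95 and mean absolute error ≤ 2 percentage points are required; in
practice both are met with large margin (r ≈ 1.00, MAE ≈ 0.1 points,
because synthetic vacuoles are clean-edged). Artifact immunity requires
≤ 0.5% estimated steatosis on 10 slides containing only vessels, tears and
glare. The 1024-px slide size keeps a full 50-slide recovery run at a few
minutes on one CPU while remaining ~10× the default dynamic-threshold
window and ~10× the largest vacuole diameter, so no stage is
size-degenerate.

## Known limitations

* Descriptor values are not claimed to match any specific commercial
  image-analysis library numerically; definitions follow the standard
  semantics of the named features.
* The pipeline assumes bright-on-dark vacuoles in a single-layer RGB
  raster; slides larger than memory are not tiled/streamed.
* Default thresholds are synthetic-calibrated; clinical deployment would
  require re-tuning against expert overlays, exactly as interactive
  review workflows do.
* Confluent high-grade steatosis (>30%) and microvesicular droplets are
  out of scope; the former underestimates by design honesty, the latter
  needs higher magnification.
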