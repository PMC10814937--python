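# Methods

## Color model

Photographs are 8-bit sRGB rasters. CIELAB conversion follows
IEC 61966-2-1 (sRGB transfer function) with the D65 white point and 2°
standard observer, delegated to `skimage.color`; the test suite checks it
against an independently hand-coded textbook implementation of the same
chain (agreement ≤ 0.1 in each of L\*, a\*, b\* across the RGB cube) and
verifies round-trip error < 0.5 intensity units on the cube corners.
Photographs carry no ICC profile information, so no profile handling or
white-balance correction is attempted.

Region summaries report, for the pixels of a mask:

* per-channel RGB means;
* Lab means, by default the mean of per-pixel Lab values (the perceptually
  standard choice; converting the mean RGB instead is available via
  `lab_average="mean_rgb"`). The two differ because the RGB→Lab map is
  nonlinear; for the noise levels considered here the difference is small.
* ITA = arctan((L\* − 50)/b\*)·180/π, evaluated at the region's mean L\*
  and b\*. This convention (rather than averaging per-pixel ITA) was chosen
  because the packaged cohort table is internally consistent with it: for
  each of its 46 rows the printed ITA is recovered from the printed L\*
  and b\* within ±0.15°, the tolerance implied by 2-decimal rounding of
  the inputs. Per-pixel ITA averaging is available as an option but
  interacts badly with b\* near 0, where ITA is discontinuous.

ITA is undefined at b\* = 0; the package defines it there as +90° for
L\* > 50, −90° for L\* < 50 and 0° at L\* = 50, the limits along b\* → 0⁺.
Values are kept at full precision internally and rounded only at
serialization (two decimals for feature tables, matching clinical
reporting practice). Rounding is round-half-even on the double-precision
value; group means are accumulated with exact summation (`math.fsum`)
before dividing.

## Segmentation and geometry

Pixel coordinates are 0-based pixel centers, x right, y down. A boundary
is an ordered simple polygon; pixel membership is pixel-center containment
(even-odd rule, via shapely). Areas are shoelace areas of the vertex list.

*Manual mode*: operator-placed border points (≥4, non-collinear) are
closed with a periodic quadratic B-spline (`scipy.interpolate.splprep`,
k=2, per=1). With the default smoothing of 0 the spline interpolates the
points, so its mean-square distance to them is 0 — minimal over all
curves. Twelve points on a 50 px circle are recovered within 0.15 px.

*Automatic mode* assumes one dominant lesion on a skin background:
the image border's median Lab color estimates normal skin; the Euclidean
Lab distance from it is thresholded by Otsu's method; the mask is closed
with a disk (radius 5 px default), the largest connected component kept
(minimum 100 px, else a failure signal suggests manual mode), and its
outer contour traced and subsampled to ~200 vertices. On the default
synthetic lesion (noise sd 5) this recovers the true mask with Dice
≥ 0.95 and the true area within 5%. Specular highlights are not removed
by default — moderate flash reflections inside the lesion do not change
the component found — but an optional luminance-percentile mask-out
(`highlight_percentile`, e.g. 99) is provided.

The *normal-skin band* enlarges the boundary by a factor (default 1.25,
i.e. border incremented by 25%) about its area centroid — a similarity
transform, chosen over pixelwise morphological dilation because it is
parameter-free and produces the visually uniform ring seen in clinical
overlays — and takes pixels inside the enlarged but outside the original
polygon. For convex shapes the band/lesion area ratio converges to
factor² − 1 as resolution grows (within 2% on a 60 px circle). Bands
exceeding the frame are clipped with a warning.

Geometric features (from a two-point ruler calibration, cm per pixel):
surface = shoelace area · scale², perimeter = edge sum · scale, maximal
diameter = largest pairwise vertex distance (computed on the convex hull,
which provably attains the same maximum as the brute-force scan the tests
use as oracle). Validity invariants: diameter ≤ perimeter/2 and the
isoperimetric inequality 4π·area ≤ perimeter².

## Statistics

Group means are arithmetic means of the per-patient lesion values.
Two-group comparisons use the Mann–Whitney U test with the conventions of
SPSS NPAR TESTS, which the package's comparison tables mirror row for row:

* midranks for ties; U = min(U₁, U₂); W = the smaller of the two rank
  sums (note: for unequal group sizes the smaller-rank-sum group is not
  always the smaller-U group, so W − m(m+1)/2 equals U₁ or U₂ but not
  necessarily min U);
* Z = (U − n₁n₂/2)/σ with the standard tie-corrected σ and no continuity
  correction; asymptotic two-tailed p = 2(1 − Φ(|Z|));
* exact significance = min(1, 2·P(U ≤ observed U)), with P from the exact
  null distribution of U computed by a dynamic-programming count over the
  C(n₁+n₂, n₁) rank assignments, without tie adjustment (matching the
  small-sample exact value SPSS prints as "Exact Sig. (2*(1-tailed
  Sig.))"). The DP is verified against full enumeration for all
  n₁+n₂ ≤ 10, and the asymptotic branch against scipy's tie-corrected
  normal approximation.

scipy's own exact method uses a different two-sided definition, which is
why the exact distribution is implemented in-package; scipy serves as the
independent cross-check for the asymptotic path only.

No multiple-testing correction is applied: the tables report seven
per-parameter tests per comparison, as is conventional for descriptive
cohort tables of this size.

## Threshold diagnostics

A rule compares one parameter against a cutoff; a value exactly at the
cutoff counts positive (no packaged cohort value sits on the default
cutoffs, so this convention is not load-bearing there). The confusion
report keeps full-precision percentages and additionally formats a
display set at typical clinical-report precision: sensitivity, accuracy
and NPV to the nearest percent, specificity truncated at one decimal,
PPV at two decimals. Metrics with zero denominators are reported as
undefined, never as 0. The separation scan evaluates every midpoint
between adjacent sorted values in both rule directions and maximizes
sensitivity + specificity; on the packaged cohort, b\* does **not**
perfectly separate MCC from cherry angioma (the ranges overlap:
cherry min 14.52 < MCC max 21.27), which the scan reports honestly.

## Synthetic data

The image generator emulates the relevant features of the study's
photographs: an elliptical lesion whose mean RGB (default (180, 70, 90),
a red-purple nodule) differs from a noisy skin background (default
(220, 180, 160), Gaussian noise sd 5 per channel — "clinical photograph"
rather than laboratory noise levels), optional specular highlight disk,
optional two-mark ruler. It does not simulate skin texture, hair,
illumination gradients or camera response; passing recovery tests
therefore demonstrates correctness of the pipeline's measurement logic,
not robustness to real-world photographic variability. Ground truth
(analytic ellipse boundary, exact pixel-center masks) is returned with
the image, and generation is deterministic per seed.

The cohort generator draws 7-parameter vectors per diagnosis group from a
multivariate normal; defaults (means and diagonal covariances) are the
sample statistics of the packaged 46-patient table, with the study's
group sizes. The sampled ITA is discarded and recomputed from the sampled
L\* and b\*, preserving the internal-consistency invariant of real
feature tables. RGB draws are clipped to [0, 255] and L\* to [0, 100]
(a mild truncation bias at extreme settings; negligible at the default
parameters).

The packaged cohort table (46 records × 7 parameters + diagnosis) is
read-only and SHA-256-pinned; `load_study_fixture` refuses a modified
file. The hemangioma group has 12 records: the per-record table body,
the cohort totals, and the diagnostic rule's own arithmetic (PPV 9/13,
NPV 8/10) all require n = 12, which resolves a caption inconsistency in
the source material in favor of n = 12.

## Test calibration and problem sizes

Chosen so the whole suite runs in seconds on one CPU:

* type-I error of the exact test: two N(0,1) groups of n = 8, 2000 seeded
  replicates, rejection at p_exact < 0.05. n = 8 was selected because the
  discrete exact test's attainable level there is 0.0499 (computed from
  the null pmf), essentially nominal; the observed rate is required to
  fall within the binomial 95% interval around 0.05.
* cohort mean recovery: 500 draws per group; per-cell CLT bound at
  3.9 standard errors (Bonferroni over the 24 group × parameter cells,
  ≈1% familywise false-alarm rate for a fixed seed).
* image recovery: 220–256 px rasters (≥10⁴ lesion pixels), RGB means
  within 3·sd/√n plus a 0.5 quantization margin; segmentation Dice ≥ 0.95
  at noise sd 5.

## Known limitations

* Single-lesion scenes only; no hair removal, no multi-lesion handling,
  no learning-based segmentation.
* The automatic segmenter assumes the image border is normal skin; a
  lesion filling most of the frame violates that assumption.
* Geometry of any specific published case cannot be checked without the
  original photograph; geometry code is validated against closed forms
  (square, circle) and brute-force oracles instead.
* The exact Mann–Whitney distribution ignores ties (as small-sample SPSS
  does); heavily tied data make the exact p conservative.
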