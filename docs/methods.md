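# Methods

## Scope and data model

`qvasc` quantifies 2-D microvessel maps. The input contract is a raster
(binary or grayscale) in which foreground pixels are vessel lumen, a lesion
mask (single closed region; defaults to the full frame), and a physical
pixel spacing in mm/px (default 0.05 mm/px, at which a 300 µm vessel spans
6 px — the practical floor for stable skeletonization). All physical outputs
are in mm and degrees; coordinates are pixel-centered, origin top-left,
(row, col) order.

The pipeline is: binarize → skeletonize and prune → skeleton graph →
biomarker panel → logistic malignancy model. Each stage is exposed
separately so any of them can be replaced or inspected.

## Skeleton graph

The skeleton is the 1-px 8-connected medial axis
(`skimage.morphology.skeletonize`). Cleanup applies three rules, in order:

1. **Spur pruning.** Terminal chains shorter than `prune_len_px`
   (default 5 px) *or* shorter than the vessel radius at their junction are
   skeletonization whiskers, not branches, and are removed iteratively. A
   second, graph-level pass repeats the rule because re-skeletonizing after
   a removal can regrow a radius-scale stub.
2. **Junction merging.** A thick bifurcation often skeletonizes into two
   nearby degree-3 pixels. Junction pixel clusters are first merged by
   adjacency; then any connector between two junctions shorter than
   1.5 × the local vessel radius is contracted into a single branch point.
   Without this, NB double-counts on rasterized trees.
3. **Pinhole loops.** A self-loop shorter than ~3 junction radii is a
   skeleton cycle around a 1–2 px rasterization hole in the junction crotch
   and is deleted. Genuine vascular loops are vessel-scale and survive; an
   isolated loop becomes one segment with coincident endpoints (excluded
   from tortuosity, where the chord is zero).

Branch points are the remaining nodes of degree ≥ 3; vessel segments are
maximal centerline paths between nodes; degree-2 joints left by the cleanup
are fused.

## Estimators and their calibration

Three measurement details matter at the 3–15 px vessel scales this package
targets. Each was chosen by calibrating against rasterized vessels of known
geometry (the calibrations are re-run in the test suite):

- **Path length.** The raw 8-connected chain overestimates smooth-curve
  length by up to ~8% (staircase bias); subsampling or spline fits instead
  *under*-estimate by attenuating real vessel-scale meander. Chain
  coordinates are Gaussian-smoothed (σ = 2 px, endpoints pinned) before
  summing, which leaves < 0.5% residual on straight oblique runs and < 2%
  on meandering vessels. The distance metric uses this length over the exact
  endpoint chord.
- **Radius.** Per-point radius is the Euclidean distance transform of the
  vessel foreground sampled at chain pixels. For this rasterization
  convention the EDT at the centerline is an unbiased radius estimate
  (verified on constant-radius strips across orientations); axis-aligned
  vessels with fractional radii can still read up to +0.6 px because the
  discrete boundary quantizes — an irreducible raster effect.
- **Local diameter at a branch.** The EDT is inflated inside the junction
  blob and depressed for roughly two radii beyond it by the background wedge
  between the daughters (the crotch). The representative local diameter is
  therefore a *plateau* estimate: the maximum of a 3-point running median
  over a window starting one junction radius from the node. The mother at a
  branch is the incident segment with the largest such diameter; Murray's
  deviation uses these local diameters, summing all daughters' cubes at
  trifurcations.
- **Daughter direction (BA).** Directions are total-least-squares line fits
  over 0.8 mm of centerline arc starting 1.5 junction radii from the node:
  inside that zone the daughters have not physically separated (for narrow
  angles the crotch extends ~r/sin(θ/2)) and the skeleton runs along the
  bisector. At a junction of degree > 3 the two largest-diameter daughters
  define the angle. The synthetic generator states its ground-truth angles
  with the same convention, because no image-based observer can measure a
  direction inside the junction zone.

**Resolution requirements.** Diameters recover within 10% and tortuosity
within 2% at 0.05 mm/px for ≥ 6 px-wide vessels. Murray's deviation cubes
the diameter ratio, tripling relative error: recovering MD to ±0.05 requires
sub-2% diameter precision, i.e. vessels of roughly ≥ 15 px radius. The test
suite therefore checks MD recovery on rasters at 0.02 mm/px with 0.5 mm
root radii; at the default spacing the MD of individual small branches
carries noise of order ±0.1 and is best used in aggregate.

## Degenerate conventions

A lesion with no branch points reports MD = 1 and BA = 180° exactly (both
mean and max); an empty vessel map additionally has NB = NV = 0, VD = 0,
mvFD = 0 (with a warning) and undefined VDR/SVP (NaN, reported as missing).
These conventions make the avascular/unbranched case a well-defined,
benign-like corner of feature space rather than missing data.

## Fractal dimension

mvFD is computed on the full binary vessel map (not the skeleton), cropped
to the foreground bounding box, with box sizes s = 2, 4, 8, … up to
min(H, W)/4. Each count is minimized over four half-box grid offsets to
reduce grid-phase bias, the counts are made monotone non-increasing (offset
jitter can otherwise violate this by one box), and mvFD is the least-squares
slope of log N_s vs log(1/s). The returned curve (sizes, counts, R²) is kept
for QC. Calibration: a straight line reads 1.00, a filled square 2.00, and a
Sierpinski raster (bit-trick construction, exactly N_s = 3^k at aligned
dyadic scales) reads log 3 / log 2.

## Spatial vascularity

The lesion mask is split by uniform (isotropic 3×3) erosion until the center
region falls to `center_fraction` (default 0.5) of the mask area; the
peripheral region is the remaining rim. VDR = VD_center / VD_peripheral;
vessels only in the center give VDR = +∞ (reported as a sentinel), no
vessels anywhere leave VDR and SVP undefined. SVP = 0 for VDR < 1,
1 for VDR > 1; the measure-zero tie VDR = 1 maps to 1 by default
(configurable), on the reading that vessels reaching the center at peripheral
density are not a peripherally concentrated pattern. The exact
center/periphery partition is a package choice; only the sign semantics of
VDR are guaranteed.

## Statistical layer

The malignancy model is an unpenalized maximum-likelihood logistic
regression (`statsmodels.Logit`), deterministic given data, over one of
four feature families: `new` (MD_mean, mvFD, BA_mean, SVP), `initial`
(NB, NV, VD, D_mean, D_max, DM_mean, DM_max), `combined`, and
`combined_birads` (adds BI-RADS as an ordinal 2–5 covariate). Rows with
missing features are deleted listwise and counted. Perfect or quasi-perfect
separation — routine on clean synthetic cohorts — is detected (failed MLE
convergence or |coefficient| > 50) and handled by a vanishing-ridge refit
(L2, C = 10⁶) with a `separation_flag` and warning, so the reported AUC and
operating point remain meaningful.

ROC analysis is empirical with trapezoidal AUC; the operating point
maximizes Youden's J unless a fixed probability threshold is supplied; the
AUC 95% CI is a seeded nonparametric percentile bootstrap over lesions
(2000 replicates by default). Group comparisons use the two-sided Wilcoxon
rank-sum test via `scipy.stats.mannwhitneyu`, which evaluates the exact
permutation distribution for small untied samples. Correlations are Pearson,
with |r| < 0.45 flagged as a low-correlation (nearly independent) pair.

## Synthetic generator: what it emulates, and what it does not

`generate_vessel_tree` grows rooted trees: straight chords perturbed by a
seeded sinusoid plus a smooth endpoint-pinned random walk (tortuosity
amplitude as a fraction of segment length; meander wavelength kept at or
above ~1.5 mm, since sub-diameter wiggle is both unphysiological and
invisible after rasterization). At each branch event (always ≥ 2 daughters,
so stored topology counts agree with the skeleton-graph definitions) radii
split by `Σ r_d^m = r_mother^m`; m = 3 reproduces Murray's law exactly
(ground-truth MD ≡ 0), a sampled m ≠ 3 injects a known deviation. Branch
opening angles are drawn per branch from a clipped normal. All ground truth
(lengths, chords, angles, deviations) is recomputed from the final stored
polylines, so any placement transform is automatically reflected.

`generate_cohort` draws two phenotypes, fixed once as plausible
submillimeter-vessel morphology:

| parameter | benign-like | malignant-like |
|---|---|---|
| branching (daughters/tip) | 1.2–1.8 | 1.9–2.6 |
| tortuosity amplitude | 0.02–0.08 | 0.12–0.22 |
| root radius (mm) | 0.17–0.24 | 0.26–0.38 |
| radius exponent m | 2.85–3.15 | 1.9–4.4 |
| opening angle (°) | 95–120 | 35–55 |
| generations | 2 | 2 (small) / 3 |

Lesion diameters are drawn per size stratum (5–9, 10–20, 21–30 mm); the
lesion mask is a disk; 2–3 trees per lesion are placed either centrally
(within 0.65 R) or in a peripheral annulus (0.74–0.96 R, outside the default
50%-area center region), with the malignant pattern central for small/medium
lesions and peripheral for large ones, and benign the opposite. Root segment
length derives from the space each tree has in its band, so trees fill the
band without piling up. Everything is driven by one `numpy` Generator:
identical arguments and seed give byte-identical rasters.

What the generator does **not** emulate: ultrasound physics (no speckle,
clutter, flow sensitivity or beamforming), 3-D structure and its projection
artifacts, real vessel-radius or angle distributions (no published
distributions exist to fit), anastomoses/loops, or segmentation errors of a
real vessel-enhancement chain. Passing tests therefore demonstrate that the
geometry pipeline measures what it claims on resolvable vessel maps — not
that the biomarkers separate real patient populations.

## Problem sizes used by the tests and acceptance script

Oracle-equivalence suites use trees of ≤ 10 segments (12–16 fixed seeds,
filtered by a ground-truth clearance check that enforces the non-overlap
precondition for exact topology recovery). Effect-direction and model-
dominance checks use a 50 + 50 mixed-size cohort at 0.05 mm/px (~20 s to
generate and extract). The acceptance script builds two medium lesions and
runs the spatial-vascularity computation; it completes in seconds.

## Known limitations

- 2-D only: crossings of physically distinct vessels create degree-4
  junctions that count toward NB and can blur BA in dense networks.
- Diameter quantization: ±0.5 px irreducible raster error; per-branch MD at
  the default spacing is noisy for vessels under ~8 px diameter.
- The VDR center/periphery split assumes a star-shaped (practically convex)
  mask; highly concave masks may erode unevenly.
- Narrow bifurcations (< ~30°) merge for longer than the exclusion zone and
  their BA is biased toward the bisector-fork geometry.
- The logistic layer reports training-data performance; no cross-validation
  is built in.
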