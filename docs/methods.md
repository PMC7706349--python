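# Methods

This note documents the models, algorithms, numerical choices, and known
limitations behind rootscape.

## Segmentation and skeleton measurement

Roots are imaged on blue germination paper.  Segmentation converts RGB to
HSV (hue on a 0–360° scale, no wrap-around handling: reds near 0° count as
foreground) and labels pixels with hue above 175° as background.  When that
rule floods — more than half of the frame reads as foreground, the
signature of an oversaturated background — the frame is converted to Lab
and the lightness channel is thresholded by Otsu's method, taking the
smaller class as the root (roots are thin).  Components under 20 px are
removed as paper-texture noise and the largest connected component is
retained; an empty result raises a `SegmentationError` carrying the
foreground fractions seen under each rule.

Skeletons are medial-axis thinnings.  The skeleton graph connects
8-neighbouring pixels with weights 1 (orthogonal) and √2 (diagonal), and a
diagonal edge is pruned whenever either of its two shared orthogonal
neighbours is also on the skeleton — without this pruning a T-junction
reads as several branch points and path lengths double-count.  Skeleton
length is the sum of edge weights; on a 300 px bar the thinning trims
roughly one pixel per end.

Outlines are Moore-neighbour boundary traces (ordered boundary pixels of
the largest component), returned counter-clockwise (positive shoelace area
with the y axis flipped up).

## Trait definitions

Coordinates are row-major with depth increasing downward.  Conventions
that the trait names do not fully pin down:

* **Primary root path** — the geodesic from the topmost skeleton pixel to
  the deepest reachable pixel (greedy-deepest: among deepest rows, the
  largest geodesic distance).  This matches taproot morphology; on a root
  whose lateral out-grows the taproot tip the path can run through that
  lateral.
* **Depth bands** — "upper one-third" is defined on the depth extent of
  the root system, not the image frame, so cropping does not change band
  traits.  Skeleton edges are banded by their midpoint row.
* **Lateral roots** — LRB counts skeleton graph edges that leave the
  primary path; NLR counts branch nodes (degree ≥ 3) on the path.  LRA
  walks ~20 px into each departing branch and measures the angle of that
  initial direction from the vertical axis (0° = steep, 90° = horizontal);
  the reported value is the median over laterals.
* **Diameter and volume** — local radius is the distance-transform value
  minus half a pixel (floored at half a pixel) to correct the half-pixel
  bias of the transform on thin structures; VOL integrates π r² ds along
  the primary path.
* **Rhizosphere (RHZO)** — the area within 2 mm of the root, computed as
  a background distance-transform threshold (equivalent to disc dilation,
  much cheaper at high resolution).
* **Crossing counts** — MED/MAX are the median/maximum number of distinct
  skeleton pixel runs per occupied image row.
* **Centroid ratios** — COM and the CMT/CMM/CMB band values use the
  mask-pixel centroid depth fraction; COP/CPT/CPM/CPB use the
  skeleton-pixel centroid ("center of point"), a choice the trait names
  leave open.
* **Growth rate** — TRL_GR at day 6 is TRL/6 (germination baseline); at
  later days the difference quotient against the previous recorded day.
  A missing earlier day leaves the rate missing, never zero, and missing
  values propagate as missing through all downstream statistics.

Units are cm-based (px_per_cm supplied with each image); doubling the
raster scale halves every cm-valued trait exactly (tested).

## Random-effects model, BLUPs, heritability

Per trait and day the model is y_ik = μ + g_i + b_k + e_ik with all
factors random.  Variance components are estimated by Henderson-III
quadratic forms: σe² from the residual mean square of the two-factor
fixed-effects fit, and σg² (σb²) from the sequential sum of squares of the
factor adjusted for the other, with the expectation coefficients computed
exactly from projection traces.  Negative solutions truncate to zero
(boundary estimates).  For the balanced designs the study uses (equal
replication, round-robin block assignment) these estimators coincide with
REML; a test cross-checks them against an independent REML optimizer.
The block term enters only when the data contain ≥ 2 blocks.

BLUPs solve Henderson's mixed-model equations at the estimated components
(a dense symmetric solve of size 1 + #genotypes + #blocks); in the
balanced case they reduce to the closed form
ĝ_i = σg²/(σg² + σe²/r) · (ȳ_i − ȳ), which is asserted in tests.
Heritability is entry-mean based, H² = σg²/(σg² + σe²/r), with r the
median replicate count unless given.  Genotype-effect significance uses
the F ratio of the genotype mean square to σe².

Outlier fences are Tukey boxplot fences per (trait, day) across all
genotypes jointly — per-genotype strata of 14 observations make quartiles
unstable.  Removed observations become missing for that trait only.

## Ideotype (iRoot) scoring

Each category is a set of (trait, direction) pairs; genotypes are ranked
per trait (average ranks at ties, missing values last, so the panel stays
intact for the summary tables) and the category score is the rank sum;
lower is better.  Directions: nutrient foraging (WID+, TRL_GR+,
TRLUpper+); drought tolerant (PRL+, LRA−, SOL2−, TRL_GR+); umbrella
(PRL+, WID+, CVA+, LRA+, LED+); beard (TRL+, WID−, LRB+, LRA−, SOL2−,
LED−); maximum (TRL+, PRL+, WID+, CVA+, LRB+, VOL+, RHZO+, Root_weight+).
The beard LED and drought SOL2 directions follow the lower-favorable
convention; definitions ship as editable YAML, so either convention is a
config change.  Scores are invariant to strictly monotone trait
transforms (tested), and the study design restricts scoring to the
9-days-after-germination BLUPs.

## Population genetics

Dosages are minor-allele counts {0, 1, 2} with NaN for missing calls.
Markers with MAF below 0.05 (computed from non-missing calls; exactly
0.05 is retained) or monomorphic are removed.  Individual distance is
allele sharing: similarity per pair is the mean over co-called markers of
(2 − |d_i − d_j|)/2, distance 1 − similarity.  This distance is not
guaranteed metric (triangle-inequality violations are possible); Ward
linkage is applied to it regardless, matching common practice, and
genotype clusters are labeled A.. in dendrogram leaf order.

The cluster count is chosen from a spherical-Gaussian (x-means style) BIC
over k-means fits on the top 10 principal components: the selected k
maximizes the negative second difference of the BIC curve (the point where
improvement stops); a curve whose maximum sits at k = 1, or degenerate
data, returns 1, and a flat curve is flagged.  PCA mean-imputes missing
dosages per marker and centers columns without unit-variance scaling.

Hudson FST per marker is
[(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)] / [p1(1−p2) + p2(1−p1)],
with n the number of genotyped individuals in each group — the convention
of the R implementation the field uses.  For diploids this overcorrects
the sampling term slightly (residual ≈ −1/(2n) on a null split), which is
visible only for small groups.  The mean across markers is the ratio of
the mean numerator to the mean denominator (robust to near-zero
denominators); zero-denominator markers are excluded.  Between-cluster
FST matrices leave pairs with a singleton cluster missing.

## Shape analysis

Closed outlines are decomposed into elliptic Fourier descriptors
(harmonics (a_n, b_n, c_n, d_n) plus offset (A0, C0)).  Two contour
parameterizations are supported: the classic chain arc-length formulation
(default) and a uniform vertex parameter.  The closed-form identity
"an ellipse is exactly one harmonic" holds only in the curve's generating
parameter — under arc length an eccentric ellipse has genuine odd
harmonics (≈ 6% of the first harmonic at 2:1 eccentricity) — so the
closed-form checks use the uniform convention.  Pixel-chain outlines are
near-equally spaced, which makes the two conventions practically
indistinguishable for image-derived shapes.  Truncation error is reported
exactly via Parseval (L2 norm of the tail), so it is non-increasing in
the harmonic count by construction.

A genotype mean shape dilates each replicate mask with a square kernel
(50 px at the reference 100 px/cm scale, scaled with resolution) so the
root becomes one solid blob, extracts and transforms each outline,
averages descriptors coefficient-wise, and reconstructs at 5 harmonics —
the truncation is the smoothing; no separate filter is applied.  Profiles
are aligned with the topmost point at 0 and horizontally centered, which
preserves the up/down anatomy (no rotation normalization; root
orientation is meaningful).

For clustering, mean-shape silhouettes are rasterized to 64×64 binary
images (height mapped to the full side, symmetric width-only padding; a
shape wider than tall is an error) and compressed to 8-dimensional
latents by a convolutional autoencoder implemented in numpy: three
stride-2 3×3 conv blocks (8/16/32 channels) to a dense 8-d bottleneck,
mirrored decoder with nearest-neighbour upsampling, sigmoid output,
binary cross-entropy loss, full-batch Adam (lr 2e-3), default 60 epochs —
the smallest standard design meeting the 8-d latent contract, chosen
because the loss plateaus and family recovery saturates well before 60
epochs on silhouette data.  Training is bit-deterministic per seed.
k-means (Euclidean, 25 restarts, fixed seed) groups the latents; shape
clusters are relabeled A.. by decreasing mean of the members' z-scored
trait values (ties by cluster size), or by size when no scores are given.

## Synthetic study generator

The generator defines the study conditions and is first-class, tested
code.  Phenotypes follow the random-effects model exactly, with
replicates assigned round-robin to blocks and independent draws per
(trait, day); the default 13-trait block uses day-9-scale means with
strong genotypic signal (H² ≈ 0.9 class), mirroring a high-replication
seedling study.  Root images come from a 2-D growth model: the taproot is
a downward random walk (heading noise = tortuosity, clamped to ±45° of
vertical) of arc length elongation-rate × day; laterals are a Poisson
process along it (branches/cm), with emergence angles drawn around a
genotype mean and lengths shrinking linearly toward the tip; rendering
strokes the polylines at a genotype diameter onto a hue-220° background
with a hue-40° foreground, so the segmentation rule is exercised on both
sides of the threshold.  SNPs follow the Balding–Nichols model (ancestral
MAF uniform in a range, subpopulation frequencies Beta-distributed with
differentiation F, dosages binomial).  Shape families are symmetric
width-over-depth profiles (umbrella / beard / drought) with smooth
multiplicative jitter, guaranteeing simple polygons.

All generators are pure functions of (config, seed); per-operation
substreams derive from a master seed by stable hashing, so stages do not
share randomness and runs are bit-reproducible.

What the generator does not emulate: overlapping/crossing roots that
merge in the mask (real images have them; the renderer only approximates
this at high branch densities), illumination gradients, root hairs, paper
texture, 3-D structure projected to 2-D, or realistic soybean allele
frequency spectra and linkage disequilibrium beyond Balding–Nichols
structure.  Passing tests therefore demonstrate correctness of the
measurement and statistics machinery under known ground truth, not
robustness to every artifact of real scans.

## Problem sizes

Tests and the acceptance script run at deliberately chosen sizes:
heritability recovery at the full study design (292 genotypes × 14
replications, 20 simulations); FST consistency at 5,000 markers with
50+50 genotypes; cluster recovery at 8 subpopulations × 15 genotypes and
500 markers (ARI, plus 20 BIC selections); shape-cluster recovery at 3
families × 12 silhouettes over 5 seeds; the orchestration test at a
16-genotype miniature.  These sizes give stable estimates for every
tolerance asserted while keeping a full run in the minutes range on one
CPU.

## Known limitations

* The primary-path heuristic can route through a deep lateral; PRL is
  validated to 5% on clean geometries only.
* ANOVA/Henderson estimation equals REML only for (near-)balanced data;
  strongly unbalanced designs would warrant a dedicated REML optimizer.
* The allele-sharing distance is not metric; Ward on it is a heuristic
  (as in common practice).
* VCF input reads biallelic GT calls only.
* The BIC inflection rule assumes a reasonably sharp elbow; weak
  structure (small F, few markers) degrades both it and cluster recovery.
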