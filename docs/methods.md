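# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each `gastrukit` stage, in the spirit of a methods
supplement: enough detail to reimplement every number the package
produces.

Conventions. Pixel (row *i*, col *j*) has its center at physical
coordinates (x, y) = (j, i)·pixel_size, 0-based. All quantities are in µm
and minutes after loading; calibration is always caller-supplied and
never read from TIFF tags (the acquisitions this pipeline targets come
from several microscopes with different metadata conventions).

## Organoid segmentation

A single organoid is segmented from a smoothed 2-D image (DAPI maximum
projection or brightfield) by a global threshold — Otsu by default, with
MaxEntropy and fixed-value alternatives — followed by largest-component
selection, hole filling, and optional morphological closing. Defaults:
Gaussian σ = 2 px, Otsu. The masking threshold rule is a declared default,
not a measured property of any particular dataset; both it and σ are
exposed in the API and CLI. A mask whose foreground covers more than half
the image border is rejected as a likely segmentation failure. The
`OrganoidMask` invariants — exactly one component, no holes — are enforced
at construction because the profile binning below requires a simply
connected region.

Mask area is pixel count × pixel area. Perimeter and the elongation index
use the sub-pixel marching-squares contour (0.5 level), lightly smoothed
with a 5-point periodic moving average: pixel-edge perimeters overestimate
smooth outlines by ~8–12 % and would bias circularity accordingly. With
this contour a rasterized disk of radius 100 px measures EI ≤ 0.007.

## Medial-axis morphometrics

The body axis is extracted in five steps:

1. **Distance-ridge skeleton** (`skimage.morphology.medial_axis`). The
   thinning-based alternative (`skeletonize`) meanders up to ~7 px around
   the true centerline on thick bodies, which corrupts arc length; the
   distance ridge stays within ~1 px.
2. **Longest geodesic** between skeleton leaves on the 8-connected pixel
   graph, edges weighted by Euclidean step length; ties break toward the
   lexicographically smallest endpoint pixels, and cyclic skeletons fall
   back to a double Dijkstra sweep.
3. **Spur trimming by clearance.** The discrete ridge grows spurs from the
   rounded ends toward boundary staircase corners. Along a spur the
   clearance (distance transform) decays toward 1 px, whereas the true
   axis keeps near-maximal clearance up to the end caps, so each path end
   is trimmed to the first point with clearance ≥ 0.97 of the path
   maximum.
4. **Smoothing and resampling**: 5-point moving average, then equal
   arc-length resampling at ~1 px spacing.
5. **Tangent extension.** At each end, a quadratic in arc length is fitted
   over a window of ~0.9× the maximal clearance (≈ the end-cap radius,
   with a 10-point floor) and the end derivative defines a straight ray,
   extended to the first contour crossing. The window is adaptive because
   a short fixed window makes the tangent hostage to pixel-level jitter:
   an angular error δ displaces the extension endpoint by ≈ r·δ. A fixed
   window remains available (`tangent_points`).

Near-circular masks whose skeleton collapses to ≤ 1 px fall back to the
major inertia axis through the centroid, so a disk reports its diameter.

Validation on rasterized capsules swept along constant-curvature arcs
(length 150–250 µm, cap radius 30–60 µm, arc angle up to 2.5 rad, 1 µm/px):
maximal length error 0.3 % against the closed form arc + 2r, maximal
straightness error 1.6 % against the closed-form chord/arc of the extended
axis. With ±1 px boundary jitter the errors grow to ~1 % and ~8 %
respectively; straightness of strongly bent, noisy organoids is the least
robust quantity in the package.

**Straightness orientation.** S = chord/arc (≤ 1, 1 iff straight). The
inverse convention (arc/chord) is available as a switch; chord/arc is the
default because it makes "straightness approaches 1" mean a straight,
non-deforming organoid.

**Elongation index.** EI = 1 − 4πA/P² from the contour polygon. This is a
deterministic, scale- and rotation-invariant departure-from-circularity
score (disk → 0, elongated → large); it is the package's own definition,
chosen for having a closed form on test shapes.

## AP intensity profiles

The contour is cut at the two axis endpoints (each must lie on the
contour within half a pixel — they do by construction, being ray–contour
intersections). Each open arc is resampled to 101 equal-arc-length
points; quadrilateral bin *i* is (A_i, A_{i+1}, B_{i+1}, B_i). Pixels are
assigned to the bin containing their center (first claim wins where bins
overlap on bent shapes); sliver pixels in no bin go to the nearest bin
center. Bins whose section lines cross are repaired (`buffer(0)`) and
flagged. On random bent capsules the 100 bins tile the mask to ≈ 0.1 %
(3 % is the enforced bound).

**Bin positions.** A bin's axial position is the mean arc-length fraction
of its member pixels projected onto the medial axis, not the uniform grid
(i + ½)/100. The distinction matters: contour-equidistant points advance
faster than the axis across the rounded caps, and section lines tilt on
bent bodies, so the uniform grid misstates where a bin's pixels actually
sit by up to several bins. Pixel-mean projection is self-consistent with
the bin contents; empty sub-pixel bins at the tips receive interpolated
(interior) or locally extrapolated (edge) positions, and rare sub-bin
inversions there are repaired with an isotonic fit. Flat-ended shapes
(e.g. exact rectangles cut at the short-edge midpoints) produce
degenerate zero-width end bins; the method targets round-ended organoid
silhouettes, where this does not arise.

**Normalization.** Per experiment, the cohort-average profile (mean over
organoids per bin) defines low/high anchors as the means of its 10 lowest
and 10 highest bins; every profile is rescaled as (raw − low)/(high − low).
The arithmetic is organized over bin sums so that affine transforms of
integer-valued cohorts (the camera-count case) produce bit-identical
normalized output. Both the number of extreme bins and the grouping are
parameters; "lowest/highest decile of the cohort-average profile" is the
implemented reading of range normalization, chosen for robustness over
per-profile percentiles. A constant cohort has no range and raises.

**Orientation.** Profiles are oriented so the BRA-high end sits at x = 1
(`orient_posterior`); without a BRA channel the caller orients. In tests
on single-channel synthetic markers the profile's own high end is used.

**Boundary calling.** Within a search window (defaults: rising [0.5, 1],
falling [0, 0.5]; both configurable and recorded), the half-max level is
(min + max)/2 of the in-window values, and the crossing in the stated
direction is located by linear interpolation between bin centers; with
several crossings the one nearest the steepest in-window gradient wins.
On noiseless synthetic gradients the recovered crossing sits within
0.4 bins of the painted midpoint; under 10 % multiplicative noise the
median error over a 50-organoid cohort is ≈ 0.002 of axis length. Note
that the *pointwise* profile near a steep midpoint is systematically
flatter than the painted logistic — bin averaging integrates over each
bin's axial spread — which is why round-trip accuracy is stated at the
crossing, not per bin value.

## Pole calling and bootstrap

Visual pole scoring is replaced by an explicit criterion: threshold the
normalized profile at 0.5 and count maximal runs of ≥ 10 consecutive
supra-threshold bins; each run is one pole, reported at its mean position.
Values outside [−0.5, 1.5] flag a likely un-normalized profile (warning,
not error, since cohort normalization of heterogeneous groups can
legitimately exceed 1). On 60 synthetic scenes with 0/1/2 poles and 10 %
noise the classification accuracy is 100 % at these defaults.

The unique-pole fraction uses a nonparametric bootstrap: B = 1000 (tests
use 10 000) resamples of size n with replacement; SE = SD of resampled
proportions; 95 % percentile interval; seed mandatory. At n = 20,
p̂ = 0.75 the bootstrap SE matches the analytic binomial √(p(1−p)/n)
within 5 %.

## Mitotic-density counting

Gaussian σ = 5 px filter → 256-bin histogram of in-mask intensities →
Kapur MaxEntropy threshold → binary map → Euclidean distance transform →
seeds at local maxima of the σ = 1-smoothed distance (minimum separation
5 px, per connected component) → watershed → count objects ≥ 10 px
(min_area_px, configurable). The seed-map smoothing suppresses plateau
maxima of the raw distance ridge that would over-split elongated blobs.
Mean DAPI intensity inside the mask is reported alongside when a DAPI
plane is supplied; density = count / mask area.

The Kapur threshold maximizes H_bg + H_fg, the summed Shannon entropies
of the below- and above-threshold histogram classes, with ties broken
toward the lowest level and class occupancy decided on exact counts
(a probability cumsum can round to just below 1 and admit an empty
foreground). It is verified against an exhaustive plain-loop search on
random histograms. Whether intensities should be rescaled to 8-bit first
is acquisition-dependent; the histogram bin count is a parameter
(default 256).

## Track statistics

Tracks (strictly increasing timestamps, ≥ 2 points, sampling uniformity
checked to 1 %) are filtered to 10–25 time points inclusive — the length
band in which manually curated light-sheet tracks are reliable. Features:

- mean speed = total 3-D path length / duration;
- confinement ratio = net displacement / path length ∈ [0, 1];
- directional change rate = mean unsigned angle between consecutive steps
  per minute (zero-length steps are skipped and flagged);
- MSD(k·Δt) = mean over all ordered pairs at lag k of the squared 3-D
  displacement (time-averaged, all-pairs); `dims=2` projects to xy first.

D and α come from least squares on log MSD = log(2·dims·D) + α·log τ over
lags ≤ 25 % of track duration (long-lag MSD values average few pairs and
are high-variance). The ensemble curve is the mean of per-track MSDs at
shared lags, fitted the same way. With 50 Brownian tracks × 25 points at
D = 0.01 µm²/min, Δt = 20 min, the ensemble fit recovers D within 20 %
and α within [0.85, 1.15]; ballistic tracks give α = 2 and confinement 1
to machine precision. Localization noise adds a constant 2·dims·σ² offset
to the MSD that the pure power law does not model, biasing α down and D
up; parameter-recovery validation therefore uses noise-free tracks, and
fits on noisy data should be read as effective exponents. No interpolation
is performed across the coarse z-step; statistics are unit-true in 3-D.

## Mask-series motion

Per frame: centroid (foreground mean position) and effective radius
r = √(A/π). Radial growth rate = OLS slope of r(t), requiring ≥ 3 frames.
A 25-frame series at 30-min intervals with growth 0.015 µm/min and ±1 px
boundary jitter recovers the rate within 1 % (5 % is the enforced bound):
the jitter is near-area-preserving, and the slope averages it over the
12.5-h span.

## Synthetic scenes

The generator emulates the study conditions, not photorealism:

- **Silhouettes**: capsules swept along constant-curvature arcs
  (defaults 200 µm centerline, 50 µm caps — a 120-h gastruloid scale),
  rasterized from the signed distance to the centerline; truth length
  arc + 2r and truth straightness chord/arc of the tangent-extended axis
  are closed-form. Optional smooth boundary jitter (Gaussian field,
  σ = 3 px correlation) at ±1 px default amplitude when enabled.
- **Markers**: per-pixel intensity = sum of logistic components of the
  pixel's axial coordinate (steepness 20, amplitude 1 by default) ×
  (1 + 0.1·N(0,1)) multiplicative noise, clipped at 0. Midpoints are the
  truth boundaries; the component count is the truth pole multiplicity.
- **Nuclei planes**: Gaussian spots (σ = 4 px, amplitude 1000 over
  background 10, additive noise SD 2) at rejection-sampled in-mask
  centers with 20 px minimum separation; explicit centers supported for
  constructed touching cases.
- **Tracks**: Brownian (per-axis step variance 2DΔt), ballistic (random
  fixed direction), or confined (Ornstein–Uhlenbeck toward the origin
  with stationary per-axis variance L²/3); 0.3 µm localization noise by
  default, Δt = 20 min, 25 points.
- **Timelapses**: disks with linear radial growth and constant centroid
  drift, re-rasterized per frame with optional boundary jitter.

Every scene's randomness comes from one `numpy.random.default_rng(seed)`;
regeneration is bit-identical. What the generator does *not* emulate —
optical PSF and shot noise, intensity attenuation with depth, multipolar
or branching morphologies, organoid-to-organoid texture — bounds what
green tests mean: they certify the measurement chain on known geometry
and noise of realistic magnitude, not performance on raw microscope data.

## Numerical choices and degenerate inputs

Ties in the skeleton longest path break lexicographically; the Kapur
argmax takes the lowest level; empty profile bins are imputed by neighbor
interpolation and flagged; stationary tracks yield speed 0 with
confinement and MSD fits flagged degenerate rather than raised;
single-level histograms in the density analysis yield count 0 for a blank
plane but raise for `kapur_threshold` called directly; bootstrap of a
constant outcome vector returns SE 0 with a point interval. Record files
round-trip floats at 17 significant digits (≤ 1e-9 relative error).

## Known limitations

- Straightness degrades to ~8 % error on strongly bent organoids with
  ±1 px boundary noise (endpoint extension is the dominant error term).
- The contour binning assumes a simply connected, round-ended silhouette;
  flat ends produce degenerate end bins, and strongly non-convex shapes
  get crossing section lines (flagged, repaired, but less trustworthy).
- Pole calling operates on 1-D profiles; two poles on the same axis end,
  or off-axis poles, are outside its design.
- The MSD fit has no localization-noise offset term by design; see above.
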