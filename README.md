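# gastrukit

Quantitative image analysis of gastruloid morphogenesis.

Gastruloids are three-dimensional aggregates of embryonic stem cells that
self-organize an anteroposterior (AP) body axis. Experiments that embed
them in hydrogels of controlled stiffness ask quantitative questions —
how long and how straight is the body axis, where do marker expression
boundaries sit along it, what fraction of organoids forms a unique
BRA/SOX2 pole, how dense are dividing cells, how motile are single cells —
that all reduce to measurements on microscopy images and cell tracks.
`gastrukit` implements that measurement stack as a tested, reusable
library and CLI, together with a synthetic-scene generator that provides
exact ground truth for every stage, so the whole pipeline is verifiable
without access to microscope data.

## What it computes

**Morphometrics** (`gastrukit.morphometry`). From a binary organoid mask:
the body-axis length *L* (arc length of the pruned medial axis, extended
at both ends by straight tangent rays to the contour), the straightness
ratio *S* = chord/arc of that axis (*S* = 1 for a straight organoid), the
elongation index EI = 1 − 4π·A/P² (complement of circularity; 0 for a
disk), and the aspect ratio of the inertia-equivalent ellipse. From mask
time series: centroid trajectories and the radial growth rate, the OLS
slope of the effective radius r(t) = √(A(t)/π) in µm/min.

**AP intensity profiles** (`gastrukit.profiles`). The contour is cut at
the two axis endpoints; each side is subdivided into 100 equal-arc-length
segments, and corresponding point pairs bound 100 quadrilateral bins that
tile the mask. Mean marker intensity per bin, placed at the bin's mean
axial position x ∈ (0, 1), gives the 100-bin profile. Profiles are
normalized per experiment against the cohort-average profile's lowest and
highest decile of bins, and marker boundaries are called where the
normalized profile crosses half-max within a search window.

**Pole scoring** (`gastrukit.polarization`). A pole is a run of ≥ 10
consecutive bins above 0.5 on the normalized profile; the unique-pole
fraction of a group is estimated with a bootstrap standard error and
percentile confidence interval.

**Mitotic density** (`gastrukit.segmentation`). In a single marker plane
(e.g. phospho-histone H3): Gaussian filter (σ = 5 px), MaxEntropy (Kapur)
threshold of in-mask intensities, distance-transform watershed to split
touching nuclei, object count ≥ 10 px → dividing-cell density per µm².

**Track statistics** (`gastrukit.tracking`). For 3-D single-cell tracks
(TrackMate CSV dialect), filtered to 10–25 time points: mean speed,
confinement ratio (net/total displacement), mean directional change rate,
and the time-averaged all-pairs MSD with a power-law fit
MSD(τ) = 2·dims·D·τ^α giving the diffusion coefficient D (µm²/min) and
exponent α.

**Synthetic scenes** (`gastrukit.synthetic`). Capsules swept along
constant-curvature arcs with known length and straightness, logistic
marker gradients with known boundary positions and pole multiplicity,
Gaussian nuclei planes with known counts, Brownian/ballistic/confined
tracks with known D, v and α, and growing/drifting disk timelapses with
known rate — all bit-reproducible from (parameters, seed).

## Worked example

Generate a straight capsule organoid (200 µm centerline, 50 µm caps) and
measure it:

```sh
gastrukit simulate organoid --out-dir sim --seed 3 --pixel-size 1.0 \
    --length 200 --radius 50
gastrukit morphometry sim/mask.tif --out morph.csv --pixel-size 1.0
```

which logs

```
INFO gastrukit: mask.tif: L=299.8 µm S=1.000 EI=0.312 AR=2.89
```

The analytic values for this shape are L = 200 + 2·50 = 300 µm (the
tangent extension adds one cap radius per end), S = 1 (straight axis),
and EI = 1 − 4π(2ra + πr²)/(2a + 2πr)² = 0.3137 with a = 4r — the
measurements land within 0.1 %, 10⁻⁴ and 0.7 % of them respectively.
`morph.csv` carries the same numbers plus area and perimeter under a
provenance header (package version, config hash).

The same stages compose in Python:

```python
from gastrukit import (medial_axis, straightness, bin_mask, extract_profile,
                       normalize_cohort, boundary_position)
from gastrukit.synthetic import make_organoid_mask, make_marker_image, LogisticComponent

mask, truth = make_organoid_mask(250, 40, curvature=0.002, pixel_size_um=1.0, seed=4)
image, _ = make_marker_image(mask, truth.axis_um, [LogisticComponent(midpoint=0.6)],
                             noise_sigma=0.0, seed=5)
path = medial_axis(mask)
profile = extract_profile(image, bin_mask(mask, path), path, mask)
```

`boundary_position(profile, "rising", (0.05, 0.95)).x_b` returns 0.5993
for the painted midpoint 0.6 — under a tenth of a bin.

## CLI

Subcommands: `simulate`, `segment`, `morphometry`, `motion`, `profiles`,
`poles`, `tracks`, `density`, and `run` (multi-stage TOML config). Every
output table starts with `#` comment lines recording the package version,
a hash of the effective parameters, and the seed. See
`gastrukit --help`.
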