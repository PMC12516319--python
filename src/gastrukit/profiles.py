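"""Anteroposterior intensity profiles: contour binning, extraction,
cohort normalization, and half-max boundary calling.

The organoid contour is cut at the two medial-axis endpoints, each side is
subdivided into 100 equal-arc-length segments (101 points), and pairs of
equivalent points across the two sides bound 100 quadrilateral bins that
tile the mask from end A to end B. Each bin's mean marker intensity, placed
at its relative axial position x in (0, 1), forms the 100-bin AP profile.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.optimize import isotonic_regression
from scipy.spatial import cKDTree
from shapely import Polygon

from ._geometry import cut_ring, resample_polyline
from .morphometry import MedialAxisPath
from .segmentation import OrganoidMask

N_BINS = 100


@dataclass(eq=False)
class ContourBinning:
    """The 100-bin quadrilateral tiling of one organoid mask."""

    side_a: np.ndarray  # (101, 2) µm, end A -> end B
    side_b: np.ndarray  # (101, 2) µm, same orientation
    polygons: list[Polygon]
    crossed_bins: list[int]  # indices whose section lines cross (flagged)
    pixel_size_um: float

    def bin_areas_um2(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons])

    def label_map(self, mask: OrganoidMask) -> np.ndarray:
        """Assign each foreground pixel center to a bin; -1 = background.

        Pixels falling in no bin polygon (discretization slivers at the
        contour) are assigned to the bin with the nearest centroid.
        """
        labels = np.full(mask.pixels.shape, -1, dtype=int)
        rows, cols = np.nonzero(mask.pixels)
        x = cols * self.pixel_size_um
        y = rows * self.pixel_size_um
        unassigned = np.ones(len(rows), dtype=bool)
        for i, poly in enumerate(self.polygons):
            if not unassigned.any():
                break
            minx, miny, maxx, maxy = poly.bounds
            cand = unassigned & (x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy)
            idx = np.nonzero(cand)[0]
            if not len(idx):
                continue
            inside = shapely.contains_xy(poly, x[idx], y[idx])
            hit = idx[inside]
            labels[rows[hit], cols[hit]] = i
            unassigned[hit] = False
        if unassigned.any():
            # corner-mean centers: finite even for degenerate repaired bins
            centroids = (
                self.side_a[:-1] + self.side_a[1:] + self.side_b[:-1] + self.side_b[1:]
            ) / 4.0
            tree = cKDTree(centroids)
            idx = np.nonzero(unassigned)[0]
            nearest = tree.query(np.column_stack([x[idx], y[idx]]))[1]
            labels[rows[idx], cols[idx]] = nearest
        return labels


@dataclass
class IntensityProfile:
    """100-bin AP intensity profile of one organoid and channel."""

    positions: np.ndarray  # bin centers, relative axial position in (0, 1)
    raw: np.ndarray  # mean intensity per bin (a.u.)
    normalized: np.ndarray | None = None
    organoid_id: str | None = None
    channel: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.positions.shape != self.raw.shape:
            raise ValueError("positions and raw must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def values(self) -> np.ndarray:
        """Normalized values when available, else raw."""
        return self.normalized if self.normalized is not None else self.raw

    def reversed(self) -> "IntensityProfile":
        """Mirror the profile: data at x moves to 1 - x (exactly)."""
        return replace(
            self,
            positions=1.0 - self.positions[::-1],
            raw=self.raw[::-1].copy(),
            normalized=None if self.normalized is None else self.normalized[::-1].copy(),
            flags=list(self.flags),
        )


@dataclass
class NormalizationAnchors:
    """Low/high intensity anchors of one experiment's cohort."""

    low: float
    high: float
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError("anchors require high > low")


@dataclass
class BoundaryPosition:
    """Relative axial position of a half-max expression boundary."""

    x_b: float
    direction: str
    channel: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_b <= 1.0:
            raise ValueError("boundary position must lie in [0, 1]")


def split_contour(
    mask: OrganoidMask, medial_path: MedialAxisPath, n_points: int = N_BINS + 1
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the contour at the axis endpoints into two resampled sides.

    Each side runs from end A to end B with ``n_points`` equidistant
    (arc-length) points. The axis endpoints must lie on the contour within
    half a pixel.
    """
    contour = mask.contour_um
    p1, p2 = medial_path.endpoints
    line = shapely.LineString(np.vstack([contour, contour[:1]]))
    tol = 0.5 * mask.pixel_size_um
    for p in (p1, p2):
        if line.distance(shapely.Point(p)) > tol:
            raise ValueError("axis endpoint lies off the contour by more than half a pixel")
    arc1, arc2 = cut_ring(contour, p1, p2)
    side_a = resample_polyline(arc1, n_points)
    side_b = resample_polyline(arc2, n_points)
    return side_a, side_b


def make_bins(
    side_a: np.ndarray, side_b: np.ndarray, pixel_size_um: float
) -> ContourBinning:
    """Build the 100 quadrilateral bins from two 101-point contour sides.

    Bin i is the quadrilateral (A_i, A_i+1, B_i+1, B_i). Bins whose section
    lines cross (self-intersecting quadrilateral, pathological shapes) are
    flagged in ``crossed_bins``.
    """
    side_a = np.asarray(side_a, dtype=float)
    side_b = np.asarray(side_b, dtype=float)
    if side_a.shape != side_b.shape or side_a.ndim != 2 or len(side_a) < 2:
        raise ValueError("sides must be equal-length (n, 2) arrays")
    polygons: list[Polygon] = []
    crossed: list[int] = []
    for i in range(len(side_a) - 1):
        quad = Polygon([side_a[i], side_a[i + 1], side_b[i + 1], side_b[i]])
        if not quad.is_valid:
            crossed.append(i)
            quad = quad.buffer(0)  # valid (possibly multi-lobed) repair
            if quad.geom_type != "Polygon":
                quad = max(quad.geoms, key=lambda g: g.area)
        polygons.append(quad)
    if crossed:
        warnings.warn(f"{len(crossed)} bin(s) have crossing section lines")
    return ContourBinning(side_a, side_b, polygons, crossed, pixel_size_um)


def bin_mask(mask: OrganoidMask, medial_path: MedialAxisPath) -> ContourBinning:
    """Convenience: split the contour and build the bins in one call."""
    side_a, side_b = split_contour(mask, medial_path)
    return make_bins(side_a, side_b, mask.pixel_size_um)


def _axial_positions(
    labels: np.ndarray,
    n_bins: int,
    medial_path: MedialAxisPath,
    pixel_size_um: float,
) -> np.ndarray | None:
    """Relative axial position of each bin, by projecting its pixels.

    Every pixel of a bin is projected onto the medial axis and the bin's
    position is the mean arc-length fraction of its members. This stays
    consistent with the bin contents even where the section lines tilt on
    bent organoids (a fixed uniform grid can be off by several bins
    there). Returns None when the result is not strictly increasing.
    """
    dense = resample_polyline(medial_path.points, 2048)
    frac = np.linspace(0.0, 1.0, len(dense))
    tree = cKDTree(dense)
    rows, cols = np.nonzero(labels >= 0)
    pts = np.column_stack([cols, rows]) * pixel_size_um
    s = frac[tree.query(pts)[1]]
    lbl = labels[rows, cols]
    sums = np.bincount(lbl, weights=s, minlength=n_bins)
    counts = np.bincount(lbl, minlength=n_bins)
    good = np.nonzero(counts > 0)[0]
    if len(good) < 2:
        return None
    positions = np.full(n_bins, np.nan)
    positions[good] = sums[good] / counts[good]
    empty = np.nonzero(counts == 0)[0]
    if len(empty):
        # sub-pixel sliver bins at the organoid tips: interpolate interior
        # gaps, extrapolate edge gaps from the local slope
        positions[empty] = np.interp(empty, good, positions[good])
        slope_lo = (positions[good[1]] - positions[good[0]]) / (good[1] - good[0])
        slope_hi = (positions[good[-1]] - positions[good[-2]]) / (good[-1] - good[-2])
        for idx in empty[empty < good[0]]:
            positions[idx] = positions[good[0]] - slope_lo * (good[0] - idx)
        for idx in empty[empty > good[-1]]:
            positions[idx] = positions[good[-1]] + slope_hi * (idx - good[-1])
    if np.any(np.diff(positions) <= 0):
        # tiny sliver bins at the tips can locally invert; repair with an
        # isotonic (monotone least-squares) fit and break residual ties
        positions = isotonic_regression(positions, increasing=True).x
        positions = positions + np.arange(n_bins) * 1e-9
        if np.any(np.diff(positions) <= 0):
            return None
    return positions


def extract_profile(
    image: np.ndarray,
    binning: ContourBinning,
    medial_path: MedialAxisPath,
    mask: OrganoidMask,
    *,
    organoid_id: str | None = None,
    channel: str | None = None,
) -> IntensityProfile:
    """Mean intensity per bin along the axis, as an IntensityProfile.

    Positions are the cumulative medial-axis arc length at bin centers
    normalized by L: each bin's section midpoints are projected onto the
    axis, which corrects the axial compression of contour-equidistant bins
    over the rounded organoid ends (up to ~1 bin at mid-axis). Should the
    projected positions be non-monotone (pathological geometry) the uniform
    grid (i + 1/2)/100 is used instead and flagged. Empty bins (possible at
    sub-pixel-thin tips) are imputed by neighbor averaging and flagged.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != mask.pixels.shape:
        raise ValueError("image and mask shapes differ")
    labels = binning.label_map(mask)
    n_bins = len(binning.polygons)
    flat = labels.ravel()
    inside = flat >= 0
    sums = np.bincount(flat[inside], weights=image.ravel()[inside], minlength=n_bins)
    counts = np.bincount(flat[inside], minlength=n_bins)
    raw = np.full(n_bins, np.nan)
    nonzero = counts > 0
    raw[nonzero] = sums[nonzero] / counts[nonzero]
    flags = []
    if not nonzero.all():
        empty = np.nonzero(~nonzero)[0]
        good = np.nonzero(nonzero)[0]
        raw[empty] = np.interp(empty, good, raw[good])
        flags.append(f"imputed empty bins: {empty.tolist()}")
    positions = _axial_positions(labels, n_bins, medial_path, mask.pixel_size_um)
    if positions is None:
        positions = (np.arange(n_bins) + 0.5) / n_bins
        flags.append("non-monotone axial projection: uniform positions used")
    return IntensityProfile(
        positions=positions, raw=raw, organoid_id=organoid_id, channel=channel, flags=flags
    )


def orient_posterior(
    profiles: dict[str, IntensityProfile], by: str = "BRA"
) -> dict[str, IntensityProfile]:
    """Orient one organoid's profiles so the ``by``-high end sits at x = 1.

    The marker (BRA by default) labels the posterior pole; if its mean raw
    intensity over the posterior half is below the anterior half, all
    channels are mirrored together.
    """
    if by not in profiles:
        raise ValueError(f"orientation channel {by!r} not among profiles")
    ref = profiles[by].raw
    half = len(ref) // 2
    if ref[half:].mean() >= ref[:half].mean():
        return profiles
    return {name: prof.reversed() for name, prof in profiles.items()}


def normalize_cohort(
    profiles: list[IntensityProfile],
    *,
    n_extreme: int = 10,
    experiment_id: str | None = None,
) -> tuple[list[IntensityProfile], NormalizationAnchors]:
    """Scale an experiment's profiles by its cohort-average decile anchors.

    The cohort-average profile (mean over organoids, per bin) defines
    low = mean of its ``n_extreme`` lowest bins and high = mean of its
    ``n_extreme`` highest bins; every profile is rescaled as
    (raw - low)/(high - low). Raises ValueError on a flat cohort.
    """
    if len(profiles) < 2:
        raise ValueError("cohort normalization needs at least 2 profiles")
    stack = np.vstack([p.raw for p in profiles])
    # work with bin sums rather than means: the rescaling
    # (raw - low)/(high - low) is computed as
    # (m*n*raw - sum_low*m)/(sum_high*m - sum_low*m) with integer-exact
    # numerators, so affine transforms of integer-valued cohorts
    # normalize bit-identically
    m = stack.shape[0]
    col_sums = np.sort(stack.sum(axis=0))
    sum_low = float(col_sums[:n_extreme].sum())
    sum_high = float(col_sums[-n_extreme:].sum())
    low = sum_low / (n_extreme * m)
    high = sum_high / (n_extreme * m)
    if not high > low:
        raise ValueError("flat cohort: high anchor does not exceed low anchor")
    anchors = NormalizationAnchors(low=low, high=high, experiment_id=experiment_id)
    scale = n_extreme * m
    out = [
        replace(
            p,
            positions=p.positions.copy(),
            raw=p.raw.copy(),
            normalized=(scale * p.raw - sum_low) / (sum_high - sum_low),
            flags=list(p.flags),
        )
        for p in profiles
    ]
    return out, anchors


def boundary_position(
    profile: IntensityProfile | np.ndarray,
    direction: str = "rising",
    search_window: tuple[float, float] | None = None,
    *,
    channel: str | None = None,
) -> BoundaryPosition:
    """Half-max boundary of a (normalized) profile within a search window.

    Within the window the profile's half-max level is (min + max)/2 of the
    in-window values; the crossing in the stated direction is located by
    linear interpolation between bin centers. With several crossings the
    one nearest the window's steepest gradient is returned. Default
    windows: rising (posterior markers) [0.5, 1], falling (anterior) [0, 0.5].
    """
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    if isinstance(profile, IntensityProfile):
        positions, values = profile.positions, profile.values
        channel = channel or profile.channel
    else:
        values = np.asarray(profile, dtype=float)
        positions = (np.arange(len(values)) + 0.5) / len(values)
    if search_window is None:
        search_window = (0.5, 1.0) if direction == "rising" else (0.0, 0.5)
    lo, hi = search_window
    sel = np.nonzero((positions >= lo) & (positions <= hi))[0]
    if len(sel) < 2:
        raise ValueError("search window covers fewer than 2 bins")
    v = values[sel]
    x = positions[sel]
    half = (v.min() + v.max()) / 2.0
    diffs = np.diff(v)
    crossings = []
    for i in range(len(v) - 1):
        if direction == "rising" and v[i] <= half < v[i + 1]:
            frac = (half - v[i]) / (v[i + 1] - v[i])
            crossings.append((x[i] + frac * (x[i + 1] - x[i]), i))
        elif direction == "falling" and v[i] >= half > v[i + 1]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            crossings.append((x[i] + frac * (x[i + 1] - x[i]), i))
    if not crossings:
        raise ValueError("no half-max crossing in the search window")
    steep = int(np.argmax(diffs)) if direction == "rising" else int(np.argmin(diffs))
    x_steep = (x[steep] + x[steep + 1]) / 2.0
    x_b = min(crossings, key=lambda c: abs((c[0]) - x_steep))[0]
    return BoundaryPosition(x_b=float(np.clip(x_b, 0.0, 1.0)), direction=direction, channel=channel)
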