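"""Synthetic scene generators with exact ground truth for every pipeline
stage: organoid silhouettes, marker gradients, nuclei planes, cell tracks,
and growing/drifting mask timelapses.

Every generator takes an explicit seed, draws all randomness from a single
``numpy.random.default_rng(seed)``, and returns a SceneTruth carrying the
parameters and the analytically known quantities the pipeline is supposed
to recover. Regeneration from (parameters, seed) is bit-identical.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure

from ._geometry import polyline_length, resample_polyline
from .io import TrackTable
from .segmentation import OrganoidMask


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth attached to one generated scene."""

    kind: str
    seed: int
    params: dict
    length_um: float | None = None
    straightness: float | None = None
    axis_um: np.ndarray | None = None  # true extended body axis polyline
    boundary_positions: dict | None = None
    pole_count: int | None = None
    n_spots: int | None = None
    spot_centers_px: np.ndarray | None = None
    model: str | None = None
    D_um2_per_min: float | None = None
    v_um_per_min: float | None = None
    growth_rate_um_per_min: float | None = None
    drift_um_per_frame: tuple[float, float] | None = None
    radii_um: np.ndarray | None = None


@dataclass(frozen=True)
class LogisticComponent:
    """One logistic marker-gradient component along the axis.

    ``direction="rising"`` means expression increases toward x = 1 (a
    posterior marker like BRA); "falling" decreases (anterior, like FOXC1).
    The midpoint is the half-max boundary position.
    """

    midpoint: float
    steepness: float = 20.0
    amplitude: float = 1.0
    direction: str = "rising"

    def __post_init__(self) -> None:
        if not 0.0 < self.midpoint < 1.0:
            raise ValueError("midpoint must lie in (0, 1)")
        if self.direction not in ("rising", "falling"):
            raise ValueError("direction must be 'rising' or 'falling'")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        sign = 1.0 if self.direction == "rising" else -1.0
        return self.amplitude / (1.0 + np.exp(-sign * self.steepness * (x - self.midpoint)))


def _capsule_axis(
    centerline_length_um: float, cap_radius_um: float, curvature: float, n: int = 512
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Constant-curvature centerline plus tangent extensions.

    Returns (centerline, extended axis, true length, true straightness)
    before any rotation/translation. Curvature is 1/µm (signed).
    """
    a, r = centerline_length_um, cap_radius_um
    s = np.linspace(0.0, a, n)
    if abs(curvature) < 1e-12:
        center = np.column_stack([s, np.zeros_like(s)])
        t0 = np.array([1.0, 0.0])
        t1 = np.array([1.0, 0.0])
    else:
        k = curvature
        center = np.column_stack([np.sin(k * s) / k, (1.0 - np.cos(k * s)) / k])
        t0 = np.array([1.0, 0.0])
        t1 = np.array([math.cos(k * a), math.sin(k * a)])
    ext = np.vstack([center[0] - r * t0, center, center[-1] + r * t1])
    length = a + 2.0 * r
    chord = float(np.hypot(*(ext[-1] - ext[0])))
    return center, ext, length, chord / length


def make_organoid_mask(
    centerline_length_um: float = 200.0,
    cap_radius_um: float = 50.0,
    curvature: float = 0.0,
    pixel_size_um: float = 1.0,
    *,
    orientation_deg: float = 0.0,
    boundary_noise_px: float = 0.0,
    margin_um: float = 6.0,
    seed: int = 0,
) -> tuple[OrganoidMask, SceneTruth]:
    """Rasterize a capsule swept along a constant-curvature arc.

    True length = arc length + 2·cap radius (the tangent extension adds one
    radius per end); true straightness = chord/arc of the extended axis.
    ``boundary_noise_px`` adds a smooth ±1σ jitter field to the boundary.
    Self-overlapping sweeps (cap radius >= bend radius, or arc angle above
    1.75π) are rejected.
    """
    if centerline_length_um <= 0 or cap_radius_um <= 0 or pixel_size_um <= 0:
        raise ValueError("dimensions must be positive")
    # a swept capsule self-overlaps when the tube radius reaches the bend
    # radius or the sweep closes on itself (semicircular sweeps are fine)
    if abs(curvature) > 0:
        bend_radius = 1.0 / abs(curvature)
        if cap_radius_um >= bend_radius:
            raise ValueError("self-intersecting sweep: cap radius exceeds bend radius")
        if abs(curvature) * centerline_length_um > 1.75 * math.pi:
            raise ValueError("self-intersecting sweep: arc angle too large")
    center, ext, true_len, true_straight = _capsule_axis(
        centerline_length_um, cap_radius_um, curvature
    )
    theta = math.radians(orientation_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    center = center @ rot.T
    ext = ext @ rot.T
    pad = cap_radius_um + margin_um + 2.0 * boundary_noise_px * pixel_size_um
    origin = center.min(axis=0) - pad
    center = center - origin
    ext = ext - origin
    extent = center.max(axis=0) + pad
    w = int(math.ceil(extent[0] / pixel_size_um)) + 1
    h = int(math.ceil(extent[1] / pixel_size_um)) + 1
    xs = np.arange(w) * pixel_size_um
    ys = np.arange(h) * pixel_size_um
    gx, gy = np.meshgrid(xs, ys)
    dense = resample_polyline(center, max(2, int(polyline_length(center) / (pixel_size_um / 2)) + 1))
    tree = cKDTree(dense)
    dist = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))[0].reshape(h, w)
    signed = dist - cap_radius_um
    rng = np.random.default_rng(seed)
    if boundary_noise_px > 0:
        noise = ndi.gaussian_filter(rng.standard_normal((h, w)), 3.0)
        noise /= noise.std()
        signed = signed + noise * boundary_noise_px * pixel_size_um
    pixels = signed <= 0
    labels = measure.label(pixels, connectivity=2)
    if labels.max() == 0:
        raise ValueError("degenerate raster: no foreground")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    pixels = ndi.binary_fill_holes(labels == largest)
    mask = OrganoidMask(pixels, pixel_size_um)
    truth = SceneTruth(
        kind="organoid_mask",
        seed=seed,
        params=dict(
            centerline_length_um=centerline_length_um,
            cap_radius_um=cap_radius_um,
            curvature=curvature,
            pixel_size_um=pixel_size_um,
            orientation_deg=orientation_deg,
            boundary_noise_px=boundary_noise_px,
        ),
        length_um=true_len,
        straightness=true_straight,
        axis_um=ext,
    )
    return mask, truth


def make_marker_image(
    mask: OrganoidMask,
    axis_um: np.ndarray,
    components: Sequence[LogisticComponent],
    *,
    noise_sigma: float = 0.1,
    background: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, SceneTruth]:
    """Paint a marker intensity field from an axial profile specification.

    Each in-mask pixel takes the profile value at its axial coordinate (the
    arc-length fraction of the nearest point on the true axis), times a
    multiplicative Gaussian noise factor (1 + σ·N(0,1)), clipped at 0.
    Truth records the component midpoints as boundary positions and the
    component count as the pole multiplicity.
    """
    axis_um = np.asarray(axis_um, dtype=float)
    dense = resample_polyline(axis_um, 2048)
    frac = np.linspace(0.0, 1.0, len(dense))
    tree = cKDTree(dense)
    rows, cols = np.nonzero(mask.pixels)
    pts = np.column_stack([cols, rows]) * mask.pixel_size_um
    nearest = tree.query(pts)[1]
    x = frac[nearest]
    value = np.full(len(x), background)
    for comp in components:
        value = value + comp.evaluate(x)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        value = value * (1.0 + noise_sigma * rng.standard_normal(len(value)))
    image = np.zeros(mask.pixels.shape, dtype=float)
    image[rows, cols] = np.clip(value, 0.0, None)
    truth = SceneTruth(
        kind="marker_image",
        seed=seed,
        params=dict(
            noise_sigma=noise_sigma,
            background=background,
            components=[
                dict(
                    midpoint=c.midpoint,
                    steepness=c.steepness,
                    amplitude=c.amplitude,
                    direction=c.direction,
                )
                for c in components
            ],
        ),
        boundary_positions={"marker": [c.midpoint for c in components]},
        pole_count=len(components),
        axis_um=axis_um,
    )
    return image, truth


def make_nuclei_plane(
    mask: OrganoidMask,
    n_spots: int,
    *,
    spot_sigma_px: float = 4.0,
    min_separation_px: float = 20.0,
    amplitude: float = 1000.0,
    background: float = 10.0,
    noise_sigma: float = 2.0,
    edge_margin_px: float | None = None,
    centers_px: np.ndarray | None = None,
    seed: int = 0,
    max_tries: int = 20000,
) -> tuple[np.ndarray, SceneTruth]:
    """Sum of Gaussian nuclear spots at random in-mask centers.

    Centers are rejection-sampled uniformly over the mask interior (at
    least ``edge_margin_px`` from the boundary, default 2σ + 2) with the
    requested pairwise separation; placement failure after bounded retries
    raises. Pass ``centers_px`` (as (row, col)) to construct deterministic
    near-touching cases.
    """
    h, w = mask.pixels.shape
    if centers_px is not None:
        centers = np.asarray(centers_px, dtype=float)
        if len(centers) != n_spots:
            raise ValueError("centers_px length must equal n_spots")
    elif n_spots == 0:
        centers = np.empty((0, 2))
    else:
        margin = edge_margin_px if edge_margin_px is not None else 2.0 * spot_sigma_px + 2.0
        interior = ndi.distance_transform_edt(mask.pixels) > margin
        candidates = np.argwhere(interior)
        if not len(candidates):
            raise ValueError("mask interior too small for the requested margin")
        rng = np.random.default_rng(seed)
        chosen: list[np.ndarray] = []
        tries = 0
        while len(chosen) < n_spots:
            if tries >= max_tries:
                raise ValueError(
                    f"could not place {n_spots} spots at separation {min_separation_px}"
                )
            tries += 1
            cand = candidates[rng.integers(len(candidates))].astype(float)
            if all(np.hypot(*(cand - c)) >= min_separation_px for c in chosen):
                chosen.append(cand)
        centers = np.array(chosen)
    yy, xx = np.mgrid[0:h, 0:w]
    image = np.full((h, w), background, dtype=float)
    for (r, c) in centers:
        image += amplitude * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * spot_sigma_px**2)
        )
    rng_noise = np.random.default_rng(seed + 1)
    if noise_sigma > 0:
        image = image + noise_sigma * rng_noise.standard_normal((h, w))
    image = np.clip(image, 0.0, None)
    truth = SceneTruth(
        kind="nuclei_plane",
        seed=seed,
        params=dict(
            spot_sigma_px=spot_sigma_px,
            min_separation_px=min_separation_px,
            amplitude=amplitude,
            background=background,
            noise_sigma=noise_sigma,
        ),
        n_spots=int(n_spots),
        spot_centers_px=centers,
    )
    return image, truth


def make_tracks(
    n_tracks: int = 50,
    model: str = "brownian",
    *,
    D_um2_per_min: float = 0.01,
    v_um_per_min: float = 0.05,
    confinement_radius_um: float = 5.0,
    n_points: int = 25,
    dt_min: float = 20.0,
    localization_noise_um: float = 0.3,
    seed: int = 0,
) -> tuple[TrackTable, SceneTruth]:
    """Simulate 3-D tracks with a known motility model.

    brownian: isotropic Gaussian steps with per-axis variance 2·D·dt.
    ballistic: constant velocity of magnitude v along a random direction.
    confined: Ornstein-Uhlenbeck relaxation toward the origin with
    stationary radius ~ confinement_radius (per-axis variance L²/3).
    Localization noise is added independently to every stored position.
    """
    if model not in ("brownian", "ballistic", "confined"):
        raise ValueError(f"unknown track model {model!r}")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if min(D_um2_per_min, v_um_per_min, confinement_radius_um, dt_min) < 0:
        raise ValueError("model parameters must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    t = np.arange(n_points) * dt_min
    for tid in range(n_tracks):
        if model == "brownian":
            steps = rng.normal(0.0, math.sqrt(2.0 * D_um2_per_min * dt_min), (n_points - 1, 3))
            pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        elif model == "ballistic":
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = np.outer(t, direction) * v_um_per_min
        else:  # confined OU
            var = confinement_radius_um**2 / 3.0
            theta = D_um2_per_min / var if var > 0 else 1.0
            decay = math.exp(-theta * dt_min)
            step_sd = math.sqrt(var * (1.0 - decay**2))
            pos = np.empty((n_points, 3))
            pos[0] = rng.normal(0.0, math.sqrt(var), 3)
            for i in range(1, n_points):
                pos[i] = pos[i - 1] * decay + rng.normal(0.0, step_sd, 3)
        if localization_noise_um > 0:
            pos = pos + rng.normal(0.0, localization_noise_um, pos.shape)
        for i in range(n_points):
            rows.append((tid, t[i], pos[i, 0], pos[i, 1], pos[i, 2]))
    df = pd.DataFrame(rows, columns=["track_id", "t_min", "x_um", "y_um", "z_um"])
    table = TrackTable(df)
    truth = SceneTruth(
        kind="tracks",
        seed=seed,
        params=dict(
            n_tracks=n_tracks,
            n_points=n_points,
            dt_min=dt_min,
            localization_noise_um=localization_noise_um,
            confinement_radius_um=confinement_radius_um,
        ),
        model=model,
        D_um2_per_min=D_um2_per_min,
        v_um_per_min=v_um_per_min,
    )
    return table, truth


def make_timelapse(
    initial_radius_um: float = 50.0,
    growth_rate_um_per_min: float = 0.015,
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0),
    *,
    n_frames: int = 25,
    frame_interval_min: float = 30.0,
    pixel_size_um: float = 1.0,
    boundary_noise_px: float = 0.0,
    field_shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, SceneTruth]:
    """Disk mask series with linear radial growth and centroid drift.

    Returns a (t, y, x) boolean array. The field of view is sized to hold
    every frame unless ``field_shape`` is given, in which case a shape
    leaving the field raises ValueError.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    t = np.arange(n_frames) * frame_interval_min
    radii = initial_radius_um + growth_rate_um_per_min * t
    if np.any(radii <= 0):
        raise ValueError("radius must stay positive")
    drift = np.asarray(drift_um_per_frame, dtype=float)
    centers = np.outer(np.arange(n_frames), drift)  # (n, 2) of (x, y) offsets
    pad = radii.max() + 5.0 + 2.0 * boundary_noise_px * pixel_size_um
    origin = centers.min(axis=0) - pad
    centers = centers - origin
    extent = centers.max(axis=0) + pad
    if field_shape is None:
        w = int(math.ceil(extent[0] / pixel_size_um)) + 1
        h = int(math.ceil(extent[1] / pixel_size_um)) + 1
    else:
        h, w = field_shape
        if extent[0] > (w - 1) * pixel_size_um or extent[1] > (h - 1) * pixel_size_um:
            raise ValueError("shape exits the field of view")
    xs = np.arange(w) * pixel_size_um
    ys = np.arange(h) * pixel_size_um
    gx, gy = np.meshgrid(xs, ys)
    rng = np.random.default_rng(seed)
    masks = np.empty((n_frames, h, w), dtype=bool)
    for i in range(n_frames):
        dist = np.hypot(gx - centers[i, 0], gy - centers[i, 1])
        signed = dist - radii[i]
        if boundary_noise_px > 0:
            noise = ndi.gaussian_filter(rng.standard_normal((h, w)), 3.0)
            noise /= noise.std()
            signed = signed + noise * boundary_noise_px * pixel_size_um
        frame = signed <= 0
        labels = measure.label(frame, connectivity=2)
        if labels.max() == 0:
            raise ValueError("degenerate raster: empty frame")
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        masks[i] = ndi.binary_fill_holes(labels == largest)
    truth = SceneTruth(
        kind="timelapse",
        seed=seed,
        params=dict(
            initial_radius_um=initial_radius_um,
            n_frames=n_frames,
            frame_interval_min=frame_interval_min,
            pixel_size_um=pixel_size_um,
            boundary_noise_px=boundary_noise_px,
        ),
        growth_rate_um_per_min=growth_rate_um_per_min,
        drift_um_per_frame=tuple(drift_um_per_frame),
        radii_um=radii,
    )
    return masks, truth
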