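"""Shape descriptors of organoid silhouettes and mask time series.

The body-axis length L is the arc length of the pruned medial axis of the
mask, extended at both ends by straight rays tangent to the axis until they
meet the contour. Straightness is the chord-to-arc ratio of that extended
axis (1 for a straight organoid). The elongation index is the complement of
circularity, EI = 1 - 4πA/P², and the aspect ratio is the major/minor axis
ratio of the inertia-equivalent ellipse.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from ._geometry import (
    polyline_length,
    ray_ring_intersection,
    resample_polyline,
    ring_polygon_area,
    ring_perimeter,
    smooth_polyline,
)
from .segmentation import OrganoidMask

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(eq=False)
class MedialAxisPath:
    """Ordered body-axis polyline in µm, from end A to end B.

    Both endpoints lie on the mask contour (they are the tangent-ray
    intersection points).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("axis polyline needs >= 2 (x, y) points")
        if not self.chord_um > 0:
            raise ValueError("zero-length axis (coincident endpoints)")

    @property
    def length_um(self) -> float:
        return polyline_length(self.points)

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]

    @property
    def chord_um(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))

    def reversed(self) -> "MedialAxisPath":
        return MedialAxisPath(self.points[::-1].copy())


@dataclass
class MorphometricRecord:
    """One organoid's shape descriptors."""

    length_um: float
    straightness: float
    elongation_index: float
    aspect_ratio: float
    area_um2: float
    perimeter_um: float


@dataclass
class TimelapseMotion:
    """Centroid trajectory and radial growth of a mask time series."""

    t_min: np.ndarray
    centroids_um: np.ndarray  # (n, 2) of (x, y)
    total_displacement_um: float
    effective_radius_um: np.ndarray
    radial_growth_rate_um_per_min: float


def _skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    graph = nx.Graph()
    coords = list(map(tuple, np.argwhere(skeleton)))
    graph.add_nodes_from(coords)
    pixel_set = set(coords)
    for (r, c) in coords:
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb in pixel_set and not graph.has_edge((r, c), nb):
                graph.add_edge((r, c), nb, weight=math.hypot(dr, dc))
    return graph


def _longest_geodesic(graph: nx.Graph) -> list[tuple[int, int]]:
    """Longest shortest path between skeleton leaves (weighted).

    Ties break toward the lexicographically smallest endpoint pair. Falls
    back to a double Dijkstra sweep when the skeleton has no leaves (cycle).
    """
    leaves = sorted(n for n in graph.nodes if graph.degree(n) <= 1)
    if len(leaves) < 2:
        start = min(graph.nodes)
        dist = nx.single_source_dijkstra_path_length(graph, start, weight="weight")
        u = min(dist, key=lambda n: (-dist[n], n))
        dist_u = nx.single_source_dijkstra_path_length(graph, u, weight="weight")
        v = min(dist_u, key=lambda n: (-dist_u[n], n))
        if u == v:
            return [u]
        return nx.dijkstra_path(graph, u, v, weight="weight")
    best: tuple[float, tuple, tuple] | None = None
    for i, u in enumerate(leaves):
        dist = nx.single_source_dijkstra_path_length(graph, u, weight="weight")
        for v in leaves[i + 1 :]:
            if v not in dist:
                continue
            cand = (-dist[v], u, v)
            if best is None or cand < best:
                best = cand
    if best is None:  # disconnected skeleton: keep the component of the min leaf
        comp = nx.node_connected_component(graph, leaves[0])
        return _longest_geodesic(graph.subgraph(comp).copy())
    return nx.dijkstra_path(graph, best[1], best[2], weight="weight")


def _end_tangent(path_um: np.ndarray, k: int, at_start: bool) -> np.ndarray:
    """Outward tangent direction at a path end.

    A quadratic in arc length is fitted to the last k points so the tangent
    of a curved axis is the true end derivative, not a secant (a secant
    systematically rotates the extension ray on bent organoids).
    """
    pts = path_um[:k] if at_start else path_um[-k:][::-1]
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    deg = 2 if len(pts) >= 4 else 1
    dx = np.polyder(np.polyfit(s, pts[:, 0], deg))
    dy = np.polyder(np.polyfit(s, pts[:, 1], deg))
    direction = np.array([np.polyval(dx, 0.0), np.polyval(dy, 0.0)])
    return -direction  # s increases inward; outward is the negative


def _trim_spurs(
    path_rc: list[tuple[int, int]], pixels: np.ndarray, clearance_fraction: float = 0.97
) -> list[tuple[int, int]]:
    """Drop low-clearance tail segments of the axis path.

    The discrete distance-ridge grows spurs from the rounded organoid ends
    toward boundary staircase corners; along such a spur the clearance
    (distance to the boundary) decays toward ~1 px, whereas the true body
    axis keeps near-maximal clearance all the way to the end caps. Each
    path end is trimmed up to the first point whose clearance reaches
    ``clearance_fraction`` of the path maximum.
    """
    clearance = ndi.distance_transform_edt(pixels)
    c = clearance[tuple(np.array(path_rc).T)]
    cut = clearance_fraction * c.max()
    good = np.nonzero(c >= cut)[0]
    if not len(good):
        return path_rc
    return path_rc[good[0] : good[-1] + 1]


def _extend_to_contour(
    path_um: np.ndarray, contour: np.ndarray, tangent_points: int, max_len: float
) -> np.ndarray:
    """Prepend/append tangent-ray intersections with the contour."""
    k = min(tangent_points, len(path_um))
    start_dir = _end_tangent(path_um, k, at_start=True)
    end_dir = _end_tangent(path_um, k, at_start=False)
    p_start = ray_ring_intersection(path_um[0], start_dir, contour, max_len)
    p_end = ray_ring_intersection(path_um[-1], end_dir, contour, max_len)
    return np.vstack([p_start, path_um, p_end])


def _fallback_axis(mask: OrganoidMask, max_len: float) -> np.ndarray:
    """Degenerate (near-circular) masks: axis = major inertia axis."""
    props = measure.regionprops(mask.pixels.astype(np.uint8))[0]
    theta = props.orientation  # angle of major axis vs row (y) axis
    direction = np.array([math.sin(theta), math.cos(theta)])  # (dx, dy)
    centroid = np.array(mask.centroid_um)
    p1 = ray_ring_intersection(centroid, direction, mask.contour_um, max_len)
    p2 = ray_ring_intersection(centroid, -direction, mask.contour_um, max_len)
    return np.vstack([p2, centroid, p1])


def medial_axis(
    mask: OrganoidMask,
    *,
    smooth_window: int = 5,
    tangent_points: int | None = None,
) -> MedialAxisPath:
    """Extract the tangent-extended medial axis of an organoid mask.

    Skeletonize (distance ridge) → longest geodesic between skeleton
    endpoints → spur trimming by clearance → moving-average smoothing and
    1-px arc-length resampling → straight tangent extension from each end
    to the contour. Near-circular masks whose skeleton collapses to a
    point fall back to the major inertia axis through the centroid.

    ``tangent_points=None`` sizes the tangent-fit window adaptively to
    ~0.9× the maximal clearance (the end-cap radius), which stabilizes the
    end tangents far better than a fixed short window.
    """
    px = mask.pixel_size_um
    h, w = mask.pixels.shape
    max_len = math.hypot(h, w) * px * 2
    # distance-ridge medial axis: follows the true centerline to ~1 px where
    # thinning-based skeletons can meander by several pixels on thick shapes;
    # fixed rng because the thinning order otherwise breaks ties randomly
    skeleton = morphology.medial_axis(mask.pixels, rng=0)
    if skeleton.sum() < 2:
        return MedialAxisPath(_fallback_axis(mask, max_len))
    path_rc = _longest_geodesic(_skeleton_graph(skeleton))
    if len(path_rc) < 2:
        return MedialAxisPath(_fallback_axis(mask, max_len))
    path_rc = _trim_spurs(path_rc, mask.pixels)
    if len(path_rc) < 2:
        return MedialAxisPath(_fallback_axis(mask, max_len))
    clearance = ndi.distance_transform_edt(mask.pixels)
    r_max_px = float(clearance[tuple(np.array(path_rc).T)].max())
    path_um = np.array([(c * px, r * px) for r, c in path_rc])
    path_um = smooth_polyline(path_um, smooth_window)
    n = max(2, int(polyline_length(path_um) / px) + 1)
    path_um = resample_polyline(path_um, n)
    if tangent_points is None:
        tangent_points = int(np.clip(0.9 * r_max_px, 10, max(10, len(path_um) // 2)))
    extended = _extend_to_contour(path_um, mask.contour_um, tangent_points, max_len)
    return MedialAxisPath(extended)


def straightness(path: MedialAxisPath, orientation: str = "chord-over-arc") -> float:
    """Chord-to-arc ratio of the body axis; 1 iff straight.

    ``orientation="arc-over-chord"`` returns the reciprocal (>= 1) for
    workflows that report the inverse convention.
    """
    arc = path.length_um
    if arc <= 0:
        raise ValueError("zero-length path")
    value = path.chord_um / arc
    if orientation == "chord-over-arc":
        return value
    if orientation == "arc-over-chord":
        return 1.0 / value
    raise ValueError(f"unknown straightness orientation {orientation!r}")


def elongation_index(mask: OrganoidMask) -> float:
    """EI = 1 - 4πA/P² (complement of circularity); 0 for a disk.

    Area and perimeter come from the sub-pixel contour polygon; pixel-edge
    perimeters would bias circularity by ~10%.
    """
    area = ring_polygon_area(mask.contour_um)
    perimeter = ring_perimeter(mask.contour_um)
    if perimeter <= 0:
        raise ValueError("zero perimeter")
    return 1.0 - 4.0 * math.pi * area / perimeter**2


def aspect_ratio(mask: OrganoidMask) -> float:
    """Major/minor axis ratio of the inertia-equivalent ellipse (>= 1)."""
    props = measure.regionprops(mask.pixels.astype(np.uint8))[0]
    minor = props.axis_minor_length
    if minor <= 0:
        raise ValueError("degenerate (collinear) foreground")
    return float(props.axis_major_length / minor)


def morphometric_record(
    mask: OrganoidMask,
    *,
    smooth_window: int = 5,
    tangent_points: int = 10,
    straightness_orientation: str = "chord-over-arc",
) -> MorphometricRecord:
    """All shape descriptors of one mask in a single record."""
    path = medial_axis(mask, smooth_window=smooth_window, tangent_points=tangent_points)
    return MorphometricRecord(
        length_um=path.length_um,
        straightness=straightness(path, straightness_orientation),
        elongation_index=elongation_index(mask),
        aspect_ratio=aspect_ratio(mask),
        area_um2=mask.area_um2,
        perimeter_um=mask.perimeter_um,
    )


def timelapse_motion(
    masks: np.ndarray,
    pixel_size_um: float,
    frame_interval_min: float,
) -> TimelapseMotion:
    """Centroid trajectory, displacement and radial growth of a mask series.

    ``masks`` is a (t, y, x) boolean array at constant calibration. The
    effective radius is r(t) = sqrt(A(t)/π) and the radial growth rate its
    ordinary least-squares slope against time; at least 3 frames required.
    """
    masks = np.asarray(masks).astype(bool)
    if masks.ndim != 3:
        raise ValueError("expected a (t, y, x) mask series")
    n = masks.shape[0]
    if n < 3:
        raise ValueError("need at least 3 frames for a growth-rate slope")
    t = np.arange(n) * frame_interval_min
    centroids = np.empty((n, 2))
    radii = np.empty(n)
    for i, frame in enumerate(masks):
        if not frame.any():
            raise ValueError(f"frame {i} has empty foreground")
        rows, cols = np.nonzero(frame)
        centroids[i] = (cols.mean() * pixel_size_um, rows.mean() * pixel_size_um)
        area = frame.sum() * pixel_size_um**2
        radii[i] = math.sqrt(area / math.pi)
    steps = np.hypot(*np.diff(centroids, axis=0).T)
    slope = float(np.polyfit(t, radii, 1)[0])
    return TimelapseMotion(
        t_min=t,
        centroids_um=centroids,
        total_displacement_um=float(steps.sum()),
        effective_radius_um=radii,
        radial_growth_rate_um_per_min=slope,
    )
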