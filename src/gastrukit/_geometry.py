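"""Shared polyline/contour geometry used by morphometry and profile binning.

Conventions: pixel (row i, col j) has its center at physical coordinates
(x, y) = (j, i) * pixel_size_um; polylines are (n, 2) float arrays of
(x, y) in µm.
"""
from __future__ import annotations

import numpy as np
from shapely import LinearRing, LineString, Point
from shapely.ops import substring
from skimage import measure


def polyline_length(points: np.ndarray) -> float:
    """Arc length of an open polyline."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.hypot(*np.diff(points, axis=0).T).sum())


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to n points equidistant in arc length."""
    points = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(points, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("cannot resample a zero-length polyline")
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack(
        [np.interp(target, s, points[:, 0]), np.interp(target, s, points[:, 1])]
    )


def smooth_polyline(points: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing with edge padding (endpoints stay anchored)."""
    points = np.asarray(points, dtype=float)
    if window <= 1 or len(points) < window:
        return points
    pad = window // 2
    padded = np.pad(points, ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, i], kernel, mode="valid") for i in range(2)]
    )


def _smooth_ring(xy: np.ndarray, window: int) -> np.ndarray:
    """Periodic moving average along a closed ring (no endpoint anchoring)."""
    if window <= 1 or len(xy) < window:
        return xy
    pad = window // 2
    padded = np.concatenate([xy[-pad:], xy, xy[:pad]])
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, i], kernel, mode="valid") for i in range(2)]
    )


def mask_contour(
    pixels: np.ndarray, pixel_size_um: float, smooth_window: int = 5
) -> np.ndarray:
    """Sub-pixel boundary of a binary mask as an open ring of (x, y) µm.

    Marching squares at the 0.5 level; the largest contour is taken and
    lightly smoothed with a periodic moving average to suppress pixel
    staircase noise (which otherwise biases perimeter by several percent).
    The last point is NOT a duplicate of the first.
    """
    contours = measure.find_contours(pixels.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour (empty foreground)")
    ring = max(contours, key=len)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    xy = np.column_stack([ring[:, 1], ring[:, 0]]) * pixel_size_um
    return _smooth_ring(xy, smooth_window)


def ring_polygon_area(ring_xy: np.ndarray) -> float:
    """Shoelace area of a closed ring given as an open point list."""
    x, y = ring_xy[:, 0], ring_xy[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def ring_perimeter(ring_xy: np.ndarray) -> float:
    closed = np.vstack([ring_xy, ring_xy[:1]])
    return polyline_length(closed)


def ray_ring_intersection(
    origin: np.ndarray, direction: np.ndarray, ring_xy: np.ndarray, max_len: float
) -> np.ndarray:
    """First crossing of a ray with a closed ring, beyond the origin.

    Raises ValueError if the ray never meets the ring within max_len.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.hypot(*direction)
    if norm == 0:
        raise ValueError("zero-length tangent direction")
    direction = direction / norm
    ray = LineString([origin, np.asarray(origin) + direction * max_len])
    ring = LinearRing(np.vstack([ring_xy, ring_xy[:1]]))
    inter = ray.intersection(ring)
    pts: list[np.ndarray] = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.is_empty:
            continue
        if isinstance(geom, Point):
            pts.append(np.array([geom.x, geom.y]))
        else:  # collinear overlap: take its vertices
            pts.extend(np.asarray(geom.coords))
    pts = [p for p in pts if np.hypot(*(p - origin)) > 1e-9]
    if not pts:
        raise ValueError("extension ray fails to intersect the contour")
    dists = [np.hypot(*(p - origin)) for p in pts]
    return pts[int(np.argmin(dists))]


def cut_ring(
    ring_xy: np.ndarray, p1: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a closed ring at the projections of p1 and p2 into two open arcs.

    Both returned arcs run from (the projection of) p1 to p2.
    """
    line = LineString(np.vstack([ring_xy, ring_xy[:1]]))
    s1 = line.project(Point(p1))
    s2 = line.project(Point(p2))
    if abs(s1 - s2) < 1e-9 or abs(abs(s1 - s2) - line.length) < 1e-9:
        raise ValueError("cut points coincide on the contour")
    swap = s1 > s2
    if swap:
        s1, s2 = s2, s1
    arc1 = np.asarray(substring(line, s1, s2).coords)
    part_a = np.asarray(substring(line, s2, line.length).coords)
    part_b = np.asarray(substring(line, 0.0, s1).coords)
    arc2 = np.vstack([part_a, part_b[1:]])[::-1]  # runs s1 -> s2 the other way
    if swap:  # make both arcs run p1 -> p2
        arc1 = arc1[::-1]
        arc2 = arc2[::-1]
    return arc1, arc2
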