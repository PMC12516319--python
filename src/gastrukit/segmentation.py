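"""Organoid mask segmentation and mitotic-nucleus density counting.

The organoid silhouette is obtained from a smoothed brightfield or DAPI
projection by global thresholding (Otsu by default), keeping the largest
connected component and filling holes. Mitotic (H3S10P-high) nuclei in a
single plane are counted by Gaussian filtering (σ = 5 px), MaxEntropy
(Kapur) thresholding of in-mask intensities, and a distance-transform
watershed that splits touching nuclei — the ImageJ-style workflow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from ._geometry import mask_contour, ring_perimeter
from .io import ImageStack


@dataclass(eq=False)
class OrganoidMask:
    """Binary silhouette of one organoid with its calibration.

    Invariants (checked on construction): exactly one connected foreground
    component, no holes, non-empty.
    """

    pixels: np.ndarray
    pixel_size_um: float
    contour_smooth_window: int = 5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.pixels.any():
            raise ValueError("empty foreground")
        n_comp = measure.label(self.pixels, connectivity=2).max()
        if n_comp != 1:
            raise ValueError(f"mask must have exactly one component, found {n_comp}")
        if not np.array_equal(ndi.binary_fill_holes(self.pixels), self.pixels):
            raise ValueError("mask must not contain holes")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2

    @property
    def centroid_um(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.pixels)
        return (
            float(cols.mean()) * self.pixel_size_um,
            float(rows.mean()) * self.pixel_size_um,
        )

    @cached_property
    def contour_um(self) -> np.ndarray:
        """Sub-pixel boundary polygon, (n, 2) of (x, y) µm, open ring."""
        return mask_contour(self.pixels, self.pixel_size_um, self.contour_smooth_window)

    @property
    def perimeter_um(self) -> float:
        return ring_perimeter(self.contour_um)


@dataclass
class DensityRecord:
    """Per-slice cell-density readout: mean DAPI level and mitotic count."""

    mitotic_count: int
    slice_area_um2: float
    mitotic_density_per_um2: float
    mean_dapi_intensity: float = math.nan
    threshold: float = math.nan

    def __post_init__(self) -> None:
        if self.mitotic_count < 0:
            raise ValueError("mitotic_count must be >= 0")


def max_projection(stack: ImageStack, t: int = 0) -> np.ndarray:
    """Maximum-intensity projection over z; returns a (c, y, x) array."""
    return stack.data[t].max(axis=0)


def kapur_threshold(histogram: np.ndarray) -> int:
    """MaxEntropy (Kapur) threshold on an intensity histogram.

    Returns the level t maximizing the sum of the Shannon entropies of the
    background (levels <= t) and foreground (levels > t) distributions.
    Ties are broken toward the lowest qualifying level. Raises ValueError
    with fewer than two nonzero bins.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if int((h > 0).sum()) < 2:
        raise ValueError("histogram needs at least 2 nonzero bins")
    p = h / h.sum()
    cum = np.cumsum(p)
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    s = np.cumsum(plogp)
    total = s[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        h_bg = np.log(cum) - s / cum
        h_fg = np.log1p(-cum) - (total - s) / (1.0 - cum)
    crit = h_bg + h_fg
    # class-occupancy validity from exact count sums (a float cumsum can
    # land a hair below 1 and spuriously admit an empty foreground)
    counts_below = np.cumsum(h)
    valid = (counts_below > 0) & (counts_below < h.sum())
    crit[~valid] = -np.inf
    return int(np.argmax(crit))  # argmax returns the first (lowest) maximizer


def kapur_threshold_image(
    values: np.ndarray, bins: int = 256
) -> tuple[float, int]:
    """Kapur threshold of an intensity sample; returns (intensity, bin index).

    The binary foreground is ``image > intensity``: pixels falling in the
    background bins (<= the returned bin's upper edge) are excluded.
    """
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = float(values.min()), float(values.max())
    if not hi > lo:
        raise ValueError("constant intensities: cannot threshold")
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    t = kapur_threshold(hist)
    return float(edges[t + 1]), t


def segment_organoid(
    image: np.ndarray,
    pixel_size_um: float,
    *,
    smoothing_sigma: float = 2.0,
    threshold: str | float = "otsu",
    closing_radius: int = 0,
    histogram_bins: int = 256,
    border_fraction_limit: float = 0.5,
) -> OrganoidMask:
    """Segment the single dominant organoid in a 2-D image.

    Gaussian smoothing → global threshold ("otsu", "maxentropy", or a fixed
    intensity) → largest connected component → fill holes → optional
    morphological closing. Raises ValueError on an empty foreground or when
    the foreground touches more than ``border_fraction_limit`` of the image
    border (a likely segmentation failure).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_organoid expects a single 2-D image")
    smoothed = ndi.gaussian_filter(img, smoothing_sigma) if smoothing_sigma > 0 else img
    if isinstance(threshold, str):
        if threshold == "otsu":
            thr = float(threshold_otsu(smoothed))
        elif threshold == "maxentropy":
            thr, _ = kapur_threshold_image(smoothed, bins=histogram_bins)
        elif threshold.startswith("fixed:"):
            thr = float(threshold.split(":", 1)[1])
        else:
            raise ValueError(f"unknown threshold method {threshold!r}")
    else:
        thr = float(threshold)
    fg = smoothed > thr
    if not fg.any():
        raise ValueError("empty foreground")
    labels = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    mask = ndi.binary_fill_holes(mask)
    if closing_radius > 0:
        mask = morphology.binary_closing(mask, morphology.disk(closing_radius))
        labels = measure.label(mask, connectivity=2)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = ndi.binary_fill_holes(labels == largest)
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    if border.mean() > border_fraction_limit:
        raise ValueError(
            "foreground touches more than "
            f"{border_fraction_limit:.0%} of the image border"
        )
    return OrganoidMask(mask, pixel_size_um)


def count_mitotic(
    plane: np.ndarray,
    mask: OrganoidMask,
    *,
    sigma: float = 5.0,
    min_area_px: int = 10,
    min_separation_px: int = 5,
    histogram_bins: int = 256,
    dapi_plane: np.ndarray | None = None,
) -> DensityRecord:
    """Count mitotic nuclei in one marker plane inside the organoid mask.

    Gaussian(σ px) filter → Kapur threshold on in-mask intensities →
    watershed seeded at distance-transform maxima → objects ≥ min_area_px.
    When a DAPI plane is given, its mean inside the mask is reported too.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.shape != mask.pixels.shape:
        raise ValueError("marker plane and mask shapes differ")
    if dapi_plane is not None and np.asarray(dapi_plane).shape != mask.pixels.shape:
        raise ValueError("DAPI plane and mask shapes differ")
    mean_dapi = (
        float(np.asarray(dapi_plane, dtype=float)[mask.pixels].mean())
        if dapi_plane is not None
        else math.nan
    )
    smoothed = ndi.gaussian_filter(plane, sigma) if sigma > 0 else plane
    vals = smoothed[mask.pixels]
    count = 0
    thr = math.nan
    if vals.max() > vals.min():
        thr, _ = kapur_threshold_image(vals, bins=histogram_bins)
        binary = (smoothed > thr) & mask.pixels
        if binary.any():
            distance = ndi.distance_transform_edt(binary)
            comp = measure.label(binary, connectivity=2)
            # light smoothing removes distance-ridge plateau maxima that
            # would over-seed the watershed on elongated blobs
            seed_map = ndi.gaussian_filter(distance, 1.0)
            coords = peak_local_max(
                seed_map, min_distance=min_separation_px, labels=comp
            )
            markers = np.zeros_like(comp)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = sk_seg.watershed(-distance, markers, mask=binary)
            areas = np.bincount(labels.ravel())[1:]
            count = int((areas >= min_area_px).sum())
    area = mask.area_um2
    return DensityRecord(
        mitotic_count=count,
        slice_area_um2=area,
        mitotic_density_per_um2=count / area,
        mean_dapi_intensity=mean_dapi,
        threshold=thr,
    )
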