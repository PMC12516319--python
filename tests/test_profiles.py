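"""Contour splitting, 100-bin tiling, profile extraction, cohort
normalization, and half-max boundary calling."""
import numpy as np
import pytest

from gastrukit import (
    IntensityProfile,
    MedialAxisPath,
    bin_mask,
    boundary_position,
    extract_profile,
    make_bins,
    medial_axis,
    normalize_cohort,
    orient_posterior,
    split_contour,
)
from gastrukit.synthetic import LogisticComponent, make_marker_image, make_organoid_mask


@pytest.fixture(scope="module")
def rectangle_axis(rectangle_mask):
    contour = rectangle_mask.contour_um
    x_lo, x_hi = contour[:, 0].min(), contour[:, 0].max()
    y_mid = (contour[:, 1].min() + contour[:, 1].max()) / 2.0
    return MedialAxisPath(np.array([[x_lo, y_mid], [x_hi, y_mid]]))


@pytest.fixture(scope="module")
def rectangle_binning(rectangle_mask, rectangle_axis):
    return bin_mask(rectangle_mask, rectangle_axis)


class TestSplitContour:
    def test_rectangle_sides_are_long_edges(self, rectangle_mask, rectangle_axis):
        side_a, side_b = split_contour(rectangle_mask, rectangle_axis)
        assert side_a.shape == side_b.shape == (101, 2)
        # one side runs along the top edge, the other along the bottom
        ys = sorted([np.median(side_a[:, 1]), np.median(side_b[:, 1])])
        assert ys[0] == pytest.approx(4.5, abs=1.0)
        assert ys[1] == pytest.approx(54.5, abs=1.0)
        # both ordered from end A to end B
        for side in (side_a, side_b):
            assert side[0, 0] < side[-1, 0]

    def test_capsule_side_arcs_equal_within_1pct(self, straight_capsule, straight_capsule_axis):
        mask, _ = straight_capsule
        side_a, side_b = split_contour(mask, straight_capsule_axis)
        la = np.hypot(*np.diff(side_a, axis=0).T).sum()
        lb = np.hypot(*np.diff(side_b, axis=0).T).sum()
        assert la == pytest.approx(lb, rel=0.01)

    def test_off_contour_endpoint_raises(self, rectangle_mask):
        bad_axis = MedialAxisPath(np.array([[30.0, 29.5], [180.0, 29.5]]))
        with pytest.raises(ValueError, match="off the contour"):
            split_contour(rectangle_mask, bad_axis)


def rectangle_edge_sides():
    """The two long edges of the 200 x 50 rectangle as 101-point sides."""
    xs = np.linspace(6.5, 206.5, 101)
    side_a = np.column_stack([xs, np.full(101, 4.5)])
    side_b = np.column_stack([xs, np.full(101, 54.5)])
    return side_a, side_b


class TestMakeBins:
    def test_rectangle_bins_are_2x50(self):
        side_a, side_b = rectangle_edge_sides()
        binning = make_bins(side_a, side_b, 1.0)
        areas = binning.bin_areas_um2()
        assert len(areas) == 100
        np.testing.assert_allclose(areas, 100.0, rtol=1e-9)
        assert not binning.crossed_bins

    def test_bin_areas_tile_bent_capsules(self):
        rng = np.random.default_rng(8)
        for i in range(4):
            a = rng.uniform(180, 260)
            r = rng.uniform(35, 55)
            k = rng.uniform(-1.4, 1.4) / a
            mask, _ = make_organoid_mask(a, r, k, 2.0, seed=40 + i)
            binning = bin_mask(mask, medial_axis(mask))
            assert binning.bin_areas_um2().sum() == pytest.approx(mask.area_um2, rel=0.03)

    def test_mirrored_mask_reverses_bins(self, rectangle_mask, rectangle_binning):
        from gastrukit import OrganoidMask

        mirrored = OrganoidMask(rectangle_mask.pixels[:, ::-1], 1.0)
        contour = mirrored.contour_um
        x_lo, x_hi = contour[:, 0].min(), contour[:, 0].max()
        y_mid = (contour[:, 1].min() + contour[:, 1].max()) / 2.0
        axis = MedialAxisPath(np.array([[x_lo, y_mid], [x_hi, y_mid]]))
        binning_m = bin_mask(mirrored, axis)
        labels = rectangle_binning.label_map(rectangle_mask)
        labels_m = binning_m.label_map(mirrored)
        flipped = labels[:, ::-1]
        inside = flipped >= 0
        agree = (labels_m[inside] == 99 - flipped[inside]).mean()
        assert agree > 0.99
        np.testing.assert_allclose(
            binning_m.bin_areas_um2(), rectangle_binning.bin_areas_um2()[::-1], atol=1e-6
        )

    def test_mismatched_sides_raise(self):
        with pytest.raises(ValueError, match="equal-length"):
            make_bins(np.zeros((101, 2)), np.zeros((50, 2)), 1.0)


class TestExtractProfile:
    def test_constant_image_gives_flat_profile(self, rectangle_mask, rectangle_binning, rectangle_axis):
        image = np.where(rectangle_mask.pixels, 3.25, 0.0)
        prof = extract_profile(image, rectangle_binning, rectangle_axis, rectangle_mask)
        np.testing.assert_allclose(prof.raw, 3.25)

    def test_linear_gradient_recovered(self, rectangle_mask, rectangle_axis):
        side_a, side_b = rectangle_edge_sides()
        binning = make_bins(side_a, side_b, 1.0)
        h, w = rectangle_mask.pixels.shape
        image = np.tile(np.arange(w, dtype=float), (h, 1)) * rectangle_mask.pixels
        prof = extract_profile(image, binning, rectangle_axis, rectangle_mask)
        # intensity grows linearly along the axis: fit residuals below one
        # bin's worth of gradient (2 px of intensity per bin)
        coeff = np.polyfit(prof.positions, prof.raw, 1)
        residual = np.abs(prof.raw - np.polyval(coeff, prof.positions)).max()
        assert residual <= 2.0
        assert prof.positions[0] == pytest.approx(0.005, abs=0.01)
        assert prof.positions[-1] == pytest.approx(0.995, abs=0.01)

    def test_logistic_gradient_crosses_at_midpoint(self):
        mask, truth = make_organoid_mask(250.0, 40.0, 0.002, 2.0, seed=4)
        image, _ = make_marker_image(
            mask, truth.axis_um, [LogisticComponent(0.6)], noise_sigma=0.0, seed=5
        )
        path = medial_axis(mask)
        binning = bin_mask(mask, path)
        prof = extract_profile(image, binning, path, mask)
        if prof.raw[:10].mean() > prof.raw[-10:].mean():
            prof = prof.reversed()
        bp = boundary_position(prof, "rising", (0.05, 0.95))
        assert bp.x_b == pytest.approx(0.6, abs=0.01)

    def test_image_shape_mismatch_raises(self, rectangle_binning, rectangle_axis, rectangle_mask):
        with pytest.raises(ValueError, match="shapes differ"):
            extract_profile(np.zeros((5, 5)), rectangle_binning, rectangle_axis, rectangle_mask)


class TestNormalizeCohort:
    def _profile(self, values, oid="p"):
        values = np.asarray(values, float)
        return IntensityProfile(
            positions=(np.arange(len(values)) + 0.5) / len(values), raw=values, organoid_id=oid
        )

    def test_extremes_map_to_zero_and_one(self):
        base = np.concatenate([np.full(10, 10.0), np.linspace(10, 110, 80), np.full(10, 110.0)])
        profiles = [self._profile(base, str(i)) for i in range(3)]
        normed, anchors = normalize_cohort(profiles)
        assert anchors.low == pytest.approx(10.0)
        assert anchors.high == pytest.approx(110.0)
        for p in normed:
            assert p.normalized.min() == pytest.approx(0.0, abs=1e-12)
            assert p.normalized.max() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance_bit_identical(self):
        # integer-valued intensities: 3*x + 7 is exact in float64, so the
        # normalized output must be bit-identical
        rng = np.random.default_rng(17)
        raws = [rng.integers(0, 1000, 100).astype(float) for _ in range(5)]
        cohort = [self._profile(r, str(i)) for i, r in enumerate(raws)]
        shifted = [self._profile(3.0 * r + 7.0, str(i)) for i, r in enumerate(raws)]
        n1, _ = normalize_cohort(cohort)
        n2, _ = normalize_cohort(shifted)
        for p1, p2 in zip(n1, n2):
            np.testing.assert_array_equal(p1.normalized, p2.normalized)

    def test_flat_cohort_raises(self):
        cohort = [self._profile(np.full(100, 5.0), str(i)) for i in range(3)]
        with pytest.raises(ValueError, match="flat cohort"):
            normalize_cohort(cohort)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            normalize_cohort([self._profile(np.arange(100.0))])


class TestBoundaryPosition:
    def _step(self, x0, n=100):
        pos = (np.arange(n) + 0.5) / n
        return IntensityProfile(positions=pos, raw=(pos > x0).astype(float))

    def test_ideal_step(self):
        bp = boundary_position(self._step(0.4), "rising", (0.1, 0.9))
        assert bp.x_b == pytest.approx(0.4, abs=0.005)

    def test_logistic_midpoint(self):
        pos = (np.arange(100) + 0.5) / 100
        prof = IntensityProfile(positions=pos, raw=1 / (1 + np.exp(-20 * (pos - 0.6))))
        bp = boundary_position(prof, "rising", (0.1, 0.95))
        assert bp.x_b == pytest.approx(0.6, abs=0.01)

    def test_falling_marker_mirrors_rising(self):
        pos = (np.arange(100) + 0.5) / 100
        rising = IntensityProfile(positions=pos, raw=1 / (1 + np.exp(-20 * (pos - 0.65))))
        falling = rising.reversed()
        b_r = boundary_position(rising, "rising", (0.1, 0.95))
        b_f = boundary_position(falling, "falling", (0.05, 0.9))
        assert b_f.x_b == pytest.approx(1.0 - b_r.x_b, abs=1e-9)

    def test_reversal_maps_positions_exactly(self):
        rng = np.random.default_rng(2)
        raw = np.sort(rng.random(100))
        prof = IntensityProfile(positions=(np.arange(100) + 0.5) / 100, raw=raw)
        b = boundary_position(prof, "rising", (0.2, 0.8))
        b_rev = boundary_position(prof.reversed(), "falling", (0.2, 0.8))
        assert b_rev.x_b == pytest.approx(1.0 - b.x_b, abs=1e-9)

    def test_no_crossing_raises(self):
        prof = IntensityProfile(positions=(np.arange(100) + 0.5) / 100, raw=np.full(100, 0.5))
        with pytest.raises(ValueError, match="no half-max crossing"):
            boundary_position(prof, "rising", (0.5, 1.0))


class TestOrientPosterior:
    def test_bra_high_end_moved_to_one(self):
        pos = (np.arange(100) + 0.5) / 100
        bra = IntensityProfile(positions=pos, raw=1 / (1 + np.exp(20 * (pos - 0.3))), channel="BRA")
        sox = IntensityProfile(positions=pos, raw=np.linspace(5, 1, 100), channel="SOX2")
        oriented = orient_posterior({"BRA": bra, "SOX2": sox})
        assert oriented["BRA"].raw[-10:].mean() > oriented["BRA"].raw[:10].mean()
        # the companion channel is mirrored together with BRA
        assert oriented["SOX2"].raw[0] == pytest.approx(1.0)

    def test_already_oriented_untouched(self):
        pos = (np.arange(100) + 0.5) / 100
        bra = IntensityProfile(positions=pos, raw=pos.copy(), channel="BRA")
        oriented = orient_posterior({"BRA": bra})
        np.testing.assert_array_equal(oriented["BRA"].raw, bra.raw)
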