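"""Generator determinism, ground-truth bookkeeping, and pipeline
round-trips on generated scenes."""
import math

import numpy as np
import pytest

from gastrukit import (
    bin_mask,
    call_poles,
    count_mitotic,
    extract_profile,
    iter_tracks,
    mean_speed,
    medial_axis,
    normalize_cohort,
    timelapse_motion,
)
from gastrukit.synthetic import (
    LogisticComponent,
    make_marker_image,
    make_nuclei_plane,
    make_organoid_mask,
    make_timelapse,
    make_tracks,
)


class TestOrganoidMaskGenerator:
    def test_straight_capsule_truth(self):
        _, truth = make_organoid_mask(200.0, 50.0, 0.0, 1.0, seed=0)
        assert truth.length_um == 300.0
        assert truth.straightness == pytest.approx(1.0)

    def test_semicircular_centerline_closed_form(self):
        R, r = 150.0, 30.0
        a = math.pi * R
        _, truth = make_organoid_mask(a, r, 1.0 / R, 1.0, seed=0)
        # extended endpoints: apexes r beyond the arc ends along the tangents
        assert truth.length_um == pytest.approx(a + 2 * r)
        chord = math.hypot(2 * R, 0.0)  # tangents at both ends are parallel
        assert truth.straightness == pytest.approx(2 * R / (a + 2 * r), rel=1e-6)

    def test_same_seed_bit_identical(self):
        m1, _ = make_organoid_mask(180.0, 40.0, 0.003, 1.0, boundary_noise_px=1.0, seed=5)
        m2, _ = make_organoid_mask(180.0, 40.0, 0.003, 1.0, boundary_noise_px=1.0, seed=5)
        np.testing.assert_array_equal(m1.pixels, m2.pixels)

    def test_self_intersecting_sweep_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            make_organoid_mask(200.0, 60.0, 1.0 / 50.0, 1.0)  # r > bend radius


@pytest.fixture(scope="module")
def host():
    return make_organoid_mask(250.0, 40.0, 0.0, 2.0, seed=4)


@pytest.fixture(scope="module")
def nuclei_host():
    mask, _ = make_organoid_mask(200.0, 80.0, 0.0, 1.0, seed=9)
    return mask


class TestMarkerImageGenerator:

    def test_truth_records_midpoints_and_pole_count(self, host):
        mask, mtruth = host
        comps = [LogisticComponent(0.6), LogisticComponent(0.25, direction="falling")]
        _, truth = make_marker_image(mask, mtruth.axis_um, comps, seed=1)
        assert truth.boundary_positions["marker"] == [0.6, 0.25]
        assert truth.pole_count == 2

    def test_noiseless_profile_round_trip(self, host):
        mask, mtruth = host
        image, _ = make_marker_image(
            mask, mtruth.axis_um, [LogisticComponent(0.5, steepness=12.0)],
            noise_sigma=0.0, background=0.0, seed=2,
        )
        path = medial_axis(mask)
        binning = bin_mask(mask, path)
        prof = extract_profile(image, binning, path, mask)
        if prof.raw[:10].mean() > prof.raw[-10:].mean():
            prof = prof.reversed()
        expected = 1 / (1 + np.exp(-12.0 * (prof.positions - 0.5)))
        # within one bin's worth of the logistic slope everywhere
        max_slope = 12.0 / 4
        assert np.abs(prof.raw - expected).max() <= max_slope * 0.01 + 0.02

    def test_determinism(self, host):
        mask, mtruth = host
        i1, _ = make_marker_image(mask, mtruth.axis_um, [LogisticComponent(0.6)], seed=3)
        i2, _ = make_marker_image(mask, mtruth.axis_um, [LogisticComponent(0.6)], seed=3)
        np.testing.assert_array_equal(i1, i2)

    def test_invalid_midpoint_rejected(self):
        with pytest.raises(ValueError, match="midpoint"):
            LogisticComponent(1.2)


class TestNucleiGenerator:

    def test_round_trip_count(self, nuclei_host):
        image, truth = make_nuclei_plane(nuclei_host, 5, seed=20)
        assert count_mitotic(image, nuclei_host).mitotic_count == truth.n_spots == 5

    def test_zero_spots_is_flat_background(self, nuclei_host):
        image, truth = make_nuclei_plane(nuclei_host, 0, noise_sigma=0.0, seed=21)
        assert truth.n_spots == 0
        assert np.ptp(image) == 0.0

    def test_min_separation_respected(self, nuclei_host):
        _, truth = make_nuclei_plane(nuclei_host, 8, min_separation_px=25.0, seed=22)
        centers = truth.spot_centers_px
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                assert np.hypot(*(centers[i] - centers[j])) >= 25.0

    def test_impossible_placement_raises(self, nuclei_host):
        with pytest.raises(ValueError, match="could not place"):
            make_nuclei_plane(nuclei_host, 50, min_separation_px=60.0, seed=23, max_tries=500)


class TestTrackGenerator:
    def test_ballistic_exact_speed(self):
        table, truth = make_tracks(
            3, "ballistic", v_um_per_min=0.05, n_points=10,
            localization_noise_um=0.0, seed=1,
        )
        for track in iter_tracks(table):
            assert mean_speed(track) == pytest.approx(0.05, rel=1e-12)

    def test_same_seed_identical_table(self):
        t1, _ = make_tracks(5, "brownian", seed=3)
        t2, _ = make_tracks(5, "brownian", seed=3)
        assert t1.df.equals(t2.df)

    def test_confined_tracks_stay_near_origin(self):
        table, _ = make_tracks(
            20, "confined", D_um2_per_min=0.05, confinement_radius_um=5.0,
            n_points=25, localization_noise_um=0.0, seed=4,
        )
        radii = np.linalg.norm(table.df[["x_um", "y_um", "z_um"]].to_numpy(), axis=1)
        assert np.quantile(radii, 0.95) < 15.0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown track model"):
            make_tracks(2, "levy", seed=0)


class TestTimelapseGenerator:
    def test_zero_growth_gives_flat_radius(self):
        masks, _ = make_timelapse(40.0, 0.0, n_frames=5, seed=1)
        tm = timelapse_motion(masks, 1.0, 30.0)
        assert np.ptp(tm.effective_radius_um) < 0.2

    def test_zero_drift_centroid_stable(self):
        masks, _ = make_timelapse(40.0, 0.01, n_frames=5, seed=2)
        tm = timelapse_motion(masks, 1.0, 30.0)
        steps = np.hypot(*np.diff(tm.centroids_um, axis=0).T)
        assert steps.max() <= 0.5

    def test_field_exit_raises(self):
        with pytest.raises(ValueError, match="field of view"):
            make_timelapse(40.0, 0.0, (30.0, 0.0), n_frames=10, field_shape=(100, 100), seed=3)

    def test_determinism(self):
        m1, _ = make_timelapse(40.0, 0.01, n_frames=4, boundary_noise_px=1.0, seed=5)
        m2, _ = make_timelapse(40.0, 0.01, n_frames=4, boundary_noise_px=1.0, seed=5)
        np.testing.assert_array_equal(m1, m2)


class TestGeneratorOutputsSatisfyConsumers:
    """Smoke property: random scenes pass their consuming preconditions."""

    def test_random_scenes(self):
        rng = np.random.default_rng(99)
        for i in range(3):
            a = rng.uniform(160, 240)
            r = rng.uniform(35, 55)
            k = rng.uniform(-1.2, 1.2) / a
            mask, truth = make_organoid_mask(a, r, k, 2.0, boundary_noise_px=0.5, seed=60 + i)
            path = medial_axis(mask)
            assert path.length_um >= path.chord_um > 0
            binning = bin_mask(mask, path)
            image, _ = make_marker_image(
                mask, truth.axis_um, [LogisticComponent(rng.uniform(0.3, 0.7))], seed=70 + i
            )
            prof = extract_profile(image, binning, path, mask)
            assert np.all(prof.raw >= 0)
            assert np.all(np.diff(prof.positions) > 0)


class TestPoleCohortRoundTrip:
    def test_pole_multiplicity_recovered(self):
        rng = np.random.default_rng(7)
        profs, truth_counts = [], []
        for i in range(12):
            n_poles = i % 3
            mask, mt = make_organoid_mask(
                rng.uniform(200, 280), rng.uniform(35, 50), rng.uniform(-1, 1) / 250,
                2.0, seed=300 + i,
            )
            comps = []
            if n_poles >= 1:
                comps.append(LogisticComponent(rng.uniform(0.6, 0.8)))
            if n_poles == 2:
                comps.append(LogisticComponent(rng.uniform(0.2, 0.4), direction="falling"))
            image, _ = make_marker_image(mask, mt.axis_um, comps, noise_sigma=0.1, seed=400 + i)
            path = medial_axis(mask)
            prof = extract_profile(image, bin_mask(mask, path), path, mask)
            profs.append(prof)
            truth_counts.append(n_poles)
        normed, _ = normalize_cohort(profs)
        correct = sum(call_poles(p).n_poles == t for p, t in zip(normed, truth_counts))
        assert correct >= 11
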