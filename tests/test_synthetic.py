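"""Generator ground truth: analytic bookkeeping and seed determinism."""

import numpy as np
import pytest

from axoquant import synthetic as syn
from axoquant.types import BinaryMask, Calibration, PolylineROI


class TestAxonField:
    def test_three_equal_rays_count_three_until_their_length(self, unit_cal):
        rays = [syn.Ray(a, 700.0) for a in (-0.9, 0.0, 0.9)]
        radii = np.arange(50.0, 1500.0, 50.0)
        _, truth = syn.make_axon_field(rays, (1601, 801), unit_cal,
                                       center=(0.0, 800.0), radii_um=radii)
        expect = np.where(radii <= 700.0, 3, 0)
        np.testing.assert_array_equal(truth.expected_counts, expect)

    def test_no_rays_gives_empty_mask_and_zero_counts(self, unit_cal):
        mask, truth = syn.make_axon_field([], (101, 101), unit_cal,
                                          center=(0.0, 50.0),
                                          radii_um=np.array([10.0, 20.0]))
        assert not mask.values.any()
        np.testing.assert_array_equal(truth.expected_counts, [0, 0])

    def test_branch_fork_raises_count_beyond_fork(self, unit_cal):
        # one 300-um ray forking at 100 um, branch sized so its tip sits at
        # radial distance 300: 1 crossing before the fork, 2 after (sampled
        # away from the fork where the two strokes are spatially resolved)
        ray = syn.Ray(0.0, 300.0, branches=(syn.Branch(100.0, 0.45, 206.8),))
        radii = np.arange(10.0, 301.0, 10.0)
        mask, truth = syn.make_axon_field([ray], (501, 351), unit_cal,
                                          center=(0.0, 250.0), radii_um=radii)
        expect = np.where(radii <= 100.0, 1, 2)
        sel = np.abs(radii - 100.0) > 20.0   # strokes merge just past the fork
        np.testing.assert_array_equal(truth.expected_counts[sel], expect[sel])
        from axoquant import sholl
        params = sholl.ShollParams(center=truth.center, radius_step_um=10.0,
                                   r_max_um=300.0, bin_edges_um=(0.0, 300.0))
        prof = sholl.sholl_intersections(mask, params)
        # exact agreement except within 2 px of the rendered branch tip
        tipsel = np.abs(radii - 300.0) > 2.0
        np.testing.assert_array_equal(prof.counts[tipsel],
                                      truth.expected_counts[tipsel])
        assert abs(prof.counts[-1] - truth.expected_counts[-1]) <= 1

    def test_ray_exiting_image_rejected(self, unit_cal):
        with pytest.raises(ValueError, match="exits"):
            syn.make_axon_field([syn.Ray(0.0, 500.0)], (101, 101), unit_cal,
                                center=(0.0, 50.0))


class TestGrowthCone:
    def test_circle_area_matches_pi_r_squared(self, gc_cal):
        mask, _ = syn.make_growth_cone((100, 100), 5.0, 5.0, 0.0, [],
                                       (200, 200), gc_cal)
        area = mask.values.sum() * gc_cal.pixel_area_um2
        assert area == pytest.approx(np.pi * 25.0, rel=0.02)

    def test_truth_carries_filopodium_lengths_and_rendering_matches(self, gc_cal):
        fils = [syn.Filopodium(base_t=t, length_um=L)
                for t, L in [(0.6, 2.5), (1.2, 1.5), (2.0, 0.5)]]
        mask, truth = syn.make_growth_cone((150, 100), 10.0, 4.0, 0.0, fils,
                                           (200, 300), gc_cal)
        assert [f.length_um for f in truth.filopodia] == [2.5, 1.5, 0.5]
        # geometric measurement: rendered pixels outside the body ellipse
        body, _ = syn.make_growth_cone((150, 100), 10.0, 4.0, 0.0, [],
                                       (200, 300), gc_cal)
        for fil, base in zip(truth.filopodia, truth.bases_px):
            ys, xs = np.nonzero(mask.values & ~body.values)
            d = np.hypot(xs - base[0], ys - base[1])
            near = d[d < (fil.length_um / gc_cal.pixel_size_um) + 2]
            assert near.max() * gc_cal.pixel_size_um == pytest.approx(
                fil.length_um, abs=0.25)

    def test_inverted_axes_rejected(self, gc_cal):
        with pytest.raises(ValueError, match="a >= b"):
            syn.make_growth_cone((50, 50), 2.0, 5.0, 0.0, [], (100, 100), gc_cal)

    def test_base_on_boundary_validation(self, gc_cal):
        _, truth = syn.make_growth_cone((100, 100), 5.0, 3.0, 0.0, [],
                                        (200, 200), gc_cal)
        syn.validate_filopodium_base(truth, np.array([150.0, 100.0]), gc_cal)
        with pytest.raises(ValueError, match="boundary"):
            syn.validate_filopodium_base(truth, np.array([100.0, 100.0]), gc_cal)


class TestCometMovie:
    @pytest.fixture
    def axis(self):
        return PolylineROI(np.array([[5.0, 10.0], [95.0, 10.0]]), 1.0)

    def test_static_only_movie_has_identical_frames(self, axis, movie_cal):
        spots = [syn.StaticSpot(30.0, 10.0), syn.StaticSpot(60.0, 10.0)]
        movie, _ = syn.make_comet_movie(axis, [], spots, (21, 100), 10, movie_cal)
        for f in range(1, movie.n_frames):
            np.testing.assert_array_equal(movie.frames[f], movie.frames[0])

    def test_comet_displacement_matches_kinematics(self, axis, movie_cal):
        # 0.1 um/s for 20 s -> 2.0 um displacement between first and last
        # active frame (centroid-tracked on the noise-free movie)
        comet = syn.Comet(start_time_s=2.0, start_pos_um=1.0,
                          velocity_um_s=0.1, lifetime_s=20.0)
        movie, _ = syn.make_comet_movie(axis, [comet], [], (21, 100), 50, movie_cal)
        active = [f for f in range(50) if movie.frames[f].max() > 1.0]
        def centroid_x(frame):
            w = frame.sum()
            return (frame.sum(axis=0) * np.arange(frame.shape[1])).sum() / w
        dx_px = centroid_x(movie.frames[active[-1]]) - centroid_x(movie.frames[active[0]])
        dt = (active[-1] - active[0]) * 0.5
        expect_um = 0.1 * dt
        assert dx_px * movie_cal.pixel_size_um == pytest.approx(expect_um, abs=0.05)

    def test_fixed_seed_reproduces_noisy_movie_bitwise(self, axis, movie_cal):
        kwargs = dict(axis=axis, comets=[], static_spots=[syn.StaticSpot(30.0, 10.0)],
                      shape=(21, 100), n_frames=6, calibration=movie_cal,
                      noise_sd=5.0, seed=99)
        m1, _ = syn.make_comet_movie(**kwargs)
        m2, _ = syn.make_comet_movie(**kwargs)
        np.testing.assert_array_equal(m1.frames, m2.frames)

    def test_comet_outside_duration_rejected(self, axis, movie_cal):
        comet = syn.Comet(start_time_s=20.0, start_pos_um=1.0,
                          velocity_um_s=0.1, lifetime_s=20.0)
        with pytest.raises(ValueError, match="duration"):
            syn.make_comet_movie(axis, [comet], [], (21, 100), 20, movie_cal)

    def test_packed_random_comets_have_disjoint_footprints(self, rng):
        comets = syn.random_comets(rng, 30, 50.0, 180.0)
        assert len(comets) == 30
        for i, a in enumerate(comets):
            for b in comets[i + 1:]:
                x_overlap = (a.start_pos_um < b.start_pos_um
                             + b.velocity_um_s * b.lifetime_s + 0.8) and \
                            (b.start_pos_um < a.start_pos_um
                             + a.velocity_um_s * a.lifetime_s + 0.8)
                t_overlap = (a.start_time_s < b.start_time_s + b.lifetime_s + 3.5) and \
                            (b.start_time_s < a.start_time_s + a.lifetime_s + 3.5)
                assert not (x_overlap and t_overlap)


class TestColocPair:
    def test_full_overlap_shares_all_centers(self, gc_cal):
        ch1, ch2, truth = syn.make_coloc_pair(12, 12, 1.0, (128, 128), gc_cal, seed=3)
        assert len(truth.shared) == 12
        np.testing.assert_array_equal(np.sort(truth.centers_ch1, axis=0),
                                      np.sort(truth.centers_ch2, axis=0))

    def test_zero_overlap_keeps_channels_apart(self, gc_cal):
        _, _, truth = syn.make_coloc_pair(10, 10, 0.0, (128, 128), gc_cal, seed=4)
        d = np.hypot(*(truth.centers_ch1[:, None, :]
                       - truth.centers_ch2[None, :, :]).transpose(2, 0, 1))
        assert d.min() > 4 * truth.sigma_px

    def test_half_overlap_shares_exactly_half(self, gc_cal):
        _, _, truth = syn.make_coloc_pair(40, 40, 0.5, (256, 256), gc_cal, seed=5)
        assert len(truth.shared) == 20


class TestPunctaField:
    @pytest.fixture
    def band_mask(self, gc_cal):
        m = np.zeros((128, 128), dtype=bool)
        m[:, :64] = True
        return BinaryMask(m, gc_cal)

    def test_truth_centers_respect_mask_side(self, band_mask, gc_cal):
        _, truth = syn.make_puncta_field(band_mask, 5, 3, seed=6)
        for x, y in truth.centers_inside:
            assert band_mask.values[int(round(y)), int(round(x))]
        for x, y in truth.centers_outside:
            assert not band_mask.values[int(round(y)), int(round(x))]

    def test_zero_inside_means_pure_background_in_mask(self, band_mask):
        img, _ = syn.make_puncta_field(band_mask, 0, 3, seed=7)
        assert img.values[:, :50].max() < 1.0

    def test_seed_determinism(self, band_mask):
        i1, _ = syn.make_puncta_field(band_mask, 4, 4, noise_sd=2.0, seed=8)
        i2, _ = syn.make_puncta_field(band_mask, 4, 4, noise_sd=2.0, seed=8)
        np.testing.assert_array_equal(i1.values, i2.values)


class TestProfileImage:
    def test_constant_function_renders_constant_stripe(self, gc_cal):
        img, truth = syn.make_profile_image(lambda d: np.full_like(d, 100.0),
                                            50.0, 11, 10.0, gc_cal)
        tip_x, tip_y = truth.tip_px
        stripe = img.values[int(tip_y), int(tip_x):int(tip_x) + 10]
        np.testing.assert_allclose(stripe, 110.0)
        corner = img.values[0, 0]
        assert corner == 10.0

    def test_negative_function_rejected(self, gc_cal):
        with pytest.raises(ValueError, match="nonnegative"):
            syn.make_profile_image(lambda d: d - 10.0, 50.0, 5, 0.0, gc_cal)
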