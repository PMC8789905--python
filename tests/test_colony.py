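"""Colony detection and radial profiling: brute-force binning oracle,
conservation, ensembles, kymographs and z-profiles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import disc_geometry
from nodalrelay.colony import (
    ColonyRejection,
    build_kymograph,
    detect_colony,
    ensemble_profile,
    radial_profile,
    z_axis_profile,
)
from nodalrelay.prep import subtract_background
from nodalrelay.render import RenderParams, render_colony_image


def brute_force_radial_profile(img, geometry, bin_width_um):
    """Independent oracle: loop over every pixel, no vectorized binning."""
    sums, counts = {}, {}
    cy = geometry.center_um[1] / geometry.um_per_px - 0.5
    cx = geometry.center_um[0] / geometry.um_per_px - 0.5
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            if not geometry.mask[y, x]:
                continue
            r = np.hypot(x - cx, y - cy) * geometry.um_per_px
            b = int(r // bin_width_um)
            sums[b] = sums.get(b, 0.0) + img[y, x]
            counts[b] = counts.get(b, 0) + 1
    n = max(counts) + 1
    mean = np.full(n, np.nan)
    count = np.zeros(n)
    for b in counts:
        mean[b] = sums[b] / counts[b]
        count[b] = counts[b]
    return mean, count


class TestDetectColony:
    def test_perfect_disc_center_and_radius(self):
        geom_true = disc_geometry((240, 240), 1.5, 150.0)
        img = np.where(geom_true.mask, 200.0, 0.0)
        geom = detect_colony(img, 1.5, expected_diameter_um=300.0)
        assert abs(geom.center_um[0] - geom_true.center_um[0]) < 0.5 * 1.5
        assert abs(geom.center_um[1] - geom_true.center_um[1]) < 0.5 * 1.5
        assert geom.radius_um == pytest.approx(150.0, rel=0.01)

    def test_noisy_rendered_colony_center_within_two_pixels(self):
        p = RenderParams(shape_px=(260, 260), um_per_px=1.5,
                         poisson_noise=True, read_noise_sd=2.0,
                         hot_pixel_rate=0.001)
        stack, truth = render_colony_image(
            {"sig": lambda r: np.ones_like(r)}, p, seed=9,
            colony_radius_um=150.0)
        from nodalrelay.prep import remove_outliers

        dapi = remove_outliers(stack.channel("dapi"), 2, 5.0)
        dapi = subtract_background(dapi, 1.5)
        geom = detect_colony(dapi, 1.5, 300.0)
        err = np.hypot(geom.center_um[0] - truth.center_um[0],
                       geom.center_um[1] - truth.center_um[1])
        assert err < 2 * 1.5

    def test_half_filled_colony_rejected(self):
        geom_true = disc_geometry((240, 240), 1.5, 150.0)
        img = np.where(geom_true.mask, 200.0, 0.0)
        img[:, 120:] = 0.0  # crescent
        with pytest.raises(ColonyRejection) as exc:
            detect_colony(img, 1.5, expected_diameter_um=300.0)
        assert exc.value.reason == "radius_out_of_tolerance"


class TestRadialProfile:
    def test_constant_image_every_bin_exact(self):
        geom = disc_geometry((64, 64), 2.0, 50.0)
        prof = radial_profile(np.full((64, 64), 5.0), geom, 10.0)
        assert np.all(prof.mean[prof.count > 0] == 5.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle_bit_exactly(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 100, (64, 64))
        cx, cy = rng.uniform(24, 40, 2)
        geom = disc_geometry((64, 64), 2.0, rng.uniform(30, 60),
                             center_px=(cx, cy))
        prof = radial_profile(img, geom, 10.0)
        mean_bf, count_bf = brute_force_radial_profile(img, geom, 10.0)
        assert np.array_equal(prof.count[: len(count_bf)], count_bf)
        good = count_bf > 0
        assert np.array_equal(prof.mean[: len(count_bf)][good], mean_bf[good])
        # conservation: sum(mean * count) == sum of binned intensities
        total = np.nansum(prof.mean * prof.count)
        assert total == pytest.approx(img[geom.mask].sum(), rel=1e-9)

    def test_smooth_gradient_matches_analytic_bin_average(self):
        geom = disc_geometry((400, 400), 1.0, 180.0)
        yy, xx = np.indices((400, 400))
        r = np.hypot(xx - 199.5, yy - 199.5)
        img = np.exp(-r / 50.0)
        prof = radial_profile(img, geom, 10.0)
        lo, hi = prof.bin_edges_um[:-1], prof.bin_edges_um[1:]
        # analytic area-weighted bin mean of exp(-r/50) over the annulus
        lam = 50.0

        def integral(r_):  # of r * exp(-r/lam)
            return -lam * np.exp(-r_ / lam) * (r_ + lam)

        analytic = (2 * (integral(hi) - integral(lo))
                    / (hi**2 - lo**2))
        sel = prof.count > 100
        assert np.allclose(prof.mean[sel], analytic[sel], rtol=0.02)

    def test_350um_colony_spans_35_ten_micron_bins(self):
        geom = disc_geometry((720, 720), 1.0, 350.0)
        prof = radial_profile(np.ones((720, 720)), geom, 10.0)
        assert (prof.count > 0).sum() == 35

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 10, (101, 101))
        geom = disc_geometry((101, 101), 2.0, 90.0)
        prof = radial_profile(img, geom, 10.0)
        prof_rot = radial_profile(np.rot90(img), geom, 10.0)
        good = prof.count > 0
        assert np.array_equal(prof.count, prof_rot.count)
        assert np.allclose(prof.mean[good], prof_rot.mean[good], rtol=1e-12)

    def test_bad_bin_width_rejected(self):
        geom = disc_geometry((64, 64), 2.0, 50.0)
        with pytest.raises(ValueError):
            radial_profile(np.ones((64, 64)), geom, 0.0)


class TestEnsemble:
    def make_profile(self, values, colony_id="c"):
        geom = disc_geometry((64, 64), 2.0, 50.0)
        return radial_profile(np.full((64, 64), values), geom, 10.0,
                              colony_id=colony_id)

    def test_identical_profiles_have_zero_sem(self):
        profs = [self.make_profile(7.0, f"c{i}") for i in range(5)]
        ens = ensemble_profile(profs)
        assert np.all(ens.sem[~np.isnan(ens.sem)] == 0.0)
        assert np.allclose(ens.mean[~np.isnan(ens.mean)], 7.0)

    def test_monte_carlo_sem_matches_sigma_over_sqrt_n(self):
        rng = np.random.default_rng(8)
        mu, sigma, n = 50.0, 4.0, 50
        profs = [self.make_profile(mu + rng.normal(0, sigma), f"c{i}")
                 for i in range(n)]
        ens = ensemble_profile(profs)
        expect_sem = sigma / np.sqrt(n)
        assert np.all(np.abs(ens.mean - mu) < 3 * expect_sem)
        assert np.allclose(ens.sem, expect_sem, rtol=0.25)

    def test_single_colony_flags_sem(self):
        with pytest.warns(UserWarning, match="SEM"):
            ens = ensemble_profile([self.make_profile(3.0)])
        assert np.all(np.isnan(ens.sem))
        assert ens.n == 1

    def test_mismatched_bins_rejected(self):
        a = self.make_profile(1.0)
        b = self.make_profile(1.0)
        b.bin_edges_um = b.bin_edges_um + 1.0
        with pytest.raises(ValueError, match="bin edges"):
            ensemble_profile([a, b])

    def test_max_normalization_rescales_each_colony(self):
        profs = [self.make_profile(v, f"c{v}") for v in (5.0, 10.0)]
        ens = ensemble_profile(profs, normalization="max")
        good = ~np.isnan(ens.mean)
        assert np.allclose(ens.mean[good], 1.0)


class TestKymograph:
    def test_static_movie_rows_identical_and_consistent_with_profile(self):
        rng = np.random.default_rng(4)
        frame = rng.uniform(0, 50, (120, 120))
        geom = disc_geometry((120, 120), 2.0, 100.0)
        movie = np.stack([frame] * 4)
        kym = build_kymograph(movie, geom, n_segments=12)
        for row in kym.values[1:]:
            assert np.array_equal(row, kym.values[0])
        prof = radial_profile(frame, geom, 10.0)
        good = prof.count > 0
        assert np.allclose(kym.values[0][good], prof.mean[good], rtol=1e-12)

    def test_segment_average_equals_whole_colony_for_symmetric_movie(self):
        geom = disc_geometry((160, 160), 2.0, 140.0)
        yy, xx = np.indices((160, 160))
        r = np.hypot(xx - 79.5, yy - 79.5) * 2.0
        movie = np.stack([np.exp(-r / (40.0 + 10 * k)) for k in range(3)])
        k12 = build_kymograph(movie, geom, n_segments=12)
        k1 = build_kymograph(movie, geom, n_segments=1)
        assert np.allclose(k12.values, k1.values, rtol=1e-10, equal_nan=True)

    def test_moving_ring_argmax_tracks_inward_speed(self):
        geom = disc_geometry((200, 200), 2.0, 180.0)
        yy, xx = np.indices((200, 200))
        r = np.hypot(xx - 99.5, yy - 99.5) * 2.0
        v, dt = 20.0, 1.0  # ring moves 20 um inward per frame: 2 bins
        movie = np.stack([
            np.exp(-((r - (160.0 - v * dt * k)) / 10.0) ** 2)
            for k in range(5)
        ])
        kym = build_kymograph(movie, geom, n_segments=12)
        centers = 0.5 * (kym.bin_edges_um[:-1] + kym.bin_edges_um[1:])
        peaks = centers[np.nanargmax(kym.values, axis=1)]
        steps = np.diff(peaks)
        assert np.all(np.abs(steps + v * dt) <= 10.0)  # within one bin

    def test_segment_count_validated(self):
        geom = disc_geometry((64, 64), 2.0, 50.0)
        with pytest.raises(ValueError):
            build_kymograph(np.ones((2, 64, 64)), geom, n_segments=0)


class TestZProfile:
    def test_target_equal_to_membrane_is_unity(self):
        stack = np.random.default_rng(0).uniform(1, 5, (6, 32, 32))
        assert np.allclose(z_axis_profile(stack, stack), 1.0)

    def test_basolateral_enrichment_peaks_at_bottom_slice(self):
        z = np.arange(8)
        target = (1.0 + np.exp(-z / 2.0))[:, None, None] * np.ones((8, 16, 16))
        membrane = np.ones((8, 16, 16))
        prof = z_axis_profile(target, membrane)
        assert prof.argmax() == 0

    def test_ratio_invariant_under_global_gain(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(1, 4, (5, 20, 20))
        m = rng.uniform(1, 4, (5, 20, 20))
        assert np.allclose(z_axis_profile(t, m),
                           z_axis_profile(2.0 * t, 2.0 * m))

    def test_nonpositive_membrane_slice_rejected(self):
        t = np.ones((3, 8, 8))
        m = np.ones((3, 8, 8))
        m[1] = 0.0
        with pytest.raises(ValueError, match="slice 1"):
            z_axis_profile(t, m)
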