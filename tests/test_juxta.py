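"""Juxtaposition quantification: distance-transform oracle, border
binning, exponential range fits and cell-tier conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodalrelay.juxta import (
    border_profile,
    distance_to_border,
    fit_exponential_decay,
    range_in_cell_tiers,
)
from nodalrelay.prep import segment_sender_mask
from nodalrelay.render import RenderParams, render_juxtaposition_image


def brute_force_distance(mask, um_per_px):
    """Oracle: per-pixel minimum over all sender pixel centers."""
    ys, xs = np.nonzero(mask)
    out = np.zeros(mask.shape)
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x]:
                continue
            out[y, x] = np.sqrt(((ys - y) ** 2 + (xs - x) ** 2).min())
    return out * um_per_px


class TestDistanceToBorder:
    def test_four_adjacent_pixel_is_one_pixel_away(self):
        mask = np.zeros((9, 9), bool)
        mask[:, :4] = True
        d = distance_to_border(mask, um_per_px=2.5)
        assert d[4, 4] == 2.5
        assert np.all(d[mask] == 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_exact_match_to_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) < rng.uniform(0.05, 0.6)
        if not mask.any() or mask.all():
            return
        d = distance_to_border(mask, um_per_px=1.0)
        assert np.allclose(d, brute_force_distance(mask, 1.0), atol=1e-9)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_to_border(np.zeros((8, 8), bool), 1.0)
        with pytest.raises(ValueError, match="no receivers"):
            distance_to_border(np.ones((8, 8), bool), 1.0)


class TestBorderProfile:
    def half_plane(self, shape=(40, 200), border_col=60):
        mask = np.zeros(shape, bool)
        mask[:, :border_col] = True
        return mask

    def test_uniform_receiver_intensity_in_every_bin(self):
        sender = self.half_plane()
        img = np.where(sender, 99.0, 7.0)
        prof = border_profile(img, sender, ~sender, um_per_px=2.0)
        assert np.all(prof.mean[prof.count > 0] == 7.0)
        assert prof.sender_mean == 99.0

    def test_rendered_exponential_matches_analytic_bin_average(self):
        """Zero-noise render with lambda = 60 um: EDT-binned means agree
        with the bin-averaged exponential to 3%."""
        p = RenderParams(shape_px=(80, 360), um_per_px=1.0)
        spec = {"border_x_um": 60.5, "channels": {
            "lefty": {"kind": "exp", "a": 100.0, "lambda_um": 60.0, "c": 0.0}}}
        stack, _ = render_juxtaposition_image(spec, p, seed=0)
        sender = segment_sender_mask(stack.channel("marker"))
        prof = border_profile(stack.channel("lefty"), sender, ~sender,
                              1.0, bin_width_um=5.0)
        lo, hi = prof.bin_edges_um[:-1], prof.bin_edges_um[1:]
        lam = 60.0
        analytic = lam * 100.0 * (np.exp(-lo / lam) - np.exp(-hi / lam)) / (hi - lo)
        sel = prof.count > 0
        sel &= hi <= 250.0
        assert np.allclose(prof.mean[sel], analytic[sel], rtol=0.03)

    def test_receiver_exclusion_preserves_conservation(self):
        rng = np.random.default_rng(0)
        sender = self.half_plane(shape=(40, 120), border_col=30)
        img = rng.uniform(0, 50, (40, 120))
        receiver = ~sender
        receiver[:20, :] = False  # exclude a quadrant
        prof = border_profile(img, sender, receiver, 2.0)
        assert prof.count.sum() == receiver.sum()
        total = np.nansum(prof.mean * prof.count)
        assert total == pytest.approx(img[receiver].sum(), rel=1e-9)

    def test_overlapping_masks_rejected(self):
        sender = self.half_plane()
        with pytest.raises(ValueError, match="overlap"):
            border_profile(np.ones(sender.shape), sender, sender, 1.0)


class TestDecayFit:
    def synthetic_profile(self, a=100.0, lam=60.0, c=10.0, width=5.0, n=40):
        from nodalrelay.juxta import BorderProfile

        edges = width * np.arange(n + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return BorderProfile(edges, a * np.exp(-centers / lam) + c,
                             np.full(n, 100.0), c, 100)

    def test_noiseless_profile_recovers_lambda_to_1e3(self):
        fit = fit_exponential_decay(self.synthetic_profile())
        assert fit.converged
        assert fit.decay_length_um == pytest.approx(60.0, rel=1e-3)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-2)

    def test_flat_profile_flagged_no_decay(self):
        fit = fit_exponential_decay(self.synthetic_profile(a=0.0, c=42.0))
        assert fit.no_decay and not fit.converged
        with pytest.raises(ValueError):
            range_in_cell_tiers(fit)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_exponential_decay(self.synthetic_profile(n=3))

    def test_lambda_invariant_under_intensity_rescaling(self):
        p1 = self.synthetic_profile(a=100.0, c=10.0)
        p2 = self.synthetic_profile(a=700.0, c=70.0)
        f1, f2 = fit_exponential_decay(p1), fit_exponential_decay(p2)
        assert f1.decay_length_um == pytest.approx(f2.decay_length_um,
                                                   rel=1e-6)

    @pytest.mark.parametrize("lam", [20.0, 60.0, 120.0])
    def test_lambda_recovered_within_15pct_from_noisy_renders(self, lam):
        """Parameter recovery under the default noise model, 4 seeded
        replicates per decay length."""
        p = RenderParams(shape_px=(120, 300), um_per_px=2.0,
                         psf_sigma_um=1.0, poisson_noise=True,
                         read_noise_sd=2.0)
        for seed in range(4):
            spec = {"border_x_um": 100.0, "channels": {
                "lefty": {"kind": "exp", "a": 100.0, "lambda_um": lam,
                          "c": 10.0, "sender_value": 110.0}}}
            stack, _ = render_juxtaposition_image(spec, p, seed=seed)
            sender = segment_sender_mask(stack.channel("marker"))
            prof = border_profile(stack.channel("lefty"), sender, ~sender,
                                  2.0, 5.0)
            fit = fit_exponential_decay(prof)
            assert fit.converged
            assert fit.decay_length_um == pytest.approx(lam, rel=0.15)


class TestRangeInTiers:
    def test_threshold_distance_70um_is_seven_tiers(self):
        from nodalrelay.juxta import BorderProfile

        edges = 5.0 * np.arange(21)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean = np.where(centers < 70.0, 100.0, 0.0)
        prof = BorderProfile(edges, mean, np.full(20, 10.0), 0.0, 10)
        assert range_in_cell_tiers(prof, 10.0, 0.1) == 7.0

    def test_fit_closed_form_conversion(self):
        from nodalrelay.juxta import DecayFit

        fit = DecayFit(100.0, 60.0, 0.0, 0.0, converged=True)
        tiers = range_in_cell_tiers(fit, 10.0, 0.1)
        assert tiers == pytest.approx(60.0 * np.log(10.0) / 10.0, rel=1e-12)
        assert tiers == pytest.approx(13.8, abs=0.02)

    def test_one_tier_band_stays_within_one_tier(self):
        """A juxtacrine-range band (signal only in cells touching the
        border) reads out as <= 1 cell tier."""
        p = RenderParams(shape_px=(60, 240), um_per_px=1.0)
        # border between pixel centers; band is one cell diameter minus the
        # half-pixel geometric offset of the center-to-center distance map
        spec = {"border_x_um": 100.0, "channels": {
            "nodal": {"kind": "band", "width_um": 9.0, "amplitude": 80.0,
                      "c": 2.0, "sender_value": 90.0}}}
        stack, _ = render_juxtaposition_image(spec, p, seed=0)
        sender = stack.channel("marker") > 60.0
        prof = border_profile(stack.channel("nodal"), sender, ~sender,
                              1.0, 5.0)
        assert range_in_cell_tiers(prof, 10.0, 0.1) <= 1.0
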