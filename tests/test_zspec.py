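"""Line-shape algebra, Z-spectrum model and per-pixel/per-image MAP fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cestpipe import AcquisitionConfig
from cestpipe.phantom import make_phantom, simulate_cest_series
from cestpipe.zspec import (
    LorentzianPeak,
    PeakModel,
    fit_image,
    fit_pixel,
    lorentzian_value,
    model_zspectrum,
    normalize_zspectrum,
    peak_area,
)


class TestLorentzian:
    def test_maximum_and_half_width(self):
        pk = LorentzianPeak("amide", 3.5, 0.05, 1.0)
        assert lorentzian_value(3.5, pk) == pytest.approx(0.05)
        assert lorentzian_value(3.5 + 0.5, pk) == pytest.approx(0.025)
        assert lorentzian_value(3.5 - 0.5, pk) == pytest.approx(0.025)

    @settings(max_examples=50, derandomize=True)
    @given(delta=st.floats(0, 20), c=st.floats(-4, 4), w=st.floats(0.2, 8))
    def test_even_about_center(self, delta, c, w):
        pk = LorentzianPeak("water", c, 0.5, w)
        assert lorentzian_value(c + delta, pk) == pytest.approx(
            lorentzian_value(c - delta, pk), rel=1e-12)

    def test_area_matches_quadrature_on_random_peaks(self, rng):
        for _ in range(100):
            pk = LorentzianPeak("x", rng.uniform(-4, 4), rng.uniform(0.01, 1.0),
                                rng.uniform(0.2, 8.0))
            ref, _ = quad(lambda f: lorentzian_value(f, pk),
                          pk.center - 2000 * pk.fwhm, pk.center + 2000 * pk.fwhm,
                          limit=400)
            assert peak_area(pk) == pytest.approx(ref, rel=1e-3)

    def test_area_closed_form_and_linearity(self):
        pk = LorentzianPeak("amide", 3.5, 0.05, 1.0)
        assert peak_area(pk) == pytest.approx(0.0785, abs=5e-5)
        double = LorentzianPeak("amide", 3.5, 0.10, 1.0)
        assert peak_area(double) == pytest.approx(2 * peak_area(pk))
        assert peak_area(LorentzianPeak("amide", 3.5, 0.0, 1.0)) == 0.0

    def test_invalid_peaks_rejected(self):
        with pytest.raises(ValueError):
            LorentzianPeak("x", 0.0, 1.5, 1.0)
        with pytest.raises(ValueError):
            LorentzianPeak("x", 0.0, 0.5, -1.0)


class TestModelZSpectrum:
    def test_empty_model_is_unity(self, offsets):
        assert np.allclose(model_zspectrum(offsets, []), 1.0)

    def test_b0_shift_moves_water_minimum(self):
        f = np.linspace(-2, 2, 4001)
        z = model_zspectrum(f, [LorentzianPeak("water", 0.0, 0.9, 2.0)], b0_shift=0.1)
        assert f[np.argmin(z)] == pytest.approx(0.1, abs=2e-3)

    def test_matches_term_by_term_summation(self, offsets, five_pool_truth):
        z = model_zspectrum(offsets, five_pool_truth)
        # independent hand summation of the line-shape formula
        hand = np.ones_like(offsets)
        for pk in five_pool_truth:
            hand -= pk.amplitude / (1 + ((offsets - pk.center) / (pk.fwhm / 2)) ** 2)
        assert np.allclose(z, np.clip(hand, 0, None), atol=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(amp=st.floats(0.0, 0.3), w=st.floats(0.5, 6.0))
    def test_never_exceeds_unity(self, offsets, amp, w):
        peaks = [LorentzianPeak("water", 0.0, 0.8, 2.0),
                 LorentzianPeak("amide", 3.5, amp, w)]
        assert np.all(model_zspectrum(offsets, peaks) <= 1.0 + 1e-12)


class TestNormalize:
    def test_identity_and_direct_division(self, offsets):
        n = offsets.size
        ref = np.full((2, 2), 2.0)
        raw = np.full((2, 2, n), 2.0)
        raw[0, 0, 0] = 1.0
        grid = normalize_zspectrum(raw, ref, offsets)
        assert grid.z[0, 0, 0] == pytest.approx(0.5)
        assert np.allclose(grid.z[1, 1], 1.0)

    def test_bad_reference_pixels_dropped(self, offsets):
        n = offsets.size
        ref = np.ones((2, 2))
        ref[0, 1] = 0.0
        grid = normalize_zspectrum(np.ones((2, 2, n)), ref, offsets)
        assert not grid.mask[0, 1] and grid.mask.sum() == 3

    def test_all_zero_reference_aborts(self, offsets):
        with pytest.raises(ValueError, match="non-positive"):
            normalize_zspectrum(np.ones((2, 2, offsets.size)), np.zeros((2, 2)), offsets)


class TestFitPixel:
    def test_noiseless_five_pool_round_trip(self, offsets, five_pool_truth):
        z = model_zspectrum(offsets, five_pool_truth)
        res = fit_pixel(offsets, z)
        assert res.converged
        for truth in five_pool_truth:
            got = res.peaks[truth.name]
            assert got.amplitude == pytest.approx(truth.amplitude, rel=1e-3)
            assert got.fwhm == pytest.approx(truth.fwhm, rel=1e-3)
            if truth.name != "water":
                assert got.center == pytest.approx(truth.center, abs=5e-3)

    def test_null_spectrum_gives_null_solute_amplitudes(self, offsets):
        res = fit_pixel(offsets, np.ones_like(offsets))
        for name in ("hydroxyl", "amine", "amide", "noe_mt"):
            assert res.peaks[name].amplitude <= 1e-4

    def test_b0_shift_recovered_within_stability_bound(self, offsets, five_pool_truth):
        z = model_zspectrum(offsets, five_pool_truth, b0_shift=0.08)
        res = fit_pixel(offsets, z)
        assert res.b0_shift == pytest.approx(0.08, abs=0.02)

    def test_too_few_offsets_rejected(self):
        f = np.linspace(-6, 6, 20)
        with pytest.raises(ValueError, match="at least"):
            fit_pixel(f, np.ones_like(f))

    def test_non_finite_samples_dropped(self, offsets, five_pool_truth):
        z = model_zspectrum(offsets, five_pool_truth)
        z[3] = np.nan
        res = fit_pixel(offsets, z)
        assert res.converged
        assert res.peaks["amide"].amplitude == pytest.approx(0.05, rel=1e-3)

    def test_monotone_contrast_propagation(self, offsets, five_pool_truth):
        base = fit_pixel(offsets, model_zspectrum(offsets, five_pool_truth))
        scaled_truth = [LorentzianPeak(p.name, p.center,
                                       p.amplitude * (1.5 if p.name == "amide" else 1.0),
                                       p.fwhm)
                        for p in five_pool_truth]
        scaled = fit_pixel(offsets, model_zspectrum(offsets, scaled_truth))
        ratio = scaled.area("amide") / base.area("amide")
        assert ratio == pytest.approx(1.5, rel=1e-3)

    def test_random_noiseless_truths_recovered(self, offsets, rng):
        model = PeakModel.default()
        for _ in range(25):
            truth = [
                LorentzianPeak("water", 0.0, rng.uniform(0.6, 0.9), rng.uniform(1.2, 3.5)),
                LorentzianPeak("hydroxyl", 1.2 + rng.uniform(-0.3, 0.3),
                               rng.uniform(0.01, 0.06), rng.uniform(0.5, 1.8)),
                LorentzianPeak("amine", 2.4 + rng.uniform(-0.3, 0.3),
                               rng.uniform(0.01, 0.08), rng.uniform(0.5, 2.0)),
                LorentzianPeak("amide", 3.5 + rng.uniform(-0.3, 0.3),
                               rng.uniform(0.01, 0.08), rng.uniform(0.5, 2.0)),
                LorentzianPeak("noe_mt", rng.uniform(-4.0, -2.0),
                               rng.uniform(0.03, 0.2), rng.uniform(2.5, 8.0)),
            ]
            z = model_zspectrum(offsets, truth, b0_shift=rng.uniform(-0.1, 0.1))
            res = fit_pixel(offsets, z, model)
            for tp in truth:
                fp = res.peaks[tp.name]
                assert fp.amplitude == pytest.approx(tp.amplitude, rel=1e-2)
                assert fp.fwhm == pytest.approx(tp.fwhm, rel=1e-2)
                if tp.name != "water":
                    assert fp.center == pytest.approx(tp.center, rel=1e-2)

    def test_area_accessor_closed_form(self, offsets, five_pool_truth):
        res = fit_pixel(offsets, model_zspectrum(offsets, five_pool_truth))
        for name, pk in res.peaks.items():
            assert res.area(name) == pytest.approx(
                np.pi / 2 * pk.amplitude * pk.fwhm, rel=1e-12)


class TestFitImage:
    def test_noiseless_phantom_amide_area_map(self):
        cfg = AcquisitionConfig(grid_size=10, noise_sigma=0.0, seed=3)
        truth = make_phantom(cfg)
        grid = simulate_cest_series(truth, cfg)
        maps = fit_image(grid, n_starts=1)
        amide_truth = (np.pi / 2) * truth.pools["amide"]["amplitude"] \
            * truth.pools["amide"]["fwhm"]
        got = maps["amide_area"].data[truth.mask]
        want = amide_truth[truth.mask]
        assert np.nanmax(np.abs(got - want) / want) < 1e-2

    def test_empty_mask_yields_empty_maps(self, offsets):
        n = offsets.size
        grid = normalize_zspectrum(np.ones((4, 4, n)), np.ones((4, 4)), offsets,
                                   mask=np.zeros((4, 4), dtype=bool))
        maps = fit_image(grid)
        assert np.all(np.isnan(maps["amide_area"].data))
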