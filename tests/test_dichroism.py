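"""Dichroism forward model and per-pixel harmonic fit."""

import numpy as np
import pytest

from enamelpic import (
    DichroismParams,
    PICMap,
    PolarizationStack,
    build_pic_map,
    default_polarization_angles,
    dichroic_ratio,
    fit_pixel,
    fold_c_prime,
    simulate_stack,
)

from _oracles import grid_search_fit


def c_prime_error(a, b):
    d = np.abs(fold_c_prime(np.asarray(a) - np.asarray(b)))
    return np.minimum(d, 180.0 - d)


class TestDichroicRatio:
    def test_axis_along_beam_is_flat(self):
        p = DichroismParams(baseline_a=1.2, amplitude_b=0.7)
        chis = np.arange(0.0, 91.0, 5.0)
        assert np.allclose(dichroic_ratio(chis, -40.0, 90.0, p), 1.2)

    def test_maximum_at_parallel_polarization(self):
        p = DichroismParams(baseline_a=1.0, amplitude_b=0.5)
        assert dichroic_ratio(37.0, 37.0, 0.0, p) == pytest.approx(1.5)
        assert dichroic_ratio(0.0, 0.0, 60.0, p) == pytest.approx(1.125)

    def test_period_180_in_chi(self):
        p = DichroismParams()
        assert dichroic_ratio(25.0, 10.0, 20.0, p) == pytest.approx(
            dichroic_ratio(205.0, 10.0, 20.0, p)
        )


class TestSimulateStack:
    def test_single_pixel_traces_closed_form(self):
        p = DichroismParams(baseline_a=1.0, amplitude_b=0.5)
        pic = PICMap(np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1), bool))
        st = simulate_stack(pic, p, seed=0)
        expected = 1.0 + 0.5 * np.cos(np.radians(st.angles_deg)) ** 2
        assert np.allclose(st.ratio_images[:, 0, 0], expected)
        assert len(st.angles_deg) == 19

    def test_same_seed_is_bit_identical(self, rng):
        cp = rng.uniform(-90, 90, (8, 8))
        g = rng.uniform(0, 60, (8, 8))
        pic = PICMap(cp, g, np.ones((8, 8), bool))
        p = DichroismParams(noise_sigma=0.05)
        a = simulate_stack(pic, p, seed=99)
        b = simulate_stack(pic, p, seed=99)
        assert np.array_equal(a.ratio_images, b.ratio_images)

    def test_masked_pixel_emits_flat_baseline(self):
        pic = PICMap(np.zeros((1, 2)), np.zeros((1, 2)), np.array([[True, False]]))
        st = simulate_stack(pic, DichroismParams(baseline_a=2.0), seed=0)
        assert np.allclose(st.ratio_images[:, 0, 1], 2.0)
        assert np.ptp(st.ratio_images[:, 0, 0]) > 0.5


class TestFitPixel:
    def test_noiseless_round_trip(self):
        p = DichroismParams()
        angles = default_polarization_angles()
        values = dichroic_ratio(angles, 37.0, 20.0, p)
        cp, g, amp, rms, valid = fit_pixel(values, angles, p)
        assert valid
        assert cp == pytest.approx(37.0, abs=1e-6)
        assert g == pytest.approx(20.0, abs=1e-4)
        assert rms < 1e-10

    def test_matches_grid_search_oracle(self):
        p = DichroismParams()
        angles = default_polarization_angles()
        for cp_true, g_true in [(-62.0, 12.0), (5.0, 45.0), (80.0, 70.0)]:
            values = dichroic_ratio(angles, cp_true, g_true, p)
            cp_fit, g_fit, *_ , valid = fit_pixel(values, angles, p)
            cp_or, g_or = grid_search_fit(values, angles, p.baseline_a, p.amplitude_b)
            assert valid
            assert c_prime_error(cp_fit, cp_or) < 0.02
            assert abs(g_fit - g_or) < 0.02

    def test_flat_series_is_masked(self):
        p = DichroismParams()
        angles = default_polarization_angles()
        cp, g, amp, _, valid = fit_pixel(np.full(19, p.baseline_a), angles, p)
        assert not valid and np.isnan(cp) and amp < 1e-10

    def test_director_periodicity_folds(self):
        p = DichroismParams()
        angles = default_polarization_angles()
        v1 = dichroic_ratio(angles, -89.0, 0.0, p)
        v2 = dichroic_ratio(angles, fold_c_prime(91.0), 0.0, p)
        cp1 = fit_pixel(v1, angles, p)[0]
        cp2 = fit_pixel(v2, angles, p)[0]
        assert cp1 == pytest.approx(cp2, abs=1e-6) == pytest.approx(-89.0, abs=1e-6)

    def test_calibration_error_raised(self):
        p = DichroismParams(amplitude_b=0.3)
        angles = default_polarization_angles()
        values = dichroic_ratio(angles, 0.0, 0.0, DichroismParams(amplitude_b=1.0))
        with pytest.raises(ValueError, match="calibration"):
            fit_pixel(values, angles, p)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_pixel([1.0, 1.1], [0.0, 45.0], DichroismParams())


class TestBuildPICMap:
    def test_round_trip_identity_noiseless(self, rng):
        cp = rng.uniform(-90, 90, (40, 40))
        g = rng.uniform(0, 75, (40, 40))
        mask = rng.random((40, 40)) > 0.1
        pic = PICMap(np.where(mask, cp, np.nan), np.where(mask, g, np.nan), mask, 22.0)
        p = DichroismParams()
        rec = build_pic_map(simulate_stack(pic, p, seed=3), p)
        assert np.array_equal(rec.mask, mask)
        assert np.nanmax(c_prime_error(rec.c_prime_deg, pic.c_prime_deg)) < 0.1
        assert np.nanmax(np.abs(rec.gamma_deg - pic.gamma_deg)) < 0.1
        assert rec.pixel_size_nm == 22.0
        assert rec.residual_rms is not None and np.nanmax(rec.residual_rms) < 1e-8

    def test_noisy_recovery_median_error(self, rng):
        cp = rng.uniform(-90, 90, (100, 100))
        g = rng.uniform(0, 75, (100, 100))
        pic = PICMap(cp, g, np.ones((100, 100), bool))
        p = DichroismParams(noise_sigma=0.01)
        rec = build_pic_map(simulate_stack(pic, p, seed=7), p)
        err = c_prime_error(rec.c_prime_deg, cp)[rec.mask]
        assert np.median(err) < 1.0

    def test_equivariance_under_c_prime_shift(self, rng):
        cp = rng.uniform(-90, 90, (20, 20))
        g = rng.uniform(0, 60, (20, 20))
        p = DichroismParams()
        base = build_pic_map(
            simulate_stack(PICMap(cp, g, np.ones((20, 20), bool)), p, seed=0), p
        )
        shifted = build_pic_map(
            simulate_stack(PICMap(fold_c_prime(cp + 25.0), g, np.ones((20, 20), bool)), p, seed=0), p
        )
        dev = c_prime_error(shifted.c_prime_deg, fold_c_prime(base.c_prime_deg + 25.0))
        assert np.nanmax(dev) < 1e-6

    def test_all_masked_input_stays_masked(self):
        mask = np.zeros((5, 5), bool)
        pic = PICMap(np.full((5, 5), np.nan), np.full((5, 5), np.nan), mask)
        p = DichroismParams()
        rec = build_pic_map(simulate_stack(pic, p, seed=0), p)
        assert not rec.mask.any()

    def test_near_beam_axis_degrades_into_mask(self):
        # gamma -> 90 kills the dichroic amplitude; the fit must reject, not err
        g = np.array([[0.0, 60.0, 80.0, 89.0, 90.0]])
        pic = PICMap(np.zeros_like(g), g, np.ones_like(g, dtype=bool))
        p = DichroismParams()
        rec = build_pic_map(simulate_stack(pic, p, seed=0), p)
        assert rec.mask[0, 0] and rec.mask[0, 1]
        assert not rec.mask[0, 3] and not rec.mask[0, 4]


def test_stack_invariants():
    with pytest.raises(ValueError):
        PolarizationStack(np.array([0.0, 45.0]), np.ones((3, 2, 2)))
    with pytest.raises(ValueError):
        PolarizationStack(np.array([0.0]), np.zeros((1, 2, 2)))
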