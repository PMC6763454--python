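"""Fracture energy, toughness, periodicity angles, tensor rotation, strain fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enamelpic import (
    A_Z_ANGSTROM,
    BiCrystalGeometry,
    StressStrainCurve,
    critical_energy_release_rate,
    fit_strain_profile,
    fracture_toughness,
    hexagonal_tensor,
    infer_lx,
    layer_tensors,
    mastication_pressure,
    periodic_misorientation_angle,
    rotate_elastic_tensor,
)
from enamelpic.mechanics import ElasticTensor, rotation_matrix_y

from _oracles import riemann_integral, rotate_full_tensor


def triangular_curve(k=50.0, eps0=0.1, l_z=20.0):
    eps = np.array([0.0, eps0, eps0 + 1e-9, 0.3])
    sig = np.array([0.0, k * eps0, 0.0, 0.0])
    return StressStrainCurve(eps, sig, l_z)


class TestEnergyReleaseRate:
    def test_triangular_closed_form(self):
        k, eps0, l_z = 50.0, 0.1, 20.0
        g = critical_energy_release_rate(triangular_curve(k, eps0, l_z))
        assert g == pytest.approx(l_z * k * eps0**2 / 2, rel=1e-6)

    def test_zero_stress_gives_zero(self):
        c = StressStrainCurve(np.linspace(0, 0.3, 10), np.zeros(10), 25.0)
        assert critical_energy_release_rate(c) == 0.0

    def test_matches_rectangle_rule_oracle(self, rng):
        eps = np.sort(np.concatenate([[0.0, 0.25], rng.uniform(0, 0.25, 20)]))
        sig = rng.uniform(0, 8, eps.size)
        c = StressStrainCurve(eps, sig, 30.0)
        got = critical_energy_release_rate(c)
        want = 30.0 * riemann_integral(eps, sig, 0.2)
        assert got == pytest.approx(want, rel=1e-3)

    def test_short_curve_rejected(self):
        c = StressStrainCurve(np.array([0.0, 0.1]), np.array([0.0, 5.0]), 20.0)
        with pytest.raises(ValueError, match="eps_max"):
            critical_energy_release_rate(c)

    def test_linear_in_stress_and_additive_in_strain(self):
        c = triangular_curve()
        g1 = critical_energy_release_rate(c)
        doubled = StressStrainCurve(c.strain, 2 * c.stress_gpa, c.gauge_length_nm)
        assert critical_energy_release_rate(doubled) == pytest.approx(2 * g1, rel=1e-9)
        half1 = 20.0 * np.trapezoid(
            np.interp([0.0, 0.05, 0.1], c.strain, c.stress_gpa), [0.0, 0.05, 0.1]
        )
        g_first_half = critical_energy_release_rate(c, eps_max=0.1)
        assert g_first_half == pytest.approx(half1, rel=1e-9)


class TestToughness:
    def test_printed_conversion(self):
        # G_c = 5.87 J/m^2 with E = 133.3 GPa gives the printed 0.88 MPa m^0.5
        assert round(fracture_toughness(5.87, 133.3e9), 2) == 0.88

    def test_zero_and_monotone(self):
        assert fracture_toughness(0.0, 1e9) == 0.0
        assert fracture_toughness(8.6, 133.3e9) == pytest.approx(
            np.sqrt(8.6 * 133.3e9) / 1e6, rel=1e-12
        )
        k1 = fracture_toughness(5.0, 100e9)
        assert fracture_toughness(6.0, 100e9) > k1 < fracture_toughness(5.0, 120e9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fracture_toughness(-1.0, 1e9)


class TestPeriodicityAngles:
    def test_printed_angle_set(self):
        lx = infer_lx(14.1, 1, A_Z_ANGSTROM)
        geo = BiCrystalGeometry(lx)
        assert round(periodic_misorientation_angle(geo, 2), 1) == 29.2
        assert round(periodic_misorientation_angle(geo, 3), 1) == 47.0

    def test_arcsin_of_one(self):
        geo = BiCrystalGeometry(2 * A_Z_ANGSTROM)
        assert periodic_misorientation_angle(geo, 2) == pytest.approx(90.0)

    def test_no_solution_beyond_lx(self):
        with pytest.raises(ValueError, match="no periodic solution"):
            periodic_misorientation_angle(BiCrystalGeometry(10.0), 2)

    def test_infer_lx_examples(self):
        assert infer_lx(14.1, 1, 6.86) == pytest.approx(28.16, abs=0.01)
        assert infer_lx(90.0, 1, 6.86) == pytest.approx(6.86)
        with pytest.raises(ValueError):
            infer_lx(0.0, 1)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(5.0, 89.0), st.integers(1, 4))
    def test_round_trip_identity(self, theta, n):
        lx = infer_lx(theta, n)
        assert periodic_misorientation_angle(BiCrystalGeometry(lx), n) == pytest.approx(
            theta, abs=1e-9
        )


HAP_LIKE = dict(c11=140.0, c12=45.0, c13=50.0, c33=170.0, c44=40.0)


class TestElasticTensor:
    def test_hexagonal_pattern(self):
        t = hexagonal_tensor(**HAP_LIKE).matrix
        assert t[1, 1] == t[0, 0] and t[1, 2] == t[0, 2] and t[4, 4] == t[3, 3]
        assert t[5, 5] == pytest.approx((HAP_LIKE["c11"] - HAP_LIKE["c12"]) / 2)
        assert np.array_equal(t, t.T)

    def test_isotropic_inputs_give_isotropic_matrix(self):
        c11, c12 = 100.0, 40.0
        t = hexagonal_tensor(c11, c12, c12, c11, (c11 - c12) / 2).matrix
        assert t[0, 0] == t[2, 2] and t[3, 3] == t[5, 5] == (c11 - c12) / 2

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            hexagonal_tensor(50.0, 60.0, 10.0, 80.0, 30.0)

    def test_asymmetric_matrix_rejected(self):
        m = np.eye(6)
        m[0, 1] = 5.0
        with pytest.raises(ValueError):
            ElasticTensor(m)


class TestRotation:
    def test_zero_rotation_is_identity(self):
        c = hexagonal_tensor(**HAP_LIKE)
        assert np.allclose(rotate_elastic_tensor(c, 0.0).matrix, c.matrix, atol=1e-12)

    def test_inverse_rotation(self):
        c = hexagonal_tensor(**HAP_LIKE)
        back = rotate_elastic_tensor(rotate_elastic_tensor(c, 33.0), -33.0)
        assert np.allclose(back.matrix, c.matrix, atol=1e-9)

    def test_90_degrees_swaps_axes_1_and_3(self):
        c = hexagonal_tensor(**HAP_LIKE)
        r = rotate_elastic_tensor(c, 90.0).matrix
        assert r[0, 0] == pytest.approx(c.matrix[2, 2], abs=1e-9)
        assert r[2, 2] == pytest.approx(c.matrix[0, 0], abs=1e-9)

    def test_matches_full_tensor_oracle_random(self, rng):
        for _ in range(100):
            a = rng.normal(size=(6, 6))
            c6 = a @ a.T + 6 * np.eye(6)
            theta = float(rng.uniform(-180, 180))
            got = rotate_elastic_tensor(ElasticTensor(c6), theta).matrix
            want = rotate_full_tensor(c6, rotation_matrix_y(theta))
            assert np.allclose(got, want, atol=1e-9)

    def test_spectrum_invariant(self, rng):
        a = rng.normal(size=(6, 6))
        c6 = a @ a.T + 6 * np.eye(6)
        # the 4th-order rotation preserves strain energy; in Voigt form the
        # eigenvalues of the Kelvin-normalised matrix are invariant
        k = np.diag([1, 1, 1, np.sqrt(2), np.sqrt(2), np.sqrt(2)])
        ev0 = np.sort(np.linalg.eigvalsh(k @ c6 @ k))
        ev1 = np.sort(
            np.linalg.eigvalsh(k @ rotate_elastic_tensor(ElasticTensor(c6), 37.0).matrix @ k)
        )
        assert np.allclose(ev0, ev1, atol=1e-8)

    def test_layer_tensors_composition(self):
        c = hexagonal_tensor(**HAP_LIKE)
        layers = layer_tensors(c, 14.1)
        assert len(layers) == 10
        assert np.allclose(layers[0].matrix, c.matrix)
        assert np.allclose(layers[3].matrix, rotate_elastic_tensor(c, 42.3).matrix, atol=1e-9)
        flat = layer_tensors(c, 0.0, n_layers=4)
        for t in flat:
            assert np.allclose(t.matrix, c.matrix)


class TestStrainProfile:
    def test_noiseless_recovery(self):
        y = np.linspace(0, 30, 40)
        e = 0.05 * np.exp(-0.1 * y) + 0.01
        fit = fit_strain_profile(y, e)
        assert fit.p == pytest.approx(0.05, abs=1e-6)
        assert fit.q == pytest.approx(0.1, abs=1e-6)
        assert fit.r == pytest.approx(0.01, abs=1e-6)
        assert fit.residual_rms < 1e-9

    def test_constant_data(self):
        fit = fit_strain_profile(np.linspace(0, 20, 10), np.full(10, 0.02))
        assert abs(fit.p) < 1e-6
        assert fit.p + fit.r == pytest.approx(0.02, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_strain_profile([0, 1, 2], [1.0, 0.5, 0.2])


class TestMasticationPressure:
    def test_canonical_and_max_bite(self):
        assert mastication_pressure(1000.0, 1.0) == pytest.approx(1.0)
        assert mastication_pressure(770.0, 1.0) == pytest.approx(0.77)
        assert mastication_pressure(0.0, 1.0) == 0.0

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            mastication_pressure(100.0, 0.0)
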