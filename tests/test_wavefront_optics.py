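"""Zernike evaluation, pupil/PSF physics and coefficient manipulations."""

import math

import numpy as np
import pytest

from vapredict.wavefront_optics import (PupilGrid, ZernikeSet,
                                        apply_correction,
                                        apply_defocus_condition,
                                        diopter_to_z20, psf_from_pupil,
                                        pupil_function, spherical_equivalent,
                                        strehl_ratio, vergence_correction,
                                        wavefront, zernike_polynomial)


@pytest.mark.parametrize("j, rho, theta, expected", [
    (0, 0.3, 1.1, 1.0),                       # piston is constant
    (4, 1.0, 0.0, math.sqrt(3)),              # Z_2^0 = sqrt3 (2 rho^2 - 1)
    (3, 1.0, math.pi / 4, math.sqrt(6)),      # Z_2^-2 = sqrt6 rho^2 sin 2theta
    (5, 1.0, 0.0, math.sqrt(6)),              # Z_2^+2 = sqrt6 rho^2 cos 2theta
])
def test_zernike_closed_forms(j, rho, theta, expected):
    assert zernike_polynomial(j, rho, theta) == pytest.approx(expected, abs=1e-12)


def test_zernike_domain_and_index_errors():
    with pytest.raises(IndexError):
        zernike_polynomial(36, 0.5, 0.0)
    with pytest.raises(ValueError):
        zernike_polynomial(4, 1.2, 0.0)


def test_zernike_orthonormality_sampled():
    """Unit-variance normalization: <Z_j^2> = 1 over the disc (Monte Carlo)."""
    rng = np.random.default_rng(0)
    rho = np.sqrt(rng.uniform(0, 1, 200_000))  # area-uniform disc sampling
    theta = rng.uniform(0, 2 * math.pi, 200_000)
    for j in (1, 4, 7, 12):
        var = np.mean(zernike_polynomial(j, rho, theta) ** 2)
        assert var == pytest.approx(1.0, rel=0.02)


def test_wavefront_single_term_and_superposition(small_grid):
    z = ZernikeSet.zeros()
    assert np.all(wavefront(z, small_grid) == 0)
    c = z.coeffs.copy()
    c[3], c[4] = 0.2, 0.5
    w = wavefront(z.with_coeffs(c), small_grid)
    # brute-force pointwise oracle
    x, y = small_grid.unit_coords()
    rho, theta = np.hypot(x, y), np.arctan2(y, x)
    inside = rho <= 1
    expected = (0.2 * zernike_polynomial(3, rho[inside], theta[inside])
                + 0.5 * zernike_polynomial(4, rho[inside], theta[inside]))
    np.testing.assert_allclose(w[inside], expected, atol=1e-12)
    assert np.all(w[~inside] == 0)


def test_pupil_function_amplitude_and_phase(small_grid, zero_zernikes):
    p = pupil_function(zero_zernikes, small_grid, rho_sc=0.0)
    assert np.allclose(np.abs(p.field[p.mask]), 1.0)
    assert np.allclose(np.angle(p.field[p.mask]), 0.0)
    # Stiles-Crawford apodization at the pupil margin: 10^(-rho r^2 / 2)
    p = pupil_function(zero_zernikes, small_grid, rho_sc=0.05)
    edge = 10 ** (-0.05 * 1.5 ** 2 / 2)
    assert np.abs(p.field[p.mask]).min() == pytest.approx(edge, rel=1e-3)
    assert np.all(np.abs(p.field) <= 1.0 + 1e-12)
    assert np.all(p.field[~p.mask] == 0)


def test_psf_normalization_and_parseval(small_grid, zero_zernikes):
    p = pupil_function(zero_zernikes, small_grid)
    psf = psf_from_pupil(p)
    assert psf.data.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(psf.data >= 0)
    # Parseval: energy of the padded pupil equals spectrum energy / N^2
    n_pad = small_grid.n_padded
    padded = np.zeros((n_pad, n_pad), complex)
    padded[:small_grid.n, :small_grid.n] = p.field
    spec_energy = (np.abs(np.fft.fft2(padded)) ** 2).sum() / n_pad ** 2
    field_energy = (np.abs(p.field) ** 2).sum()
    assert spec_energy == pytest.approx(field_energy, rel=1e-6)


def test_pure_defocus_psf_rotational_symmetry(small_grid, defocus_zernikes):
    psf = psf_from_pupil(pupil_function(defocus_zernikes(0.3), small_grid))
    n = psf.data.shape[0]
    c, w = n // 2, n // 2 - 2
    s = psf.data[c - w:c + w + 1, c - w:c + w + 1]
    assert np.abs(s - np.rot90(s)).max() < 1e-6


def test_strehl_bounds_and_center_point_oracle(small_grid, defocus_zernikes):
    assert strehl_ratio(ZernikeSet.zeros(), small_grid) == pytest.approx(1.0)
    s = strehl_ratio(defocus_zernikes(0.3), small_grid)
    assert 0 < s < 1
    # central PSF point equals |sum P|^2 (integral of the pupil
    # autocorrelation over all frequency shifts), checked against the oracle
    p = pupil_function(defocus_zernikes(0.3), small_grid)
    p0 = pupil_function(ZernikeSet.zeros(), small_grid)
    oracle = np.abs(p.field.sum()) ** 2 / np.abs(p0.field.sum()) ** 2
    psf = psf_from_pupil(p, normalize=False)
    ref = psf_from_pupil(p0, normalize=False)
    n = psf.data.shape[0]
    center_ratio = psf.data[n // 2, n // 2] / ref.data[n // 2, n // 2]
    assert center_ratio == pytest.approx(oracle, rel=1e-9)


@pytest.mark.parametrize("d, r, expected", [
    (0.0, 1.5, 0.0),
    (1.0, 1.5, 2.25 / (4 * math.sqrt(3))),
    (-3.0, 1.5, -0.97428),
])
def test_diopter_to_z20_values(d, r, expected):
    assert diopter_to_z20(d, r) == pytest.approx(expected, abs=1e-5)


def test_diopter_to_z20_linear_in_d_quadratic_in_r():
    for d in (-2.0, -0.5, 0.75, 3.0):
        for r in (1.0, 1.5, 2.5):
            assert diopter_to_z20(2 * d, r) == pytest.approx(2 * diopter_to_z20(d, r))
            assert diopter_to_z20(d, 2 * r) == pytest.approx(4 * diopter_to_z20(d, r))


def test_apply_correction_zeroes_second_order_only():
    z = ZernikeSet.zeros()
    c = z.coeffs.copy()
    c[3], c[4], c[5], c[7], c[12] = 0.2, 0.5, -0.3, 0.1, 0.05
    out = apply_correction(z.with_coeffs(c))
    assert out.coeffs[3] == out.coeffs[4] == out.coeffs[5] == 0
    assert out.coeffs[7] == 0.1 and out.coeffs[12] == 0.05
    assert np.all(apply_correction(ZernikeSet.zeros()).coeffs == 0)


def test_apply_defocus_condition_matches_correction_at_zero():
    rng = np.random.default_rng(1)
    z = ZernikeSet(rng.normal(0, 0.1, 36))
    np.testing.assert_array_equal(apply_defocus_condition(z, 0.0).coeffs,
                                  apply_correction(z).coeffs)
    out = apply_defocus_condition(z, 1.0)
    assert out.coeffs[4] == pytest.approx(0.32476, abs=1e-5)
    assert out.coeffs[3] == 0 and out.coeffs[5] == 0
    # nine clinical levels give strictly increasing defocus coefficients
    c4s = [apply_defocus_condition(z, -3.0 + 0.5 * k).coeffs[4] for k in range(9)]
    assert np.all(np.diff(c4s) > 0)


@pytest.mark.parametrize("s, c, expected", [
    (0.0, 0.0, 0.0), (-2.0, -1.0, -2.5), (1.0, -0.5, 0.75),
])
def test_spherical_equivalent(s, c, expected):
    assert spherical_equivalent(s, c) == expected


def test_vergence_correction_at_4m():
    assert vergence_correction(4.0) == pytest.approx(-0.25)
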