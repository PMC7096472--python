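import numpy as np
import pytest

from ansindex.laguerre import laguerre_basis
from ansindex.spectral import (band_integral, instantaneous_bispectrum,
                               instantaneous_spectrum, integrate_bispectrum,
                               integrate_spectrum, volterra_kernel)


@pytest.fixture(scope="module")
def basis():
    return laguerre_basis(0.2, 8, 300)


def ar1_g1(basis, c=0.5):
    """Laguerre coefficients reproducing the kernel k1 = [c, 0, 0, ...]."""
    return basis.phi[:, 0] * c


class TestSpectrum:
    def test_white_case_flat(self, basis):
        freqs, Q = instantaneous_spectrum(np.zeros(9), basis, 2.0, 1.0)
        np.testing.assert_allclose(Q, 2.0 * 2.0 * 1.0, rtol=1e-12)

    def test_ar1_closed_form(self, basis):
        g1 = ar1_g1(basis, 0.5)
        freqs = np.arange(0.0, 0.5 + 1e-12, 0.0025)
        dt, s2 = 1.0, 2.0
        _, Q = instantaneous_spectrum(g1, basis, s2, dt, freqs)
        closed = 2 * s2 * dt / np.abs(
            1 - 0.5 * np.exp(-2j * np.pi * freqs * dt))**2
        assert np.linalg.norm(Q - closed) / np.linalg.norm(closed) < 0.01

    def test_parseval(self, basis):
        g1 = ar1_g1(basis, 0.5)
        dt, s2 = 1.0, 2.0
        freqs = np.arange(0.0, 0.5 + 1e-12, 0.0005)
        _, Q = instantaneous_spectrum(g1, basis, s2, dt, freqs)
        total = np.trapezoid(Q, freqs)
        expected = s2 / (1 - 0.25)  # AR(1) process variance
        assert abs(total - expected) / expected < 0.02

    def test_kernel_roundtrip(self, basis):
        g1 = np.array([0.1, -0.2, 0.05, 0, 0, 0, 0, 0, 0])
        k1 = volterra_kernel(g1, basis)
        # orthonormality: projecting back recovers g1
        back = basis.phi[:9] @ k1
        np.testing.assert_allclose(back, g1, atol=1e-10)


class TestIntegrateSpectrum:
    def test_constant_spectrum(self):
        f = np.arange(0.0, 0.5 + 1e-12, 0.005)
        Q = np.full(f.size, 3.0)
        lf, hf, ratio = integrate_spectrum(f, Q)
        assert lf == pytest.approx(3.0 * (0.15 - 0.04), rel=1e-9)
        assert hf == pytest.approx(3.0 * (0.4 - 0.15), rel=1e-9)
        assert ratio == pytest.approx(lf / hf)

    def test_delta_peak_in_hf(self):
        f = np.arange(0.0, 0.5 + 1e-12, 0.005)
        Q = np.zeros(f.size)
        Q[np.argmin(np.abs(f - 0.25))] = 100.0
        lf, hf, _ = integrate_spectrum(f, Q)
        assert lf == 0.0
        assert hf > 0.0

    def test_refinement_oracle(self, rng, basis):
        # model-generated (smooth) random spectra: the coarse-grid integral
        # matches the halved-step quadrature within 0.5%
        for _ in range(5):
            g1 = rng.standard_normal(9) * 0.1
            f = np.arange(0.0, 0.5 + 1e-12, 0.005)
            fr = np.arange(0.0, 0.5 + 1e-12, 0.0025)
            _, Q = instantaneous_spectrum(g1, basis, 1.0, 1.0, f)
            _, Qr = instantaneous_spectrum(g1, basis, 1.0, 1.0, fr)
            lf, hf, _ = integrate_spectrum(f, Q)
            lf_r, hf_r, _ = integrate_spectrum(fr, Qr)
            assert abs(lf - lf_r) / lf_r < 0.005
            assert abs(hf - hf_r) / hf_r < 0.005

    def test_band_outside_grid_rejected(self):
        f = np.arange(0.0, 0.3, 0.005)
        with pytest.raises(ValueError):
            integrate_spectrum(f, np.ones(f.size), hf_band=(0.15, 0.4))


class TestBispectrum:
    def test_zero_quadratic_kernel(self, basis):
        g1 = ar1_g1(basis, 0.3)
        _, B = instantaneous_bispectrum(g1, np.zeros((3, 3)), basis, 1.0, 1.0)
        assert B.max() < 1e-10

    def test_symmetry(self, basis):
        rng = np.random.default_rng(0)
        G = rng.standard_normal((3, 3)) * 0.01
        G = (G + G.T) / 2
        _, B = instantaneous_bispectrum(ar1_g1(basis, 0.2), G, basis, 1.0, 1.0)
        np.testing.assert_allclose(B, B.T, rtol=1e-9, atol=1e-15)

    def test_asymmetric_g2_rejected(self, basis):
        G = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            instantaneous_bispectrum(np.zeros(9), G, basis, 1.0, 1.0)

    def test_grid_beyond_nyquist_rejected(self, basis):
        freqs = np.arange(0.0, 0.45, 0.005)
        with pytest.raises(ValueError):
            instantaneous_bispectrum(np.zeros(9), np.zeros((2, 2)), basis,
                                     1.0, 1.5, freqs)  # Nyquist = 1/3 Hz

    def test_injected_coupling_located(self):
        # g2 built from the basis transfer vectors at (0.1, 0.25) Hz gives a
        # quadratic transfer peaked there (reproducing-kernel construction)
        b = laguerre_basis(0.2, 25, 300)
        from ansindex.spectral import _laguerre_transfer

        Phi = _laguerre_transfer(b, np.array([0.1, 0.25]), 1.0, 25)
        a1, a2 = np.conj(Phi[:, 0]), np.conj(Phi[:, 1])
        G = np.real(np.outer(a1, a2) + np.outer(a2, a1))
        G = (G + G.T) / 2
        freqs = np.arange(0.0, 0.4 + 1e-12, 0.005)
        _, B = instantaneous_bispectrum(np.zeros(1), G, b, 1.0, 1.0, freqs)
        iu = np.triu_indices(freqs.size)  # search f1 <= f2 (symmetric twin)
        flat = np.zeros_like(B)
        flat[iu] = B[iu]
        i, j = np.unravel_index(np.argmax(flat), B.shape)
        assert abs(freqs[i] - 0.1) <= 0.005 + 1e-9
        assert abs(freqs[j] - 0.25) <= 0.005 + 1e-9


class TestIntegrateBispectrum:
    def test_unit_field(self):
        f = np.arange(0.0, 0.4 + 1e-12, 0.005)
        ll, lh, hh = integrate_bispectrum(f, np.ones((f.size, f.size)))
        assert ll == pytest.approx(0.15**2, rel=1e-9)
        assert lh == pytest.approx(0.15 * 0.25, rel=1e-9)
        assert hh == pytest.approx(0.25**2, rel=1e-9)

    def test_zero_field(self):
        f = np.arange(0.0, 0.4 + 1e-12, 0.005)
        assert integrate_bispectrum(f, np.zeros((f.size, f.size))) == (0, 0, 0)

    def test_refinement_oracle(self, rng, basis):
        # model-generated random bispectra are smooth; coarse vs halved-step
        # quadrature agree within 1%
        fr = np.arange(0.0, 0.4 + 1e-12, 0.0025)
        f = fr[::2]
        for _ in range(3):
            g1 = rng.standard_normal(9) * 0.1
            G = rng.standard_normal((3, 3)) * 0.05
            G = (G + G.T) / 2
            _, Br = instantaneous_bispectrum(g1, G, basis, 1.0, 1.0, fr)
            _, Bc = instantaneous_bispectrum(g1, G, basis, 1.0, 1.0, f)
            a = integrate_bispectrum(f, Bc)
            b = integrate_bispectrum(fr, Br)
            for x, y in zip(a, b):
                assert abs(x - y) / abs(y) < 0.01

    def test_insufficient_grid_rejected(self):
        f = np.arange(0.0, 0.3, 0.005)
        with pytest.raises(ValueError):
            integrate_bispectrum(f, np.ones((f.size, f.size)))


class TestBandIntegral:
    def test_linear_function_exact(self):
        f = np.arange(0.0, 1.0 + 1e-12, 0.01)
        y = 2.0 * f + 1.0
        # trapezoid is exact for linear functions, any band
        val = band_integral(f, y, 0.123, 0.777)
        exact = (0.777**2 - 0.123**2) + (0.777 - 0.123)
        assert val == pytest.approx(exact, rel=1e-9)
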