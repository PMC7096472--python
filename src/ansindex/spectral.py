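"""Instantaneous spectra and bispectra of the fitted heartbeat model.

The Laguerre-domain coefficients are mapped back to Wiener-Volterra kernels;
the linear kernel acts as an AR-style feedback whose transfer function gives
the power spectrum, and the quadratic kernel's 2-D transform combined with
the linear transfer at f1, f2 and f1+f2 gives the magnitude bispectrum.
Frequencies are interpreted against the local mean heart period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .laguerre import LaguerreBasis
from .pointprocess import PointProcessFit

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralSeries", "BispectralSeries",
    "volterra_kernel", "linear_transfer", "instantaneous_spectrum",
    "band_integral", "integrate_spectrum", "instantaneous_bispectrum",
    "integrate_bispectrum", "spectral_series",
    "LF_BAND", "HF_BAND", "BIS_SPLIT", "BIS_TOP",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
BIS_SPLIT = 0.15
BIS_TOP = 0.4


def volterra_kernel(g1: np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    """Linear Volterra kernel k1(n) = sum_i g1(i) phi_i(n)."""
    g1 = np.asarray(g1, dtype=float)
    return g1 @ basis.phi[:g1.size]


def linear_transfer(k1: np.ndarray, freqs: np.ndarray, dt: float) -> np.ndarray:
    """H(f) = 1 / (1 - sum_n k1(n) e^{-i 2 pi f (n+1) dt}).

    Lag n of the kernel acts on the sample n+1 steps back (the most recent
    available interval), so an AR(1)-equivalent kernel k1 = [c] yields the
    textbook 1 / (1 - c e^{-i 2 pi f dt}).
    """
    k1 = np.asarray(k1, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    lags = (np.arange(k1.size) + 1) * dt
    E = np.exp(-2j * np.pi * np.outer(freqs, lags))
    denom = 1.0 - E @ k1
    small = np.abs(denom) < 1e-6
    if np.any(small):
        logger.warning("near-unstable AR polynomial: |1 - K(f)| < 1e-6")
        denom = np.where(small, denom + 1e-6, denom)
    return 1.0 / denom


def instantaneous_spectrum(
    g1: np.ndarray,
    basis: LaguerreBasis,
    sigma2: float,
    dt: float,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum Q(f) = 2 sigma2 dt |H(f)|^2.

    sigma2 is the innovation variance (ms^2 for ms^2-unit band powers);
    dt the local mean heart period (s).  Integrating Q over (0, Nyquist)
    recovers the AR-process variance (Parseval).
    """
    if freqs is None:
        freqs = np.arange(0.0, 0.5 + 1e-12, 0.005)
    k1 = volterra_kernel(g1, basis)
    H = linear_transfer(k1, freqs, dt)
    Q = 2.0 * sigma2 * dt * np.abs(H) ** 2
    return freqs, Q


def band_integral(f: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of y(f) over [lo, hi], interpolating band edges."""
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError(f"band ({lo}, {hi}) outside frequency grid")
    inner = (f > lo) & (f < hi)
    fa = np.concatenate([[lo], f[inner], [hi]])
    ya = np.concatenate([[np.interp(lo, f, y)], y[inner], [np.interp(hi, f, y)]])
    return float(np.trapezoid(ya, fa))


def integrate_spectrum(
    freqs: np.ndarray,
    Q: np.ndarray,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> tuple[float, float, float]:
    """(LF, HF, LF/HF) band powers by trapezoidal integration."""
    lf = band_integral(freqs, Q, *lf_band)
    hf = band_integral(freqs, Q, *hf_band)
    ratio = lf / hf if hf > 0 else np.nan
    return lf, hf, ratio


def _laguerre_transfer(basis: LaguerreBasis, freqs: np.ndarray,
                       dt: float, order: int) -> np.ndarray:
    """Phi_i(f) for i = 0..order, shape (order+1, len(freqs))."""
    lags = (np.arange(basis.n_mem + 1) + 1) * dt
    E = np.exp(-2j * np.pi * np.outer(lags, freqs))
    return basis.phi[:order + 1] @ E


def instantaneous_bispectrum(
    g1: np.ndarray,
    g2: np.ndarray,
    basis: LaguerreBasis,
    sigma2: float,
    dt: float,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude bispectrum |Bis(f1, f2)| of the quadratic Volterra system.

    Bis = 2 sigma2^2 dt^2 H1(f1) H1(f2) conj(H1(f1+f2)) H2(f1, f2) with
    H2 the 2-D transform of the Laguerre-expanded quadratic kernel.  g2 must
    be symmetric.  The normalization constant is an implementation
    convention; magnitudes are comparable within this package only.
    """
    if freqs is None:
        freqs = np.arange(0.0, BIS_TOP + 1e-12, 0.005)
    g2 = np.atleast_2d(np.asarray(g2, dtype=float))
    if g2.size and not np.allclose(g2, g2.T, atol=1e-10):
        raise ValueError("g2 must be symmetric")
    nyq = 1.0 / (2.0 * dt)
    if freqs[-1] > nyq + 1e-9:
        raise ValueError("frequency grid exceeds local Nyquist rate")
    k1 = volterra_kernel(np.asarray(g1, dtype=float), basis)
    # H1 on the sum grid f1+f2 as well
    fsum = np.arange(0.0, 2 * freqs[-1] + 1e-12, freqs[1] - freqs[0]) \
        if freqs.size > 1 else freqs
    H1 = linear_transfer(k1, freqs, dt)
    H1s = linear_transfer(k1, fsum, dt)
    if g2.size == 0:
        return freqs, np.zeros((freqs.size, freqs.size))
    Phi = _laguerre_transfer(basis, freqs, dt, g2.shape[0] - 1)
    H2 = Phi.T @ g2 @ Phi  # symmetric in (f1, f2); Phi rows are orders
    idx = np.round((freqs[:, None] + freqs[None, :]) /
                   (fsum[1] - fsum[0])).astype(int) if fsum.size > 1 else \
        np.zeros((freqs.size, freqs.size), dtype=int)
    Bis = (2.0 * sigma2**2 * dt**2
           * H1[:, None] * H1[None, :] * np.conj(H1s[idx]) * H2)
    return freqs, np.abs(Bis)


def _rows_band_integral(f: np.ndarray, Y: np.ndarray,
                        lo: float, hi: float) -> np.ndarray:
    """Row-wise trapezoid of Y(:, f) over [lo, hi], edges interpolated."""
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError(f"band ({lo}, {hi}) outside frequency grid")

    def col_at(x):
        i = np.clip(np.searchsorted(f, x), 1, f.size - 1)
        w = (x - f[i - 1]) / (f[i] - f[i - 1])
        return Y[:, i - 1] * (1 - w) + Y[:, i] * w

    inner = (f > lo) & (f < hi)
    fa = np.concatenate([[lo], f[inner], [hi]])
    Ya = np.column_stack([col_at(lo), Y[:, inner], col_at(hi)])
    return np.trapezoid(Ya, fa, axis=1)


def _band_integral_2d(f: np.ndarray, B: np.ndarray,
                      band1: tuple[float, float],
                      band2: tuple[float, float]) -> float:
    """2-D trapezoid of B over band1 x band2 (edges interpolated)."""
    rows = _rows_band_integral(f, B, *band2)
    return band_integral(f, rows, *band1)


def integrate_bispectrum(
    freqs: np.ndarray,
    Bmag: np.ndarray,
    split: float = BIS_SPLIT,
    top: float = BIS_TOP,
) -> tuple[float, float, float]:
    """(LL, LH, HH) double band integrals of the magnitude bispectrum."""
    if freqs[-1] < top - 1e-9:
        raise ValueError("bispectrum grid does not cover the requested bands")
    ll = _band_integral_2d(freqs, Bmag, (0.0, split), (0.0, split))
    lh = _band_integral_2d(freqs, Bmag, (0.0, split), (split, top))
    hh = _band_integral_2d(freqs, Bmag, (split, top), (split, top))
    return ll, lh, hh


@dataclass
class SpectralSeries:
    times: np.ndarray
    lf: np.ndarray  # ms^2
    hf: np.ndarray  # ms^2
    lf_hf: np.ndarray
    lf_band: tuple[float, float] = LF_BAND
    hf_band: tuple[float, float] = HF_BAND


@dataclass
class BispectralSeries:
    times: np.ndarray
    ll: np.ndarray
    lh: np.ndarray
    hh: np.ndarray
    split: float = BIS_SPLIT
    top: float = BIS_TOP


def spectral_series(
    fit: PointProcessFit,
    stride: int | None = None,
    freq_step: float = 0.005,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    with_bispectrum: bool = True,
) -> tuple[SpectralSeries, BispectralSeries | None]:
    """Band-integrated spectra (and bispectra) along the fitted trajectory.

    stride selects every n-th evaluation step (default: about one per
    second, since downstream fusion runs on a 1 Hz clock).
    """
    cfg = fit.config
    if stride is None:
        stride = max(1, int(round(1.0 / cfg.step)))
    steps = np.arange(0, fit.times.size, stride)
    freqs = np.arange(0.0, 0.5 + 1e-12, freq_step)
    bfreqs = np.arange(0.0, BIS_TOP + 1e-12, freq_step)
    t_out, lfs, hfs, ratios = [], [], [], []
    lls, lhs, hhs = [], [], []
    for s in steps:
        mu, lam = fit.mu_rr[s], fit.lam[s]
        if not (np.isfinite(mu) and np.isfinite(lam) and mu > 0):
            continue
        sigma2_ms = (mu**3 / lam) * 1e6
        g1 = fit.g1(s)
        _, Q = instantaneous_spectrum(g1, fit.basis, sigma2_ms, mu, freqs)
        lf, hf, ratio = integrate_spectrum(freqs, Q, lf_band, hf_band)
        t_out.append(fit.times[s])
        lfs.append(lf)
        hfs.append(hf)
        ratios.append(ratio)
        if with_bispectrum:
            if bfreqs[-1] > 1.0 / (2.0 * mu) + 1e-9:
                # local beat rate too slow for the bispectral grid top:
                # report the step as missing rather than extrapolating
                lls.append(np.nan)
                lhs.append(np.nan)
                hhs.append(np.nan)
            else:
                g2 = fit.g2(s)
                _, B = instantaneous_bispectrum(g1, g2, fit.basis, sigma2_ms,
                                                mu, bfreqs)
                ll, lh, hh = integrate_bispectrum(bfreqs, B)
                lls.append(ll)
                lhs.append(lh)
                hhs.append(hh)
    spec = SpectralSeries(np.asarray(t_out), np.asarray(lfs), np.asarray(hfs),
                          np.asarray(ratios), lf_band, hf_band)
    bis = None
    if with_bispectrum:
        bis = BispectralSeries(np.asarray(t_out), np.asarray(lls),
                               np.asarray(lhs), np.asarray(hhs))
    return spec, bis
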