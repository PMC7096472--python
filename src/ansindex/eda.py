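"""Spectral sympathetic index from EDA plus tonic/phasic SCR decomposition.

The time-frequency plane of the Z-scored, 50 Hz EDA is computed per 1 s
step as a Welch periodogram of the trailing 60 s segment with Blackman
sub-windows; band-integrating it over 0.045-0.25 Hz yields the sympathetic
index series.  The skin-conductance decomposition is a sparse non-negative
deconvolution with a Bateman response kernel and a coarse-knot spline tonic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import fftconvolve, find_peaks, welch

from .preprocess import EdaSeries
from .synth import bateman_kernel

logger = logging.getLogger(__name__)

__all__ = ["TimeFrequencyPlane", "EdaSympSeries", "ScrDecomposition",
           "eda_time_frequency", "compute_edasymp", "decompose_scr",
           "scr_features", "EDASYMP_BAND"]

EDASYMP_BAND = (0.045, 0.25)


@dataclass
class TimeFrequencyPlane:
    times: np.ndarray  # s, 1 s step (window end-centred)
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # (n_times, n_freqs), >= 0
    window: float = 60.0
    overlap: float = 59.0


@dataclass
class EdaSympSeries:
    times: np.ndarray
    values: np.ndarray
    band: tuple[float, float] = EDASYMP_BAND


def eda_time_frequency(
    eda: EdaSeries,
    window: float = 60.0,
    step: float = 1.0,
    n_subwindows: int = 4,
    nfft: int = 8192,
) -> TimeFrequencyPlane:
    """Sliding Welch periodogram with Blackman sub-windows.

    Each ``window``-second segment (one per ``step`` seconds, i.e. 59 s
    overlap at the defaults) is analyzed with ``n_subwindows`` 50%%-
    overlapped Blackman sub-windows, zero-padded so the frequency grid is
    finer than 0.01 Hz.
    """
    fs = eda.rate
    x = eda.samples
    nwin = int(round(window * fs))
    if x.size < nwin:
        raise ValueError("recording shorter than the analysis window")
    nper = int(round(nwin / (0.5 * (n_subwindows + 1))))
    nover = nper // 2
    nstep = int(round(step * fs))
    starts = np.arange(0, x.size - nwin + 1, nstep)
    powers = []
    freqs = None
    for s in starts:
        seg = x[s:s + nwin]
        freqs, p = welch(seg, fs=fs, window="blackman", nperseg=nper,
                         noverlap=nover, nfft=max(nfft, nper), detrend=False)
        powers.append(p)
    times = (starts + nwin) / fs  # segment end times
    return TimeFrequencyPlane(times=np.asarray(times, dtype=float),
                              frequencies=freqs,
                              power=np.asarray(powers),
                              window=window, overlap=window - step)


def compute_edasymp(plane: TimeFrequencyPlane,
                    band: tuple[float, float] = EDASYMP_BAND) -> EdaSympSeries:
    """Per-step trapezoidal band integral of the time-frequency plane."""
    f = plane.frequencies
    lo, hi = band
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError("band outside the frequency grid")
    sel = (f >= lo) & (f <= hi)
    vals = np.trapezoid(plane.power[:, sel], f[sel], axis=1)
    return EdaSympSeries(times=plane.times, values=vals, band=band)


@dataclass
class ScrDecomposition:
    times: np.ndarray
    tonic: np.ndarray
    phasic: np.ndarray
    driver: np.ndarray  # >= 0
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual: float = np.nan
    lambda_sparse: float = np.nan

    @property
    def reconstruction(self) -> np.ndarray:
        return self.tonic + self.phasic


def decompose_scr(
    eda: EdaSeries,
    tau0: float = 0.7,
    tau1: float = 3.0,
    lambda_sparse: float = 2.0,
    knot_spacing: float = 30.0,
    peak_threshold: float = 0.05,
    max_iter: int = 1500,
    work_rate: float = 25.0,
) -> ScrDecomposition:
    """Sparse non-negative deconvolution of EDA into tonic + phasic parts.

    Solves  min ||y - K d - B c||^2 + lambda * sum(d)  s.t.  d >= 0,
    where K convolves with the Bateman kernel and B is a coarse cubic
    B-spline basis for the tonic level.  For a non-negative driver the L1
    penalty is linear, so the bounded problem is smooth and L-BFGS-B
    applies directly.
    """
    y = eda.samples
    fs = eda.rate
    if y.size / fs < 30.0:
        raise ValueError("need at least 30 s of EDA")
    factor = max(1, int(round(fs / work_rate)))
    if factor > 1 and abs(fs / factor - round(fs / factor)) < 1e-9:
        from scipy.signal import decimate

        y = decimate(y, factor, ftype="iir", zero_phase=True)
        fs = fs / factor
    n = y.size
    dt = 1.0 / fs
    kt = np.arange(0, 10 * tau1, dt)
    # raw kernel: a unit driver impulse produces a unit-amplitude-scale SCR
    # (same convention as the synthetic generator), so driver masses are
    # directly comparable to generated SCR amplitudes
    kern = bateman_kernel(kt, tau0, tau1)

    # coarse tonic spline basis (cubic B-splines on a uniform knot grid)
    from scipy.interpolate import BSpline

    spacing = int(round(knot_spacing * fs))
    knots_idx = np.arange(-3 * spacing, n + 4 * spacing, spacing)
    t_knots = knots_idx / fs
    n_basis = len(t_knots) - 4
    tt = np.arange(n) / fs
    B = np.column_stack([
        BSpline.basis_element(t_knots[i:i + 5], extrapolate=False)(tt)
        for i in range(n_basis)])
    B = np.nan_to_num(B)

    kern_rev = kern[::-1]

    def conv(d):
        return fftconvolve(d, kern)[:n]

    def corr(r):
        return fftconvolve(r, kern_rev)[kern.size - 1:kern.size - 1 + n]

    lam = lambda_sparse / fs  # penalty per driver sample, rate-invariant

    def objective(x):
        d, c = x[:n], x[n:]
        r = y - conv(d) - B @ c
        f = float(r @ r + lam * d.sum())
        gd = -2.0 * corr(r) + lam
        gc = -2.0 * (B.T @ r)
        return f, np.concatenate([gd, gc])

    x0 = np.zeros(n + n_basis)
    # start the spline at a smoothed version of y
    c0, *_ = np.linalg.lstsq(B, y, rcond=None)
    x0[n:] = c0
    bounds = [(0.0, None)] * n + [(None, None)] * n_basis
    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise RuntimeError(f"SCR deconvolution failed: {res.message} "
                           f"(residual {res.fun:.3g})")
    d = np.clip(res.x[:n], 0.0, None)
    c = res.x[n:]
    tonic = B @ c
    phasic = conv(d)
    resid = float(np.linalg.norm(y - tonic - phasic) /
                  max(np.linalg.norm(y), 1e-12))

    # significant driver peaks: local maxima of the windowed driver mass,
    # expressed in the driver's amplitude units (kernel has unit mass)
    smooth_w = max(1, int(round(1.0 * fs)))
    dsm = np.convolve(d, np.ones(smooth_w), mode="same")  # local driver mass
    peaks, _ = find_peaks(dsm, height=peak_threshold,
                          distance=max(1, int(round(1.0 * fs))))
    half = int(round(1.0 * fs))
    amps = np.array([d[max(0, p - half):p + half + 1].sum() for p in peaks])
    return ScrDecomposition(
        times=tt, tonic=tonic, phasic=phasic, driver=d,
        peak_times=peaks / fs, peak_amplitudes=amps,
        residual=resid, lambda_sparse=lambda_sparse)


def scr_features(
    decomp: ScrDecomposition,
    segment: tuple[float, float],
) -> dict[str, float]:
    """Standard EDA features over a segment.

    nSCR is the count of significant driver peaks per minute; SumAmpSCR the
    sum of phasic amplitudes at those peaks; PhasicMax the maximum of the
    phasic component; Tonic the mean tonic level.
    """
    lo, hi = segment
    if hi <= lo:
        raise ValueError("empty segment")
    t = decomp.times
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("segment outside decomposition support")
    in_seg = (decomp.peak_times >= lo) & (decomp.peak_times < hi)
    minutes = (hi - lo) / 60.0
    return {
        "EDA.nSCR": float(in_seg.sum() / minutes),
        "EDA.SumAmpSCR": float(decomp.peak_amplitudes[in_seg].sum()),
        "EDA.PhasicMax": float(decomp.phasic[sel].max()),
        "EDA.Tonic": float(decomp.tonic[sel].mean()),
    }
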