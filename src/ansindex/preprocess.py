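"""Raw-signal conditioning: R-peak detection, RR artifact correction, EDA prep."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, decimate, filtfilt

logger = logging.getLogger(__name__)

__all__ = ["HeartbeatSeries", "EdaSeries", "detect_r_peaks",
           "correct_rr_artifacts", "preprocess_eda"]


@dataclass
class HeartbeatSeries:
    """Ordered R-wave event times (s) and derived RR intervals."""

    event_times: np.ndarray
    flags: np.ndarray = None  # True where a beat was flagged/corrected

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.ndim != 1:
            raise ValueError("event_times must be 1-D")
        if self.event_times.size > 1 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if self.flags is None:
            self.flags = np.zeros(self.event_times.size, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.size != self.event_times.size:
                raise ValueError("flags length must equal number of beats")

    @property
    def rr(self) -> np.ndarray:
        """RR intervals (s), length = beats - 1."""
        return np.diff(self.event_times)

    def __len__(self) -> int:
        return self.event_times.size


@dataclass
class EdaSeries:
    """Z-scored EDA at a fixed sampling rate (50 Hz after preprocessing)."""

    samples: np.ndarray
    rate: float
    mean: float = 0.0  # removed mean (original units)
    sd: float = 1.0  # removed SD (original units)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def detect_r_peaks(
    ecg: np.ndarray,
    rate: float,
    refractory: float = 0.2,
    integration_window: float = 0.15,
) -> HeartbeatSeries:
    """Pan-Tompkins-style QRS detection.

    Band-pass (5-15 Hz) -> derivative -> squaring -> moving-window
    integration -> adaptive dual-threshold peak picking with a 200 ms
    refractory period; each detection is refined to the local ECG maximum.
    """
    ecg = np.asarray(ecg, dtype=float)
    if rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if ecg.size == 0:
        raise ValueError("empty ECG signal")
    if ecg.size / rate < 10:
        raise ValueError("recording must be at least 10 s long")
    if np.any(~np.isfinite(ecg)):
        raise ValueError("ECG contains NaN or infinite samples")
    if np.ptp(ecg) == 0:
        raise ValueError("flat ECG signal")

    b, a = butter(2, [5.0, 15.0], btype="band", fs=rate)
    filtered = filtfilt(b, a, ecg)
    deriv = np.gradient(filtered) * rate
    squared = deriv**2
    win = max(1, int(round(integration_window * rate)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refr = int(round(refractory * rate))
    # candidate local maxima of the integrated signal
    from scipy.signal import find_peaks

    cands, _ = find_peaks(integrated, distance=refr)
    if cands.size == 0:
        raise ValueError("no QRS candidates found")

    # adaptive dual thresholds (signal / noise running estimates); the
    # signal estimate starts near the top of the candidate distribution so
    # that filter sidelobes do not seed it
    spk = float(np.percentile(integrated[cands], 98))
    npk = float(np.percentile(integrated[cands], 50))
    peaks = []
    for c in cands:
        v = integrated[c]
        thr = npk + 0.25 * (spk - npk)
        if v > thr:
            peaks.append(c)
            spk = 0.125 * v + 0.875 * spk
        else:
            npk = 0.125 * v + 0.875 * npk
    if not peaks:
        raise ValueError("no peaks above adaptive threshold")

    # refine each detection to the raw-ECG maximum in a +/-100 ms window
    half = int(round(0.1 * rate))
    refined = []
    for c in peaks:
        lo, hi = max(0, c - half), min(ecg.size, c + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= refr:
            keep.append(r)
        elif ecg[r] > ecg[keep[-1]]:
            keep[-1] = r
    return HeartbeatSeries(np.asarray(keep, dtype=float) / rate)


def correct_rr_artifacts(
    series: HeartbeatSeries,
    threshold: float = 0.25,
    window: int = 11,
) -> HeartbeatSeries:
    """Flag RR intervals deviating > threshold from the local median and
    replace them by cubic-spline interpolation over accepted neighbours.

    Event times are rebuilt by cumulative sum from the first beat.
    """
    if len(series) < 10:
        raise ValueError("need at least 10 beats")
    rr = series.rr.copy()
    n = rr.size
    half = window // 2
    local_med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        local_med[i] = np.median(rr[lo:hi])
    bad = np.abs(rr - local_med) > threshold * local_med
    frac = bad.mean()
    if np.all(bad):
        raise ValueError("all beats flagged as artifacts")
    if frac > 0.20:
        logger.warning("artifact fraction %.1f%% exceeds 20%%", 100 * frac)
    if bad.any():
        good = ~bad
        idx = np.arange(n)
        if good.sum() >= 4:
            spline = CubicSpline(idx[good], rr[good])
            rr[bad] = spline(idx[bad])
        else:
            rr[bad] = np.interp(idx[bad], idx[good], rr[good])
        rr = np.clip(rr, 1e-3, None)
    times = np.concatenate([[series.event_times[0]],
                            series.event_times[0] + np.cumsum(rr)])
    flags = np.concatenate([[False], bad])
    return HeartbeatSeries(times, flags)


def preprocess_eda(
    eda: np.ndarray,
    rate: float,
    target_rate: float = 50.0,
    zscore: bool = True,
) -> EdaSeries:
    """Anti-alias low-pass, decimate to 50 Hz, Z-score over the recording."""
    eda = np.asarray(eda, dtype=float)
    if rate < target_rate:
        raise ValueError(f"input rate must be >= {target_rate} Hz")
    if np.any(~np.isfinite(eda)):
        raise ValueError("EDA contains NaN or infinite samples")
    if zscore and np.ptp(eda) == 0:
        raise ValueError("zero-variance EDA: Z-score undefined")
    factor = rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("input rate must be an integer multiple of the target rate")
    factor = int(round(factor))
    # demean before filtering: the FIR decimator zero-pads its edges, so a
    # constant offset would otherwise leak into edge transients
    offset = float(eda.mean())
    out = eda - offset
    # linear-phase FIR decimation (flat passband) in stages of <= 10
    while factor > 1:
        step = next((d for d in range(min(factor, 10), 1, -1) if factor % d == 0),
                    factor)
        out = decimate(out, step, ftype="fir", zero_phase=True)
        factor //= step
    mean, sd = float(out.mean()) + offset, float(out.std())
    if zscore:
        if sd == 0:
            raise ValueError("zero-variance EDA: Z-score undefined")
        out = (out - (mean - offset)) / sd
    else:
        out = out + offset
    return EdaSeries(out, target_rate, mean=mean, sd=sd)
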