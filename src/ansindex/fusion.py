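"""Sympatho-vagal index fusion and tonic/phasic decomposition.

Combines the EDA sympathetic index with the heartbeat spectral/bispectral
vagal markers into ratio indices on a common 1 Hz clock, and splits any
instantaneous index into a slow (tonic) and fast (phasic) component with a
5-level db5 wavelet decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelets import reconstruct_single

__all__ = ["AlignedSeries", "TonicPhasicPair", "align_series",
           "compute_sympathovagal", "wavelet_tonic_phasic",
           "phasic_quantifiers"]


@dataclass
class AlignedSeries:
    """Two series on an identical 1 Hz clock (NaN marks missing samples)."""

    times: np.ndarray
    a: np.ndarray
    b: np.ndarray


def align_series(
    times_a: np.ndarray,
    values_a: np.ndarray,
    times_b: np.ndarray,
    values_b: np.ndarray,
    clock_step: float = 1.0,
) -> AlignedSeries:
    """Average both series into common ``clock_step`` bins over their overlap.

    The finer series is bin-averaged; bins centred on the coarser clock.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    lo = max(times_a[0], times_b[0])
    hi = min(times_a[-1], times_b[-1])
    if hi <= lo:
        raise ValueError("series supports do not overlap")
    clock = np.arange(np.ceil(lo / clock_step) * clock_step, hi + 1e-9,
                      clock_step)

    def binned(t, v):
        out = np.full(clock.size, np.nan)
        edges = np.concatenate([clock - clock_step / 2,
                                [clock[-1] + clock_step / 2]])
        idx = np.digitize(t, edges) - 1
        ok = (idx >= 0) & (idx < clock.size) & np.isfinite(v)
        sums = np.bincount(idx[ok], weights=v[ok], minlength=clock.size)
        cnts = np.bincount(idx[ok], minlength=clock.size)
        nz = cnts > 0
        out[nz] = sums[nz] / cnts[nz]
        return out

    return AlignedSeries(clock, binned(times_a, np.asarray(values_a, float)),
                         binned(times_b, np.asarray(values_b, float)))


def compute_sympathovagal(
    edasymp: np.ndarray,
    denom: np.ndarray,
    floor_frac: float = 1e-12,
) -> np.ndarray:
    """Elementwise ratio index S = EDAsymp / denominator.

    Denominator samples below ``floor_frac`` of the series median (or
    non-finite) are masked as NaN.  Raises if everything is masked.
    """
    edasymp = np.asarray(edasymp, dtype=float)
    denom = np.asarray(denom, dtype=float)
    if edasymp.shape != denom.shape:
        raise ValueError("series must share a clock")
    med = np.nanmedian(np.abs(denom))
    floor = floor_frac * med if med > 0 else floor_frac
    ok = np.isfinite(denom) & np.isfinite(edasymp) & (denom > floor)
    out = np.full_like(edasymp, np.nan)
    out[ok] = edasymp[ok] / denom[ok]
    if not ok.any():
        raise ValueError("all samples masked: denominator vanishes everywhere")
    return out


@dataclass
class TonicPhasicPair:
    tonic: np.ndarray
    phasic: np.ndarray
    wavelet: str = "db5"
    levels: int = 5
    tonic_keep: str = "A1"
    phasic_keep: str = "D5"


def wavelet_tonic_phasic(
    series: np.ndarray,
    wavelet: str = "db5",
    levels: int = 5,
    tonic_keep: str = "A1",
    phasic_keep: str = "D5",
) -> TonicPhasicPair:
    """Tonic/phasic split of a 1 Hz index series by db5 wavelet reconstruction.

    Tonic keeps the level-1 approximation (details of level 1 zeroed);
    phasic keeps only the level-5 details.  NaN samples are filled by linear
    interpolation before the transform and restored as NaN afterwards.
    """
    x = np.asarray(series, dtype=float)
    nan = ~np.isfinite(x)
    if nan.all():
        raise ValueError("series is entirely missing")
    if nan.any():
        idx = np.arange(x.size)
        x = x.copy()
        x[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    tonic = reconstruct_single(x, tonic_keep, wavelet, levels)
    phasic = reconstruct_single(x, phasic_keep, wavelet, levels)
    tonic[nan] = np.nan
    phasic[nan] = np.nan
    return TonicPhasicPair(tonic, phasic, wavelet, levels,
                           tonic_keep, phasic_keep)


def phasic_quantifiers(
    phasic: np.ndarray,
    times: np.ndarray | None = None,
    segment: tuple[float, float] | None = None,
    rectify_auc: bool = True,
) -> tuple[float, float]:
    """(median, AUC) of a phasic series over a segment.

    AUC is the trapezoidal integral of |phasic| by default (a signed
    integral of a zero-mean oscillation would be uninformative); masked
    samples are excluded.
    """
    phasic = np.asarray(phasic, dtype=float)
    if times is None:
        times = np.arange(phasic.size, dtype=float)
    times = np.asarray(times, dtype=float)
    if segment is not None:
        sel = (times >= segment[0]) & (times < segment[1])
        phasic, times = phasic[sel], times[sel]
    ok = np.isfinite(phasic)
    phasic, times = phasic[ok], times[ok]
    if phasic.size == 0:
        raise ValueError("empty segment")
    med = float(np.median(phasic))
    y = np.abs(phasic) if rectify_auc else phasic
    auc = float(np.trapezoid(y, times)) if phasic.size > 1 else 0.0
    return med, auc
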