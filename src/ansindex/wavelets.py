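"""Orthogonal Daubechies DWT with symmetric boundary extension.

Filters are built at run time by spectral factorization of the Daubechies
half-band polynomial (accurate to ~1e-13), so any dbN up to ~db12 is
available without tabulated coefficients.  The transform keeps
floor((n + L - 1)/2) coefficients per channel, which makes reconstruction
exact for every signal length and boundary mode.
"""

from __future__ import annotations

from math import comb

import numpy as np

__all__ = ["daubechies_filter", "Wavelet", "wavedec", "waverec",
           "rec_lengths", "reconstruct_single"]


def daubechies_filter(n_moments: int) -> np.ndarray:
    """Orthonormal Daubechies scaling filter with N vanishing moments
    (length 2N, sum sqrt(2))."""
    N = int(n_moments)
    if not 1 <= N <= 12:
        raise ValueError("supported range is db1..db12")
    if N == 1:
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # B(z) = sum_k C(N-1+k,k) (-(z-1)^2 / 4z)^k, cleared of z^-k
    poly = np.zeros(2 * N - 1)
    for k in range(N):
        c = comb(N - 1 + k, k) * (-0.25) ** k
        term = c * np.polynomial.polynomial.polypow([-1.0, 1.0], 2 * k)
        poly[N - 1 - k:N - 1 - k + 2 * k + 1] += term
    roots = np.roots(poly[::-1])
    keep = roots[np.abs(roots) < 1.0]  # minimum-phase spectral factor
    if keep.size != N - 1:
        raise RuntimeError("spectral factorization failed")
    h = np.polynomial.polynomial.polyfromroots(
        np.concatenate([keep, -np.ones(N)]))
    h = np.real(h)
    return h * (np.sqrt(2.0) / h.sum())


class Wavelet:
    """Analysis/synthesis filter quadruple for an orthogonal wavelet."""

    def __init__(self, name: str = "db5"):
        if not name.startswith("db"):
            raise ValueError("only Daubechies (dbN) wavelets are supported")
        self.name = name
        h = daubechies_filter(int(name[2:]))
        L = h.size
        self.rec_lo = h
        self.dec_lo = h[::-1].copy()
        self.rec_hi = np.array([(-1.0) ** k * h[L - 1 - k] for k in range(L)])
        self.dec_hi = self.rec_hi[::-1].copy()
        self.filter_length = L


def _dwt(x: np.ndarray, w: Wavelet) -> tuple[np.ndarray, np.ndarray]:
    L = w.filter_length
    pad = L - 1
    if x.size < pad:
        raise ValueError("signal shorter than the filter support")
    xe = np.concatenate([x[:pad][::-1], x, x[-pad:][::-1]])
    out_len = (x.size + L - 1) // 2
    ca = np.convolve(xe, w.dec_lo)[L::2][:out_len]
    cd = np.convolve(xe, w.dec_hi)[L::2][:out_len]
    return ca, cd


def _idwt(ca: np.ndarray, cd: np.ndarray, w: Wavelet, n: int) -> np.ndarray:
    L = w.filter_length
    u = np.zeros(2 * ca.size)
    u[::2] = ca
    v = np.zeros(2 * cd.size)
    v[::2] = cd
    y = np.convolve(u, w.rec_lo) + np.convolve(v, w.rec_hi)
    return y[L - 2:L - 2 + n]


def wavedec(x: np.ndarray, wavelet: Wavelet | str = "db5",
            level: int = 5) -> list[np.ndarray]:
    """Multilevel DWT: returns [cA_level, cD_level, ..., cD_1]."""
    if isinstance(wavelet, str):
        wavelet = Wavelet(wavelet)
    x = np.asarray(x, dtype=float)
    min_len = 2**level * wavelet.filter_length
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} too short for {level} levels "
            f"of {wavelet.name} (need >= {min_len})")
    coeffs = []
    a = x
    for _ in range(level):
        a, d = _dwt(a, wavelet)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray], lengths: list[int],
            wavelet: Wavelet | str = "db5") -> np.ndarray:
    """Inverse of :func:`wavedec`; lengths are the per-level target sizes
    (original signal length first — obtain with :func:`rec_lengths`)."""
    if isinstance(wavelet, str):
        wavelet = Wavelet(wavelet)
    a = coeffs[0]
    level = len(coeffs) - 1
    for i in range(level):
        n = lengths[level - 1 - i]
        a = _idwt(a, coeffs[i + 1], wavelet, n)
    return a


def rec_lengths(n: int, wavelet: Wavelet | str = "db5",
                level: int = 5) -> list[int]:
    """Intermediate approximation lengths [n, len(cA1), ..., len(cA_{L-1})]."""
    if isinstance(wavelet, str):
        wavelet = Wavelet(wavelet)
    L = wavelet.filter_length
    out = [n]
    m = n
    for _ in range(level - 1):
        m = (m + L - 1) // 2
        out.append(m)
    return out


def reconstruct_single(x: np.ndarray, keep: str,
                       wavelet: Wavelet | str = "db5",
                       level: int = 5) -> np.ndarray:
    """Reconstruction from a subset of DWT coefficients.

    keep: "A<k>" zeroes the detail coefficients of levels 1..k (the level-k
    approximation signal); "D<k>" keeps only the level-k details.
    """
    if isinstance(wavelet, str):
        wavelet = Wavelet(wavelet)
    x = np.asarray(x, dtype=float)
    coeffs = wavedec(x, wavelet, level)
    kind, k = keep[0].upper(), int(keep[1:])
    if not 1 <= k <= level:
        raise ValueError(f"level {k} outside 1..{level}")
    out = []
    for i, c in enumerate(coeffs):
        lev = level - i + 1 if i > 0 else level  # detail level of coeffs[i]
        if i == 0:  # approximation at the deepest level
            keep_it = (kind == "A")
        elif kind == "A":
            keep_it = lev > k  # details coarser than level k stay
        else:
            keep_it = lev == k
        out.append(c if keep_it else np.zeros_like(c))
    return waverec(out, rec_lengths(x.size, wavelet, level), wavelet)
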