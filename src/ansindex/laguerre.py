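"""Discrete-time orthonormal Laguerre basis and filter outputs.

The basis is generated through the stable all-pass cascade

    Phi_0(z) = sqrt(1-a) / (1 - sqrt(a) z^-1)
    Phi_i(z) = Phi_{i-1}(z) * (sqrt(a) - z^-1) / (1 - sqrt(a) z^-1)

whose impulse responses coincide with the closed-form binomial expression
(evaluated directly only in tests, where it is numerically safe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = ["LaguerreBasis", "laguerre_basis", "laguerre_filter", "filter_outputs"]


@dataclass(frozen=True)
class LaguerreBasis:
    alpha: float
    order: int  # highest order i
    phi: np.ndarray  # shape (order+1, n_mem+1); phi[i, n]

    @property
    def n_mem(self) -> int:
        return self.phi.shape[1] - 1

    def gram(self) -> np.ndarray:
        return self.phi @ self.phi.T


def laguerre_basis(alpha: float, order: int, n_mem: int = 200) -> LaguerreBasis:
    """Orthonormal Laguerre functions phi_i(n), i = 0..order, n = 0..n_mem."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    if order < 0:
        raise ValueError("order must be >= 0")
    sa = np.sqrt(alpha)
    n = np.arange(n_mem + 1)
    phi = np.empty((order + 1, n_mem + 1))
    phi[0] = np.sqrt(1.0 - alpha) * sa**n
    for i in range(1, order + 1):
        phi[i] = lfilter([sa, -1.0], [1.0, -sa], phi[i - 1])
    return LaguerreBasis(alpha, order, phi)


def laguerre_filter(rr_history: np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    """Laguerre filter outputs l_i from a past-RR history (most recent last).

    l_i = sum_n phi_i(n) * e[-1-n] where e are the successive RR increments;
    the sum runs over whatever history is available.
    """
    rr_history = np.asarray(rr_history, dtype=float)
    if rr_history.size < 2:
        raise ValueError("need at least 2 past beats")
    inc = np.diff(rr_history)[::-1]  # inc[0] = most recent increment
    n_use = min(inc.size, basis.n_mem + 1)
    return basis.phi[:, :n_use] @ inc[:n_use]


def filter_outputs(rr: np.ndarray, basis: LaguerreBasis) -> np.ndarray:
    """Laguerre outputs for every target interval of an RR series.

    Returns L of shape (len(rr), order+1) where L[k] are the filter outputs
    available just before interval rr[k] (built from increments up to
    rr[k-1] - rr[k-2]).  Rows with no history are zero.
    """
    rr = np.asarray(rr, dtype=float)
    m = rr.size
    inc = np.zeros(m)
    inc[1:] = np.diff(rr)  # inc[j] = rr[j] - rr[j-1]
    L = np.zeros((m, basis.order + 1))
    for i in range(basis.order + 1):
        c = np.convolve(inc, basis.phi[i])[:m]
        # l_i(k) uses increments up to index k-1
        L[2:, i] = c[1:m - 1]
    return L
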