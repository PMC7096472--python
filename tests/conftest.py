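import numpy as np
import pytest
from scipy.stats import invgauss

from ansindex.preprocess import HeartbeatSeries
from ansindex.synth import ProtocolSpec, SegmentParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_renewal_series(mu: float = 0.8, lam: float = 50.0,
                        duration: float = 480.0, seed: int = 0) -> HeartbeatSeries:
    """Stationary IG renewal heartbeat series truncated to `duration` s."""
    rng = np.random.default_rng(seed)
    n = int(duration / mu * 1.5) + 50
    rr = invgauss.rvs(mu / lam, scale=lam, size=n, random_state=rng)
    u = np.concatenate([[0.0], np.cumsum(rr)])
    return HeartbeatSeries(u[u <= duration])


@pytest.fixture
def renewal_series():
    return make_renewal_series()


def flat_protocol(duration: float = 120.0, seed: int = 0,
                  **kw) -> ProtocolSpec:
    return ProtocolSpec((SegmentParams("rest", duration, **kw),), seed=seed)
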