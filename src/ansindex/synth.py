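"""Synthetic ECG/RR and EDA generation with known autonomic ground truth.

Stands in for unavailable human recordings: an integral pulse frequency
modulation (IPFM) model produces beat times with controllable LF/HF
modulation and per-segment mean heart period, and EDA is built as a slow
tonic level plus Bateman-shaped skin-conductance responses driven by a
Poisson impulse train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SegmentParams",
    "ProtocolSpec",
    "SyntheticRecording",
    "CohortEffect",
    "generate_rr",
    "generate_eda",
    "generate_ecg",
    "generate_cohort",
    "bateman_kernel",
    "bateman_peak_time",
    "default_protocol",
]

SEGMENT_LABELS = ("rest", "cpt", "neutral", "pleasant", "unpleasant", "recovery")

LF_FREQ = 0.1
HF_FREQ = 0.25


@dataclass(frozen=True)
class SegmentParams:
    """Autonomic parameters for one protocol segment."""

    label: str
    duration: float  # s
    mean_rr: float = 900.0  # ms
    lf_amp: float = 0.05  # fractional LF (0.1 Hz) rate modulation
    hf_amp: float = 0.08  # fractional HF (0.25 Hz) rate modulation
    scr_rate: float = 4.0  # SCR events per minute
    scr_amp: float = 0.3  # SCR amplitude scale (gamma mean, uS)
    tonic_level: float = 2.0  # tonic EDA level (uS)

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if not 300.0 <= self.mean_rr <= 2000.0:
            raise ValueError("mean RR must lie in [300, 2000] ms")
        if self.lf_amp < 0 or self.hf_amp < 0:
            raise ValueError("modulation amplitudes must be >= 0")
        if self.scr_rate < 0:
            raise ValueError("SCR rate must be >= 0")
        if self.scr_amp < 0:
            raise ValueError("SCR amplitude scale must be >= 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered protocol segments plus the master seed."""

    segments: tuple[SegmentParams, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def boundaries(self) -> np.ndarray:
        """Cumulative segment edges, length n_segments + 1, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def segment_window(self, label: str, occurrence: int = 0) -> tuple[float, float]:
        """(start, end) of the n-th segment with the given label."""
        edges = self.boundaries()
        hits = [i for i, s in enumerate(self.segments) if s.label == label]
        if occurrence >= len(hits):
            raise KeyError(f"no segment {label!r} (occurrence {occurrence})")
        i = hits[occurrence]
        return float(edges[i]), float(edges[i + 1])

    def to_json(self, path) -> None:
        """Write the protocol as a documented key-value config file."""
        import dataclasses
        import json
        from pathlib import Path

        payload = {"seed": self.seed,
                   "segments": [dataclasses.asdict(s) for s in self.segments]}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ProtocolSpec":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        segs = tuple(SegmentParams(**s) for s in payload["segments"])
        return cls(segs, seed=int(payload.get("seed", 0)))

    def param_profile(self, t: np.ndarray, attr: str) -> np.ndarray:
        """Piecewise-constant per-segment parameter evaluated at times t."""
        edges = self.boundaries()
        vals = np.array([getattr(s, attr) for s in self.segments], dtype=float)
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(vals) - 1)
        return vals[idx]


@dataclass
class SyntheticRecording:
    """One synthetic subject: raw signals plus the ground truth behind them."""

    ecg: np.ndarray
    ecg_rate: float
    eda: np.ndarray
    eda_rate: float
    true_beat_times: np.ndarray
    true_scr_times: np.ndarray
    protocol: ProtocolSpec
    eda_tonic: np.ndarray = field(default=None, repr=False)
    eda_phasic: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        bt = np.asarray(self.true_beat_times, dtype=float)
        if bt.size > 1 and np.any(np.diff(bt) <= 0):
            raise ValueError("true_beat_times must be strictly increasing")


def generate_rr(
    protocol: ProtocolSpec,
    grid_dt: float = 0.005,
    noise_amp: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Beat event times (s) from an IPFM model.

    The instantaneous rate is m(t) = (1/mu_RR(t)) * [1 + a_LF sin(2*pi*0.1*t)
    + a_HF sin(2*pi*0.25*t) + noise]; a beat fires each time the running
    integral of m crosses the next integer.  Crossings are located by linear
    interpolation on a ``grid_dt`` grid, so with zero modulation the beat
    spacing is exact to machine precision.  ``noise_amp`` adds band-limited
    (< 0.4 Hz) Gaussian modulation of that RMS amplitude for stochastic
    beat-to-beat variability.
    """
    T = protocol.duration
    t = np.arange(0.0, T + grid_dt, grid_dt)
    mu = protocol.param_profile(t, "mean_rr") / 1000.0  # s
    if np.any(mu <= 0):
        raise ValueError("mean RR must be positive")
    a_lf = protocol.param_profile(t, "lf_amp")
    a_hf = protocol.param_profile(t, "hf_amp")
    mod = (1.0 + a_lf * np.sin(2 * np.pi * LF_FREQ * t)
           + a_hf * np.sin(2 * np.pi * HF_FREQ * t))
    if noise_amp > 0:
        if rng is None:
            rng = np.random.default_rng(protocol.seed)
        from scipy.signal import butter, filtfilt

        white = rng.standard_normal(t.size)
        b, a = butter(2, 0.4, fs=1.0 / grid_dt)
        low = filtfilt(b, a, white)
        sd = low.std()
        if sd > 0:
            mod = mod + noise_amp * low / sd
    m = np.clip(mod, 0.05, None) / mu
    # cumulative integral of m via the trapezoid rule
    integral = np.concatenate([[0.0], np.cumsum(0.5 * (m[1:] + m[:-1]) * grid_dt)])
    n_beats = int(math.floor(integral[-1]))
    thresholds = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integral, thresholds)
    # linear interpolation of the crossing inside [idx-1, idx]
    i0 = idx - 1
    frac = (thresholds - integral[i0]) / (integral[idx] - integral[i0])
    beats = t[i0] + frac * grid_dt
    return beats[beats <= T + 1e-9]


def bateman_kernel(t: np.ndarray, tau0: float = 0.7, tau1: float = 3.0) -> np.ndarray:
    """Double-exponential SCR shape (exp(-t/tau1) - exp(-t/tau0))/(tau1-tau0)."""
    t = np.asarray(t, dtype=float)
    h = (np.exp(-t / tau1) - np.exp(-t / tau0)) / (tau1 - tau0)
    h[t < 0] = 0.0
    return h


def bateman_peak_time(tau0: float = 0.7, tau1: float = 3.0) -> float:
    """Closed-form peak latency of the Bateman kernel."""
    return tau0 * tau1 * math.log(tau1 / tau0) / (tau1 - tau0)


def generate_eda(
    protocol: ProtocolSpec,
    rate: float = 500.0,
    tau0: float = 0.7,
    tau1: float = 3.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    driver_times: np.ndarray | None = None,
    driver_amps: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sampled EDA = tonic baseline + Bateman-convolved driver impulses.

    Returns ``(eda, scr_times, tonic, phasic)``.  SCR times are Poisson with
    the per-segment rate, amplitudes gamma with the per-segment scale; both
    can be overridden explicitly for oracle tests.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    T = protocol.duration
    n = int(round(T * rate))
    t = np.arange(n) / rate

    # tonic: smooth spline through per-segment levels at segment midpoints
    edges = protocol.boundaries()
    mids = 0.5 * (edges[:-1] + edges[1:])
    levels = np.array([s.tonic_level for s in protocol.segments], dtype=float)
    if len(mids) == 1:
        tonic = np.full(n, levels[0])
    else:
        from scipy.interpolate import CubicSpline

        xs = np.concatenate([[0.0], mids, [T]])
        ys = np.concatenate([[levels[0]], levels, [levels[-1]]])
        tonic = CubicSpline(xs, ys, bc_type="clamped")(t)

    if driver_times is None:
        # Poisson SCR events segment by segment
        times, amps = [], []
        for seg, lo, hi in zip(protocol.segments, edges[:-1], edges[1:]):
            lam = seg.scr_rate / 60.0  # events per second
            n_ev = rng.poisson(lam * (hi - lo))
            ev = np.sort(rng.uniform(lo, hi, size=n_ev))
            times.append(ev)
            if seg.scr_amp > 0:
                amps.append(rng.gamma(2.0, seg.scr_amp / 2.0, size=n_ev))
            else:
                amps.append(np.zeros(n_ev))
        scr_times = np.concatenate(times) if times else np.empty(0)
        scr_amps = np.concatenate(amps) if amps else np.empty(0)
    else:
        scr_times = np.asarray(driver_times, dtype=float)
        scr_amps = (np.ones_like(scr_times) if driver_amps is None
                    else np.asarray(driver_amps, dtype=float))
        if np.any(scr_amps < 0):
            raise ValueError("driver amplitudes must be >= 0")

    driver = np.zeros(n)
    idx = np.round(scr_times * rate).astype(int)
    keep = (idx >= 0) & (idx < n)
    np.add.at(driver, idx[keep], scr_amps[keep])

    # convolve with the Bateman kernel (support ~ 8*tau1)
    kt = np.arange(0, 8 * tau1, 1 / rate)
    from scipy.signal import fftconvolve

    phasic = fftconvolve(driver, bateman_kernel(kt, tau0, tau1), mode="full")[:n]
    eda = tonic + phasic
    if noise_sd > 0:
        eda = eda + rng.normal(0.0, noise_sd, size=n)
    return eda, scr_times[keep], tonic, phasic


# QRS-like template: narrow positive spike with small side lobes, peak at 0.
_QRS_WIDTH = 0.012  # s (Gaussian sigma of the R wave)


def _qrs_template(t: np.ndarray) -> np.ndarray:
    r = np.exp(-0.5 * (t / _QRS_WIDTH) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.030) / 0.010) ** 2)
    s = -0.20 * np.exp(-0.5 * ((t - 0.030) / 0.010) ** 2)
    return r + q + s


def generate_ecg(
    beat_times: np.ndarray,
    rate: float = 500.0,
    duration: float | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Place a QRS-like template at each beat time, plus white noise.

    The template peak lands within half a sample of each beat time.
    """
    if rate < 100:
        raise ValueError("sampling rate below 100 Hz cannot resolve the QRS template")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size > 1 and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if duration is None:
        duration = float(beat_times[-1]) + 1.0 if beat_times.size else 1.0
    n = int(round(duration * rate))
    ecg = np.zeros(n)
    half = int(round(0.08 * rate))
    tt = np.arange(-half, half + 1) / rate
    for bt in beat_times:
        c = int(round(bt * rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        ecg[lo:hi] += _qrs_template(tt[(lo - (c - half)):(hi - (c - half))] + (c / rate - bt))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        ecg = ecg + rng.normal(0.0, noise_sd, size=n)
    return ecg


@dataclass(frozen=True)
class CohortEffect:
    """Per-segment deltas applied to CPT segments of a cohort protocol."""

    mu_rr_drop: float = 0.0  # ms subtracted from mean RR during CPT
    hf_amp_factor: float = 1.0  # multiplies HF modulation during CPT
    scr_rate_factor: float = 1.0  # multiplies SCR rate during CPT
    scr_amp_factor: float = 1.0  # multiplies SCR amplitude during CPT
    tonic_delta: float = 0.0  # added to tonic level during CPT

    @classmethod
    def null(cls) -> "CohortEffect":
        return cls()


def _jitter(rng: np.random.Generator, value: float, cv: float) -> float:
    """Log-normal jitter with coefficient of variation cv around value."""
    if value == 0 or cv == 0:
        return value
    sigma = math.sqrt(math.log(1 + cv**2))
    return value * rng.lognormal(-0.5 * sigma**2, sigma)


def default_protocol(seed: int = 0, rest: float = 240.0, cpt: float = 180.0,
                     include_emotion: bool = True) -> ProtocolSpec:
    """Protocol mirroring the experiment timeline at configurable durations."""
    segs = [
        SegmentParams("rest", rest),
        SegmentParams("cpt", cpt),
        SegmentParams("rest", rest * 0.75),
    ]
    if include_emotion:
        segs += [
            SegmentParams("neutral", 90.0),
            SegmentParams("pleasant", 90.0, scr_rate=6.0, scr_amp=0.4),
            SegmentParams("unpleasant", 90.0, scr_rate=8.0, scr_amp=0.5,
                          mean_rr=860.0, hf_amp=0.06),
        ]
    segs.append(SegmentParams("recovery", rest))
    return ProtocolSpec(tuple(segs), seed=seed)


def generate_cohort(
    n_subjects: int,
    effect: CohortEffect | None = None,
    seed: int = 0,
    base_protocol: ProtocolSpec | None = None,
    jitter_cv: float = 0.08,
    ecg_rate: float = 500.0,
    eda_rate: float = 500.0,
    ecg_noise_sd: float = 0.02,
    eda_noise_sd: float = 0.005,
    rr_noise_amp: float = 0.03,
    render_ecg: bool = True,
) -> list[SyntheticRecording]:
    """Cohort of synthetic recordings with per-subject parameter jitter.

    CPT segments receive the configured sympathetic effect.  Each subject
    draws from an independent substream spawned from the master seed by
    subject index, so the cohort is reproducible regardless of order.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effect = effect or CohortEffect.null()
    if base_protocol is None:
        base_protocol = default_protocol(seed)
    recordings = []
    root = np.random.SeedSequence(seed)
    for k in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=root.entropy,
                                                           spawn_key=(k,)))
        segs = []
        for s in base_protocol.segments:
            mean_rr = float(np.clip(_jitter(rng, s.mean_rr, jitter_cv), 300.0, 2000.0))
            lf = _jitter(rng, s.lf_amp, jitter_cv)
            hf = _jitter(rng, s.hf_amp, jitter_cv)
            rate_ = _jitter(rng, s.scr_rate, jitter_cv)
            amp = _jitter(rng, s.scr_amp, jitter_cv)
            ton = s.tonic_level * (1 + rng.normal(0, jitter_cv))
            if s.label == "cpt":
                mean_rr = float(np.clip(mean_rr - effect.mu_rr_drop, 300.0, 2000.0))
                hf *= effect.hf_amp_factor
                rate_ *= effect.scr_rate_factor
                amp *= effect.scr_amp_factor
                ton += effect.tonic_delta
            segs.append(replace(s, mean_rr=mean_rr, lf_amp=lf, hf_amp=hf,
                                scr_rate=rate_, scr_amp=amp, tonic_level=ton))
        proto = ProtocolSpec(tuple(segs), seed=seed)
        beats = generate_rr(proto, noise_amp=rr_noise_amp, rng=rng)
        eda, scr_times, tonic, phasic = generate_eda(
            proto, rate=eda_rate, noise_sd=eda_noise_sd, rng=rng)
        if render_ecg:
            ecg = generate_ecg(beats, rate=ecg_rate, duration=proto.duration,
                               noise_sd=ecg_noise_sd, rng=rng)
        else:
            ecg = np.empty(0)
        recordings.append(SyntheticRecording(
            ecg=ecg, ecg_rate=ecg_rate, eda=eda, eda_rate=eda_rate,
            true_beat_times=beats, true_scr_times=scr_times, protocol=proto,
            eda_tonic=tonic, eda_phasic=phasic))
    return recordings
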