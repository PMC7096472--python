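"""Plain-text I/O helpers: (time, value) signal CSVs and annotation files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_signal", "read_signal", "write_events", "read_events",
           "write_rr"]


def write_signal(path: str | Path, samples: np.ndarray, rate: float) -> None:
    """Two-column CSV (time_s, value) with the rate recoverable from times."""
    t = np.arange(len(samples)) / rate
    pd.DataFrame({"time_s": t, "value": samples}).to_csv(path, index=False)


def read_signal(path: str | Path) -> tuple[np.ndarray, float]:
    """Returns (samples, rate); rate inferred from the time column."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("signal file needs at least 2 samples")
    dt = np.median(np.diff(t))
    return v, float(1.0 / dt)


def write_events(path: str | Path, times: np.ndarray) -> None:
    """One event time (s) per line."""
    Path(path).write_text("\n".join(f"{t:.6f}" for t in times) + "\n")


def read_events(path: str | Path) -> np.ndarray:
    txt = Path(path).read_text().split()
    return np.asarray([float(x) for x in txt])


def write_rr(path: str | Path, event_times: np.ndarray) -> None:
    """Two-column text (beat time s, RR s) for corrected heartbeat series."""
    rr = np.diff(event_times)
    pd.DataFrame({"time_s": event_times[1:], "rr_s": rr}).to_csv(
        path, index=False)
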