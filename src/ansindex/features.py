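"""Feature assembly and rest-vs-stressor statistical comparison.

Implements the time-domain heartbeat descriptors, per-window averaging, the
neutral-session normalization, an exact paired Wilcoxon signed-rank test,
a Lilliefors-type normality screen, and robust median +/- scaled-MAD
summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = ["rmssd", "pnn50", "window_average", "beats_in_window",
           "normalize_by_neutral", "paired_wilcoxon", "normality_check",
           "robust_summary", "compare_conditions", "WilcoxonResult",
           "FEATURE_GROUPS"]

# Table-style grouping of the full feature dictionary
FEATURE_GROUPS = {
    "F1": ["mu_RR", "sigma2_RR", "RMSSD", "pNN50", "LF_pp", "HF_pp", "LF_HF"],
    "F2": ["LL_pp", "LH_pp", "HH_pp"],
    "F3": ["EDAsymp", "S_HF"],
    "F4": ["EDA.nSCR", "EDA.SumAmpSCR", "EDA.PhasicMax", "EDA.Tonic"],
    "F5": ["S_LL", "S_LH", "S_HH"],
    "F6_1": ["LL_ph_med", "LH_ph_med", "HH_ph_med",
             "S_LL_ph_med", "S_LH_ph_med", "S_HH_ph_med"],
    "F6_2": ["LL_ph_auc", "LH_ph_auc", "HH_ph_auc",
             "S_LL_ph_auc", "S_LH_ph_auc", "S_HH_ph_auc"],
}


def rmssd(rr: np.ndarray) -> float:
    """Root mean square of successive RR differences (input units)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 intervals")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def pnn50(rr: np.ndarray, threshold_ms: float = 50.0) -> float:
    """Percentage of successive RR differences exceeding 50 ms (RR in s)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 intervals")
    d = np.abs(np.diff(rr)) * 1000.0
    return float(100.0 * np.mean(d > threshold_ms))


def beats_in_window(event_times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """RR intervals whose ending beat lies inside [lo, hi)."""
    u = np.asarray(event_times, dtype=float)
    rr = np.diff(u)
    tend = u[1:]
    return rr[(tend >= lo) & (tend < hi)]


def window_average(times: np.ndarray, values: np.ndarray,
                   windows: list[tuple[float, float]]) -> np.ndarray:
    """Mean of an instantaneous series within each (lo, hi) window.

    Empty windows yield NaN (logged)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.full(len(windows), np.nan)
    for i, (lo, hi) in enumerate(windows):
        sel = (times >= lo) & (times < hi) & np.isfinite(values)
        if sel.any():
            out[i] = values[sel].mean()
        else:
            logger.warning("window (%.1f, %.1f) empty", lo, hi)
    return out


def normalize_by_neutral(table: pd.DataFrame, label_col: str = "session",
                         subject_col: str = "subject",
                         neutral_label: str = "neutral") -> pd.DataFrame:
    """Divide each subject's feature rows by that subject's neutral row.

    Zero neutral entries mask the column for that subject (NaN, logged).
    The neutral rows themselves are dropped from the output.
    """
    feature_cols = [c for c in table.columns
                    if c not in (label_col, subject_col)
                    and np.issubdtype(table[c].dtype, np.number)]
    out_rows = []
    for subj, grp in table.groupby(subject_col, sort=False):
        neutral = grp[grp[label_col] == neutral_label]
        if neutral.empty:
            raise ValueError(f"subject {subj!r} has no neutral session")
        base = neutral.iloc[0][feature_cols].astype(float)
        for _, row in grp[grp[label_col] != neutral_label].iterrows():
            r = row.copy()
            for c in feature_cols:
                if base[c] == 0 or not np.isfinite(base[c]):
                    logger.warning("neutral %s = %s for subject %s: masked",
                                   c, base[c], subj)
                    r[c] = np.nan
                else:
                    r[c] = row[c] / base[c]
            out_rows.append(r)
    return pd.DataFrame(out_rows).reset_index(drop=True)


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    p_value: float
    n_used: int  # pairs after zero-difference removal
    exact: bool
    note: str = ""


def paired_wilcoxon(x: np.ndarray, y: np.ndarray,
                    exact_max_n: int = 12) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's rule); ties get average ranks.
    For n <= ``exact_max_n`` the null distribution is enumerated over all
    2^n sign assignments of the observed ranks; otherwise the normal
    approximation with continuity and tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, True, "all differences zero")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = ranks.sum()
    if n <= exact_max_n:
        # enumerate all sign patterns of the observed (possibly tied) ranks
        sums = np.zeros(2**n)
        for bits in range(2**n):
            s = 0.0
            b = bits
            i = 0
            while b:
                if b & 1:
                    s += ranks[i]
                b >>= 1
                i += 1
            sums[bits] = s
        lower = np.mean(sums <= w_pos + 1e-9)
        upper = np.mean(sums >= w_pos - 1e-9)
        p = min(1.0, 2.0 * min(lower, upper))
        return WilcoxonResult(w_pos, float(p), n, True)
    mean = total / 2.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_pos, p, n, False)


# Lilliefors 5% critical values (Abdi & Molin approximation for finite n)
def _lilliefors_crit(n: int) -> float:
    return 0.895 / (np.sqrt(n) * (1.0 - 0.01 / np.sqrt(n) + 0.85 / n))


def normality_check(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True if the sample is compatible with normality (Lilliefors KS).

    The KS distance is computed against the normal with fitted moments and
    compared to the Lilliefors-corrected 5% critical value.  Constant
    samples are rejected outright.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    s = x.std(ddof=1)
    if s == 0:
        logger.info("constant sample: normality rejected by convention")
        return False
    z = np.sort((x - x.mean()) / s)
    cdf = norm.cdf(z)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    d = max(np.max(emp_hi - cdf), np.max(cdf - emp_lo))
    if alpha != 0.05:
        raise NotImplementedError("critical values tabulated for alpha=0.05")
    return bool(d < _lilliefors_crit(n))


def robust_summary(x: np.ndarray) -> tuple[float, float]:
    """(median, 1.4826 * MAD / sqrt(n)) robust location/dispersion summary."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, 1.4826 * mad / np.sqrt(x.size)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compare_conditions(
    table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    label_col: str = "window",
    subject_col: str = "subject",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-feature paired comparison between two condition labels.

    Returns one row per feature with robust summaries for both conditions,
    the Wilcoxon p-value and the normality screen for the differences.
    Raw p-values are reported by default; ``adjust="bh"`` appends a
    Benjamini-Hochberg adjusted column.
    """
    feature_cols = [c for c in table.columns
                    if c not in (label_col, subject_col)
                    and np.issubdtype(table[c].dtype, np.number)]
    a = table[table[label_col] == cond_a].set_index(subject_col)
    b = table[table[label_col] == cond_b].set_index(subject_col)
    common = a.index.intersection(b.index)
    rows = []
    for c in feature_cols:
        xa = a.loc[common, c].to_numpy(dtype=float)
        xb = b.loc[common, c].to_numpy(dtype=float)
        ok = np.isfinite(xa) & np.isfinite(xb)
        xa, xb = xa[ok], xb[ok]
        if xa.size < 5:
            continue
        med_a, disp_a = robust_summary(xa)
        med_b, disp_b = robust_summary(xb)
        res = paired_wilcoxon(xa, xb)
        rows.append({
            "feature": c, "n": xa.size,
            f"median_{cond_a}": med_a, f"disp_{cond_a}": disp_a,
            f"median_{cond_b}": med_b, f"disp_{cond_b}": disp_b,
            "p_value": res.p_value, "exact": res.exact,
            "normal_diffs": normality_check(xa - xb) if xa.size >= 5 else None,
        })
    out = pd.DataFrame(rows)
    if adjust == "bh" and not out.empty:
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
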