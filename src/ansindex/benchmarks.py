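"""Property-based validation benchmarks run by the acceptance suite.

Each function recomputes one validation quantity from scratch by exercising
the package on synthetic data with known ground truth; the acceptance tests
assert the documented tolerances on the returned values and
``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import hashlib
import itertools
import json

import numpy as np
from scipy.stats import invgauss, rankdata, spearmanr

from .eda import compute_edasymp, eda_time_frequency
from .features import beats_in_window, paired_wilcoxon, rmssd
from .fusion import wavelet_tonic_phasic
from .laguerre import laguerre_basis
from .pipeline import PipelineConfig, extract_features, process_recording
from .pointprocess import PointProcessConfig, fit_point_process, \
    ks_goodness_of_fit
from .preprocess import EdaSeries, HeartbeatSeries, preprocess_eda
from .spectral import (_laguerre_transfer, instantaneous_bispectrum,
                       instantaneous_spectrum)
from .synth import (CohortEffect, ProtocolSpec, SegmentParams, generate_cohort,
                    generate_eda, generate_rr)
from .wavelets import rec_lengths, wavedec, waverec

__all__ = [
    "laguerre_orthonormality", "renewal_recovery", "ar1_spectrum_check",
    "bispectrum_null", "bispectrum_coupling", "edasymp_selectivity",
    "edasymp_monotonicity", "wavelet_checks", "index_identity",
    "wilcoxon_exactness", "null_calibration", "effect_direction",
    "rfe_benchmark", "rfe_permutation_null", "pipeline_determinism",
]


def laguerre_orthonormality(alphas=(0.1, 0.2, 0.5), order=9,
                            n_mem=500) -> float:
    """Worst Gram-matrix deviation from identity across alphas."""
    worst = 0.0
    for a in alphas:
        b = laguerre_basis(a, order, n_mem)
        worst = max(worst, float(np.abs(b.gram() - np.eye(order + 1)).max()))
    return worst


def _renewal_series(mu, lam, duration, seed):
    rng = np.random.default_rng(seed)
    n = int(duration / mu * 1.5) + 50
    rr = invgauss.rvs(mu / lam, scale=lam, size=n, random_state=rng)
    u = np.concatenate([[0.0], np.cumsum(rr)])
    return HeartbeatSeries(u[u <= duration])


def renewal_recovery(n_seeds=100, mu=0.8, lam=50.0, duration=480.0,
                     step=1.0, seed0=0) -> dict:
    """Mean-recovery error and KS pass rate on stationary IG renewal data."""
    errs, ks_pass = [], []
    cfg = PointProcessConfig(step=step)
    for s in range(seed0, seed0 + n_seeds):
        series = _renewal_series(mu, lam, duration, s)
        fit = fit_point_process(series, cfg)
        errs.append(abs(float(np.nanmean(fit.mu_rr)) - mu) / mu)
        ks_pass.append(ks_goodness_of_fit(fit).passed)
    return {"median_rel_err": float(np.median(errs)),
            "ks_pass_rate": float(np.mean(ks_pass))}


def ar1_spectrum_check(c=0.5, sigma2=2.0, dt=1.0) -> dict:
    """Closed-form AR(1) spectrum match (L2) and Parseval error."""
    basis = laguerre_basis(0.2, 8, 300)
    g1 = basis.phi[:, 0] * c
    freqs = np.arange(0.0, 0.5 + 1e-12, 0.001)
    _, Q = instantaneous_spectrum(g1, basis, sigma2, dt, freqs)
    closed = 2 * sigma2 * dt / np.abs(
        1 - c * np.exp(-2j * np.pi * freqs * dt))**2
    l2 = float(np.linalg.norm(Q - closed) / np.linalg.norm(closed))
    total = float(np.trapezoid(Q, freqs))
    expected = sigma2 / (1 - c**2)
    return {"l2_rel_err": l2,
            "parseval_rel_err": abs(total - expected) / expected}


def bispectrum_null() -> float:
    """Maximum |Bis| with a vanishing quadratic kernel."""
    basis = laguerre_basis(0.2, 8, 300)
    g1 = basis.phi[:, 0] * 0.4
    _, B = instantaneous_bispectrum(g1, np.zeros((3, 3)), basis, 1.0, 1.0)
    return float(B.max())


def bispectrum_coupling(n_seeds=20, f1=0.1, f2=0.25) -> float:
    """Fraction of seeds whose injected coupling is located within one
    grid step (searching the f1 <= f2 half-plane)."""
    basis = laguerre_basis(0.2, 25, 300)
    freqs = np.arange(0.0, 0.4 + 1e-12, 0.005)
    Phi = _laguerre_transfer(basis, np.array([f1, f2]), 1.0, 25)
    a1, a2 = np.conj(Phi[:, 0]), np.conj(Phi[:, 1])
    G0 = np.real(np.outer(a1, a2) + np.outer(a2, a1))
    G0 = (G0 + G0.T) / 2
    hits = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(G0.shape) * 0.02 * np.abs(G0).max()
        G = G0 + (noise + noise.T) / 2
        _, B = instantaneous_bispectrum(np.zeros(1), G, basis, 1.0, 1.0,
                                        freqs)
        half = np.zeros_like(B)
        iu = np.triu_indices(freqs.size)
        half[iu] = B[iu]
        i, j = np.unravel_index(np.argmax(half), B.shape)
        if abs(freqs[i] - f1) <= 0.005 + 1e-9 and \
                abs(freqs[j] - f2) <= 0.005 + 1e-9:
            hits += 1
    return hits / n_seeds


def _sine_eda(freq, duration=180.0, fs=50.0, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return EdaSeries(amp * np.sin(2 * np.pi * freq * t), fs)


def edasymp_selectivity() -> dict:
    """Band capture of in-band (0.1 Hz) and out-of-band (0.5 Hz) tones."""
    out = {}
    tf = eda_time_frequency(_sine_eda(0.1))
    symp = compute_edasymp(tf)
    sel = tf.frequencies <= 0.5
    total = np.trapezoid(tf.power[:, sel], tf.frequencies[sel], axis=1)
    out["in_band_frac"] = float(np.min(symp.values / total))
    tf = eda_time_frequency(_sine_eda(0.5))
    symp = compute_edasymp(tf)
    total = np.trapezoid(tf.power, tf.frequencies, axis=1)
    out["out_band_frac"] = float(np.max(symp.values / total))
    return out


def edasymp_monotonicity(n_levels=10, seed=0) -> float:
    """Spearman rho of mean EDAsymp vs in-band modulation amplitude."""
    rng = np.random.default_rng(seed)
    t = np.arange(0, 180, 1 / 50.0)
    base_noise = 0.05 * rng.standard_normal(t.size)
    amps = np.linspace(0.1, 2.0, n_levels)
    means = []
    for a in amps:
        x = a * np.sin(2 * np.pi * 0.1 * t) + base_noise + 2.0
        eda = preprocess_eda(x, 50.0)
        means.append(float(compute_edasymp(eda_time_frequency(eda))
                           .values.mean()))
    rho, _ = spearmanr(amps, means)
    return float(rho)


def wavelet_checks(seed=0) -> dict:
    """Constant-input leakage and full perfect-reconstruction error."""
    const = np.full(600, 3.2)
    pair = wavelet_tonic_phasic(const)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(700)
    coeffs = wavedec(x, "db5", 5)
    xr = waverec(coeffs, rec_lengths(x.size, "db5", 5), "db5")
    return {"const_phasic_max": float(np.abs(pair.phasic).max()),
            "reconstruction_err": float(np.abs(xr - x).max())}


def index_identity(n_subjects=3, seed=0) -> float:
    """Worst relative violation of S_X * X = EDAsymp over a small cohort."""
    proto = ProtocolSpec((
        SegmentParams("rest", 150.0),
        SegmentParams("cpt", 90.0),
        SegmentParams("recovery", 60.0)), seed=seed)
    cohort = generate_cohort(n_subjects, CohortEffect(mu_rr_drop=60.0),
                             seed=seed, base_protocol=proto, render_ecg=False)
    cfg = PipelineConfig(pp_step=1.0, use_true_beats=True, with_scr=False)
    worst = 0.0
    for rec in cohort:
        ss = process_recording(rec, cfg)
        for s, d in ((ss.s_hf, ss.hf), (ss.s_ll, ss.ll), (ss.s_lh, ss.lh),
                     (ss.s_hh, ss.hh)):
            ok = np.isfinite(s) & (ss.edasymp != 0)
            rel = np.abs(s[ok] * d[ok] - ss.edasymp[ok]) / \
                np.abs(ss.edasymp[ok])
            if rel.size:
                worst = max(worst, float(rel.max()))
    return worst


def _wilcoxon_bruteforce(x, y):
    d = x - y
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = np.asarray([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=d.size)])
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_exactness(n_samples=200, seed=0) -> float:
    """Worst |p - enumeration oracle| over random paired samples, n <= 10."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        n = int(rng.integers(5, 11))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n) + rng.choice([0.0, 0.5])
        p = paired_wilcoxon(x, y).p_value
        worst = max(worst, abs(p - _wilcoxon_bruteforce(x, y)))
    return worst


def _quick_subject_features(rng, cohort_seed):
    """Generator-direct rest/CPT features for one subject (no model fits)."""
    proto = ProtocolSpec((SegmentParams("rest", 60.0),
                          SegmentParams("cpt", 60.0)), seed=cohort_seed)
    beats = generate_rr(proto, noise_amp=0.04, rng=rng)
    eda, scrs, tonic, phasic = generate_eda(proto, rate=50.0, rng=rng)

    def seg(lo, hi):
        rr = beats_in_window(beats, lo, hi)
        sel = (scrs >= lo) & (scrs < hi)
        sl = slice(int(lo * 50), int(hi * 50))
        return {"mu_RR": 1000.0 * rr.mean(), "RMSSD": rmssd(rr),
                "SumAmp": float(phasic[sl].sum() / 50.0),
                "PhasicMax": float(phasic[sl].max()),
                "Tonic": float(tonic[sl].mean())}

    return seg(0.0, 60.0), seg(60.0, 120.0)


def null_calibration(n_cohorts=200, n_subjects=12, seed=0) -> float:
    """Wilcoxon rejection rate at nominal 5% on exchangeable rest/CPT data."""
    rejected = total = 0
    for c in range(n_cohorts):
        root = np.random.SeedSequence(entropy=seed, spawn_key=(c,))
        rest, cpt = [], []
        for k in range(n_subjects):
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(c, k)))
            r, s = _quick_subject_features(rng, c)
            rest.append(r)
            cpt.append(s)
        for key in rest[0]:
            x = np.array([f[key] for f in rest])
            y = np.array([f[key] for f in cpt])
            rejected += paired_wilcoxon(x, y).p_value < 0.05
            total += 1
    return rejected / total


def effect_direction(n_cohorts=10, n_subjects=6, seed=0) -> float:
    """Fraction of effect cohorts reproducing the expected signs
    (mu_RR down; S_LL, S_LH, S_HH up) through the full processing chain."""
    proto_segs = (SegmentParams("rest", 150.0), SegmentParams("cpt", 120.0),
                  SegmentParams("recovery", 60.0))
    eff = CohortEffect(mu_rr_drop=80.0, hf_amp_factor=0.6,
                       scr_rate_factor=2.5, scr_amp_factor=1.8,
                       tonic_delta=0.8)
    cfg = PipelineConfig(pp_step=1.0, use_true_beats=True, with_scr=False)
    good = 0
    for c in range(n_cohorts):
        proto = ProtocolSpec(proto_segs, seed=seed + c)
        cohort = generate_cohort(n_subjects, eff, seed=seed + c,
                                 base_protocol=proto, render_ecg=False)
        diffs = {k: [] for k in ("mu_RR", "S_LL", "S_LH", "S_HH")}
        for rec in cohort:
            ss = process_recording(rec, cfg)
            rest = extract_features(ss, (120.0, 150.0))
            cpt = extract_features(ss, (150.0, 240.0))
            for k in diffs:
                diffs[k].append(cpt[k] - rest[k])
        med = {k: np.nanmedian(v) for k, v in diffs.items()}
        if med["mu_RR"] < 0 and med["S_LL"] > 0 and med["S_LH"] > 0 \
                and med["S_HH"] > 0:
            good += 1
    return good / n_cohorts


def _rfe_cohort(rng, n_subjects=26, n_features=18, n_informative=2, sep=1.5):
    X, y, subj = [], [], []
    for s in range(n_subjects):
        for label in (1, -1):
            x = rng.standard_normal(n_features)
            x[:n_informative] += sep * label
            X.append(x)
            y.append(label)
            subj.append(s)
    return np.asarray(X), np.asarray(y), np.asarray(subj)


def rfe_benchmark(n_seeds=50, top=4) -> float:
    """Fraction of seeds where both informative features land in the top
    aggregate positions after LOSO SVM-RFE."""
    from .classify import loso_evaluate

    hits = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        X, y, subj = _rfe_cohort(rng)
        _, rfe = loso_evaluate(X, y, subj)
        if set(rfe.aggregate_ranking[:top]) >= {0, 1}:
            hits += 1
    return hits / n_seeds


def rfe_permutation_null(n_perms=20, seed=0) -> dict:
    """Balanced accuracy distribution under label permutation."""
    from .classify import loso_evaluate

    rng = np.random.default_rng(seed)
    X, y, subj = _rfe_cohort(rng, n_subjects=12, n_features=8)
    accs = []
    for _ in range(n_perms):
        yp = rng.permutation(y)
        if np.unique(yp).size < 2:
            continue
        try:
            report, _ = loso_evaluate(X, yp, subj)
        except ValueError:
            continue
        accs.append(report.balanced_accuracy)
    return {"mean": float(np.mean(accs)), "min": float(np.min(accs)),
            "max": float(np.max(accs))}


def pipeline_determinism(seed=0, tmp_root="scratch") -> dict:
    """Run the small demo pipeline twice and compare output hashes."""
    from .pipeline import run_pipeline

    hashes = []
    for tag in ("a", "b"):
        cfg = PipelineConfig(n_subjects=4, seed=seed, rest_duration=120.0,
                             cpt_duration=90.0, pp_step=0.5,
                             use_true_beats=True,
                             out_dir=f"{tmp_root}/determinism_{tag}")
        result = run_pipeline(cfg, use_cache=False)
        hashes.append(result["hashes"])
    return {"identical": hashes[0] == hashes[1],
            "digest": hashlib.sha256(
                json.dumps(hashes[0], sort_keys=True).encode()).hexdigest()}
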