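"""End-to-end orchestration: synthesize -> preprocess -> fit -> fuse ->
features -> statistics/classification, with caching and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .classify import loso_evaluate
from .eda import (compute_edasymp, decompose_scr, eda_time_frequency,
                  scr_features, EDASYMP_BAND)
from .fusion import align_series, compute_sympathovagal, phasic_quantifiers, \
    wavelet_tonic_phasic
from .pointprocess import PointProcessConfig, fit_point_process, \
    ks_goodness_of_fit
from .preprocess import HeartbeatSeries, correct_rr_artifacts, detect_r_peaks, \
    preprocess_eda
from .spectral import spectral_series
from .synth import CohortEffect, ProtocolSpec, SyntheticRecording, \
    default_protocol, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectSeries", "process_recording",
           "extract_features", "session_feature_table", "run_pipeline"]

PHASIC_SOURCES = ("LL", "LH", "HH", "S_LL", "S_LH", "S_HH")


@dataclass
class PipelineConfig:
    """Every knob of the processing chain, JSON-serializable for hashing."""

    n_subjects: int = 26
    seed: int = 0
    use_true_beats: bool = False
    rest_duration: float = 240.0
    cpt_duration: float = 180.0
    effect: dict = field(default_factory=lambda: dataclasses.asdict(
        CohortEffect(mu_rr_drop=80.0, hf_amp_factor=0.6,
                     scr_rate_factor=2.5, scr_amp_factor=1.8,
                     tonic_delta=0.8)))
    pp_step: float = 0.25
    pp_window: float = 90.0
    pp_alpha: float = 0.2
    pp_p: int = 6
    pp_q: int = 1
    edasymp_band: tuple = EDASYMP_BAND
    wavelet: str = "db5"
    wavelet_levels: int = 5
    cpt_window: str = "first"  # or "last"
    cpt_spans: tuple = (30.0, 90.0, 180.0)
    svm_C: float = 1.0
    with_scr: bool = True  # SCR deconvolution (F4 features) is optional
    out_dir: str = "ansindex_run"

    def pp_config(self) -> PointProcessConfig:
        return PointProcessConfig(alpha=self.pp_alpha, p=self.pp_p,
                                  q=self.pp_q, window=self.pp_window,
                                  step=self.pp_step)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectSeries:
    """All per-subject instantaneous series on a common 1 Hz clock."""

    beats: HeartbeatSeries
    clock: np.ndarray
    mu_rr: np.ndarray  # ms
    sigma2_rr: np.ndarray  # ms^2
    lf: np.ndarray
    hf: np.ndarray
    lf_hf: np.ndarray
    ll: np.ndarray
    lh: np.ndarray
    hh: np.ndarray
    edasymp: np.ndarray
    s_hf: np.ndarray
    s_ll: np.ndarray
    s_lh: np.ndarray
    s_hh: np.ndarray
    phasic: dict  # name -> phasic component (or None)
    scr: object  # ScrDecomposition
    ks_statistic: float


def process_recording(rec: SyntheticRecording,
                      config: PipelineConfig) -> SubjectSeries:
    """Run the full single-subject chain from raw signals to fused indices."""
    if config.use_true_beats or rec.ecg.size == 0:
        beats = HeartbeatSeries(rec.true_beat_times)
    else:
        beats = detect_r_peaks(rec.ecg, rec.ecg_rate)
    beats = correct_rr_artifacts(beats)

    fit = fit_point_process(beats, config.pp_config())
    spec, bis = spectral_series(fit)
    try:
        ks = ks_goodness_of_fit(fit).statistic
    except ValueError:
        ks = np.nan

    eda = preprocess_eda(rec.eda, rec.eda_rate)
    plane = eda_time_frequency(eda)
    symp = compute_edasymp(plane, tuple(config.edasymp_band))
    scr = decompose_scr(eda) if config.with_scr else None

    # common 1 Hz clock over the overlap of the EDA and point-process series
    pairs = {}
    for name, (t, v) in {
        "HF": (spec.times, spec.hf), "LF": (spec.times, spec.lf),
        "LFHF": (spec.times, spec.lf_hf),
        "LL": (bis.times, bis.ll), "LH": (bis.times, bis.lh),
        "HH": (bis.times, bis.hh),
    }.items():
        pairs[name] = align_series(symp.times, symp.values, t, v)
    clock = pairs["HF"].times
    edasymp = pairs["HF"].a

    s_hf = compute_sympathovagal(edasymp, pairs["HF"].b)
    s_ll = compute_sympathovagal(edasymp, pairs["LL"].b)
    s_lh = compute_sympathovagal(edasymp, pairs["LH"].b)
    s_hh = compute_sympathovagal(edasymp, pairs["HH"].b)

    def on_clock(al):
        """Snap an aligned pair's b-series onto the common clock."""
        out = np.full(clock.size, np.nan)
        idx = np.searchsorted(clock, al.times)
        ok = (idx < clock.size) & np.isclose(
            np.take(clock, idx, mode="clip"), al.times)
        out[idx[ok]] = al.b[ok]
        return out

    mu_al = on_clock(align_series(symp.times, symp.values,
                                  fit.times, fit.mu_rr * 1e3))
    sig_al = on_clock(align_series(symp.times, symp.values,
                                   fit.times, fit.sigma_rr**2 * 1e6))

    named = {"LL": pairs["LL"].b, "LH": pairs["LH"].b, "HH": pairs["HH"].b,
             "S_LL": s_ll, "S_LH": s_lh, "S_HH": s_hh}
    phasic = {}
    from .wavelets import Wavelet

    min_len = 2**config.wavelet_levels * Wavelet(config.wavelet).filter_length
    for name, series in named.items():
        if clock.size >= min_len:
            phasic[name] = wavelet_tonic_phasic(
                series, config.wavelet, config.wavelet_levels).phasic
        else:
            phasic[name] = None
    if any(v is None for v in phasic.values()):
        logger.info("series too short for %d-level %s: phasic features "
                    "skipped", config.wavelet_levels, config.wavelet)

    return SubjectSeries(
        beats=beats, clock=clock, mu_rr=mu_al, sigma2_rr=sig_al,
        lf=pairs["LF"].b, hf=pairs["HF"].b, lf_hf=pairs["LFHF"].b,
        ll=pairs["LL"].b, lh=pairs["LH"].b, hh=pairs["HH"].b,
        edasymp=edasymp, s_hf=s_hf, s_ll=s_ll, s_lh=s_lh, s_hh=s_hh,
        phasic=phasic, scr=scr, ks_statistic=ks)


def extract_features(ss: SubjectSeries, window: tuple[float, float]) -> dict:
    """All Table-style features of one subject over one time window."""
    lo, hi = window
    rr = feat.beats_in_window(ss.beats.event_times, lo, hi)
    row = {}
    row["mu_RR"] = _win_mean(ss, ss.mu_rr, window)
    row["sigma2_RR"] = _win_mean(ss, ss.sigma2_rr, window)
    row["RMSSD"] = feat.rmssd(rr) if rr.size >= 2 else np.nan
    row["pNN50"] = feat.pnn50(rr) if rr.size >= 2 else np.nan
    row["LF_pp"] = _win_mean(ss, ss.lf, window)
    row["HF_pp"] = _win_mean(ss, ss.hf, window)
    row["LF_HF"] = _win_mean(ss, ss.lf_hf, window)
    row["LL_pp"] = _win_mean(ss, ss.ll, window)
    row["LH_pp"] = _win_mean(ss, ss.lh, window)
    row["HH_pp"] = _win_mean(ss, ss.hh, window)
    row["EDAsymp"] = _win_mean(ss, ss.edasymp, window)
    row["S_HF"] = _win_mean(ss, ss.s_hf, window)
    if ss.scr is not None:
        row.update(scr_features(ss.scr, window))
    else:
        row.update({k: np.nan for k in ("EDA.nSCR", "EDA.SumAmpSCR",
                                        "EDA.PhasicMax", "EDA.Tonic")})
    row["S_LL"] = _win_mean(ss, ss.s_ll, window)
    row["S_LH"] = _win_mean(ss, ss.s_lh, window)
    row["S_HH"] = _win_mean(ss, ss.s_hh, window)
    for name in PHASIC_SOURCES:
        ph = ss.phasic.get(name)
        if ph is None:
            med = auc = np.nan
        else:
            try:
                med, auc = phasic_quantifiers(ph, ss.clock, window)
            except ValueError:
                med = auc = np.nan
        row[f"{name}_ph_med"] = med
        row[f"{name}_ph_auc"] = auc
    return row


def _win_mean(ss: SubjectSeries, values: np.ndarray,
              window: tuple[float, float]) -> float:
    out = feat.window_average(ss.clock, values, [window])
    return float(out[0])


def cpt_feature_table(series: list[SubjectSeries],
                      protocols: list[ProtocolSpec],
                      config: PipelineConfig) -> pd.DataFrame:
    """Rest window vs CPT windows feature table (one row per window)."""
    rows = []
    for subj, (ss, proto) in enumerate(zip(series, protocols)):
        r_lo, r_hi = proto.segment_window("rest")
        c_lo, c_hi = proto.segment_window("cpt")
        windows = {"rest30": (r_hi - 30.0, r_hi)}
        for span in config.cpt_spans:
            span = min(span, c_hi - c_lo)
            if config.cpt_window == "first":
                windows[f"cpt{int(span)}"] = (c_lo, c_lo + span)
            else:
                windows[f"cpt{int(span)}"] = (c_hi - span, c_hi)
        for name, w in windows.items():
            row = {"subject": subj, "window": name}
            row.update(extract_features(ss, w))
            rows.append(row)
    return pd.DataFrame(rows)


def session_feature_table(series: list[SubjectSeries],
                          protocols: list[ProtocolSpec]) -> pd.DataFrame:
    """Per-session (neutral/pleasant/unpleasant) 90 s feature table."""
    rows = []
    for subj, (ss, proto) in enumerate(zip(series, protocols)):
        for label in ("neutral", "pleasant", "unpleasant"):
            try:
                lo, hi = proto.segment_window(label)
            except KeyError:
                continue
            row = {"subject": subj, "session": label}
            row.update(extract_features(ss, (lo, min(hi, lo + 90.0))))
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 use_cache: bool = True) -> dict:
    """Execute all stages; returns a dict of output tables and reports.

    Stage outputs are cached under ``out_dir/cache`` keyed by the config
    digest, so re-running an identical configuration reuses results.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = out_dir / "cache"
    cache.mkdir(exist_ok=True)
    digest = config.digest()
    manifest = {"config": dataclasses.asdict(config), "digest": digest,
                "stages": {}}

    t0 = time.time()
    cpt_csv = cache / f"cpt_features_{digest}.csv"
    ses_csv = cache / f"session_features_{digest}.csv"
    if use_cache and cpt_csv.exists() and ses_csv.exists():
        # round_trip parsing so cached tables rewrite bit-identically
        cpt_table = pd.read_csv(cpt_csv, float_precision="round_trip")
        ses_table = pd.read_csv(ses_csv, float_precision="round_trip")
        logger.info("reusing cached feature tables (%s)", digest)
    else:
        protocol = default_protocol(config.seed, rest=config.rest_duration,
                                    cpt=config.cpt_duration)
        cohort = generate_cohort(
            config.n_subjects, CohortEffect(**config.effect),
            seed=config.seed, base_protocol=protocol,
            render_ecg=not config.use_true_beats)
        series = [process_recording(rec, config) for rec in cohort]
        protocols = [rec.protocol for rec in cohort]
        cpt_table = cpt_feature_table(series, protocols, config)
        ses_table = session_feature_table(series, protocols)
        cpt_table.to_csv(cpt_csv, index=False)
        ses_table.to_csv(ses_csv, index=False)
    manifest["stages"]["features"] = {"seconds": round(time.time() - t0, 2)}

    # statistics: rest vs each CPT window
    stats = {}
    for span in config.cpt_spans:
        name = f"cpt{int(min(span, config.cpt_duration))}"
        stats[name] = feat.compare_conditions(cpt_table, "rest30", name)
    stats_df = pd.concat([df.assign(window=k) for k, df in stats.items()],
                         ignore_index=True)

    # classification: pleasant vs unpleasant, neutral-normalized
    clf_report = None
    ranking = None
    if not ses_table.empty and \
            {"pleasant", "unpleasant"} <= set(ses_table["session"]):
        norm = feat.normalize_by_neutral(ses_table)
        cols = [c for c in norm.columns if c not in ("subject", "session")]
        keep = [c for c in cols if np.isfinite(norm[c]).all()]
        X = norm[keep].to_numpy(dtype=float)
        y = np.where(norm["session"] == "pleasant", 1, -1)
        subj = norm["subject"].to_numpy()
        report, rfe = loso_evaluate(X, y, subj, C=config.svm_C)
        clf_report = {
            "confusion_pct": report.confusion.tolist(),
            "balanced_accuracy": report.balanced_accuracy,
            "ppv": report.ppv, "npv": report.npv,
            "n_features_used": report.n_features_used,
        }
        ranking = pd.DataFrame({
            "feature": [keep[f] for f in rfe.aggregate_ranking],
            "rank": np.arange(1, len(keep) + 1),
        })

    # persist outputs + manifest with content hashes
    outputs = {"cpt_features.csv": cpt_table, "session_features.csv": ses_table,
               "statistics.csv": stats_df}
    if ranking is not None:
        outputs["feature_ranking.csv"] = ranking
    hashes = {}
    for name, df in outputs.items():
        path = out_dir / name
        df.to_csv(path, index=False)
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    if clf_report is not None:
        path = out_dir / "classification.json"
        path.write_text(json.dumps(clf_report, indent=2))
        hashes["classification.json"] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    manifest["output_hashes"] = hashes
    manifest["wall_seconds"] = round(time.time() - t0, 2)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {"cpt_features": cpt_table, "session_features": ses_table,
            "statistics": stats_df, "classification": clf_report,
            "ranking": ranking, "hashes": hashes, "manifest": manifest}
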