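# ansindex

Instantaneous autonomic assessment from heartbeat dynamics and electrodermal
activity (EDA), validated end to end on synthetic physiological signals with
known ground truth.

The package implements:

- **Synthetic data** (`ansindex.synth`) — an integral pulse frequency
  modulation (IPFM) generator for R-wave event times with controllable LF
  (0.1 Hz) / HF (0.25 Hz) modulation and CPT-like step changes in mean heart
  period; EDA as a slow tonic spline plus Bateman-shaped skin-conductance
  responses (SCRs) from a Poisson driver; template-based ECG rendering; and
  reproducible multi-subject cohorts with configurable sympathetic effects.
- **Preprocessing** (`ansindex.preprocess`) — Pan-Tompkins-style R-peak
  detection, local-median RR artifact correction with cubic-spline
  replacement, and EDA anti-alias decimation to 50 Hz with Z-scoring.
- **Point-process heartbeat model** (`ansindex.pointprocess`,
  `ansindex.laguerre`, `ansindex.spectral`) — inverse-Gaussian interval
  model whose mean is a quadratic Volterra expansion of past RR increments
  in an orthonormal Laguerre basis, tracked by locally weighted maximum
  likelihood (Newton-type/Fisher scoring, exponential forgetting, 5 ms
  default resolution), with time-rescaling KS goodness-of-fit, the
  instantaneous power spectrum (LF/HF band powers), and the magnitude
  bispectrum with LL/LH/HH band integrals.
- **EDA analysis** (`ansindex.eda`) — sliding 60 s Blackman/Welch
  time-frequency plane (1 s step), the sympathetic index as the 0.045–0.25 Hz
  band integral, and sparse non-negative SCR deconvolution (Bateman kernel +
  coarse spline tonic) with the four standard EDA features.
- **Index fusion** (`ansindex.fusion`, `ansindex.wavelets`) — the four
  sympatho-vagal ratios S_HF, S_LL, S_LH, S_HH on a common 1 Hz clock, and
  tonic/phasic decomposition via an in-repo 5-level db5 DWT (Daubechies
  filters built by spectral factorization; perfect reconstruction to 1e-10)
  with median/AUC phasic quantifiers.
- **Features & statistics** (`ansindex.features`) — RMSSD, pNN50, window
  averaging, neutral-session normalization, exact paired Wilcoxon
  signed-rank test (full 2^n enumeration for n ≤ 12), Lilliefors normality
  screening, and robust median ± 1.4826·MAD/√n summaries.
- **Classification** (`ansindex.classify`) — nonlinear (RBF) SVM recursive
  feature elimination with a kernel-space weight-norm criterion,
  correlation-bias grouping, leave-one-subject-out validation, rank
  aggregation, and confusion-matrix reporting.
- **Pipeline & CLI** (`ansindex.pipeline`, `ansindex.cli`) — cached,
  manifest-logged orchestration of all stages.

## CLI

```sh
ansindex synth --subjects 4 --seed 1 --out synth_out
ansindex preprocess --ecg synth_out/s00_ecg.csv --out rr.csv
ansindex fit-pp --rr synth_out/s00_beats.txt --step 0.25 --out pp.csv
ansindex eda-symp --in synth_out/s00_eda.csv --out symp.csv
ansindex fuse --edasymp symp.csv --pp pp.csv --out indices.csv
ansindex run-all --subjects 26 --seed 0 --out demo_run
```

`run-all` synthesizes a cohort, runs every stage, and writes the feature
tables, rest-vs-CPT statistics, the SVM-RFE ranking and the classification
report together with a manifest of output hashes (identical config + seed
reproduce identical hashes; stage outputs are cached).

## Notes

- Default bands: LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, bispectral split at
  0.15 Hz with 0.4 Hz top, EDA sympathetic band 0.045–0.25 Hz; all
  configurable.
- The point-process evaluation grid defaults to 5 ms; tests and benchmarks
  use coarser grids (0.25–1 s) purely for speed — estimates are identical
  on the thinner grid since regressors are piecewise-constant between
  beats.
- The bispectrum normalization (linear transfer at f1, f2, f1+f2 times the
  2-D Laguerre-kernel transform, scaled by 2·sigma^4·dt^2) is an
  implementation convention; magnitudes are comparable within this package
  only.
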