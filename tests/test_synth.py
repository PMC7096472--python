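import numpy as np
import pytest
from scipy.signal import welch

from ansindex.synth import (CohortEffect, ProtocolSpec, SegmentParams,
                            bateman_peak_time, default_protocol, generate_cohort,
                            generate_ecg, generate_eda, generate_rr)

from conftest import flat_protocol


class TestProtocolSpec:
    def test_rejects_bad_duration(self):
        with pytest.raises(ValueError):
            SegmentParams("rest", 0.0)

    def test_rejects_mean_rr_out_of_range(self):
        with pytest.raises(ValueError):
            SegmentParams("rest", 60.0, mean_rr=250.0)
        with pytest.raises(ValueError):
            SegmentParams("rest", 60.0, mean_rr=2500.0)

    def test_rejects_negative_amplitudes_and_rates(self):
        with pytest.raises(ValueError):
            SegmentParams("rest", 60.0, lf_amp=-0.1)
        with pytest.raises(ValueError):
            SegmentParams("rest", 60.0, scr_rate=-1.0)

    def test_rejects_unknown_label(self):
        with pytest.raises(ValueError):
            SegmentParams("swimming", 60.0)

    def test_segment_window(self):
        p = default_protocol(0)
        lo, hi = p.segment_window("cpt")
        assert lo == 240.0 and hi == 420.0

    def test_json_roundtrip(self, tmp_path):
        p = default_protocol(3)
        f = tmp_path / "protocol.json"
        p.to_json(f)
        q = ProtocolSpec.from_json(f)
        assert q == p


class TestGenerateRr:
    def test_unmodulated_ipfm_exact_spacing(self):
        proto = flat_protocol(60.0, mean_rr=1000.0, lf_amp=0.0, hf_amp=0.0)
        beats = generate_rr(proto)
        assert beats.size == 60
        assert np.allclose(np.diff(beats), 1.0, atol=1e-9)
        assert np.allclose(beats, np.arange(1, 61), atol=1e-9)

    def test_hf_modulation_peak_location(self):
        proto = flat_protocol(300.0, mean_rr=1000.0, lf_amp=0.0, hf_amp=0.1)
        beats = generate_rr(proto)
        rr = np.diff(beats)
        # resample RR to a uniform 4 Hz grid for spectral analysis
        tg = np.arange(beats[1], beats[-1], 0.25)
        rrg = np.interp(tg, beats[1:], rr)
        f, p = welch(rrg - rrg.mean(), fs=4.0, nperseg=1024)
        peak = f[np.argmax(p)]
        assert abs(peak - 0.25) <= 0.02

    def test_deterministic_under_seed(self):
        proto = flat_protocol(120.0, seed=7)
        a = generate_rr(proto, noise_amp=0.05)
        b = generate_rr(proto, noise_amp=0.05)
        np.testing.assert_array_equal(a, b)

    def test_beat_count_matches_rate_integral(self):
        # IPFM invariant: count = floor(integral of m) +/- 1
        for mu, dur in [(800.0, 90.0), (1200.0, 150.0)]:
            proto = flat_protocol(dur, mean_rr=mu, lf_amp=0.08, hf_amp=0.1)
            beats = generate_rr(proto)
            expected = dur / (mu / 1000.0)
            assert abs(beats.size - expected) <= 1.5

    def test_modulated_power_concentrates_in_band(self):
        proto = flat_protocol(400.0, mean_rr=1000.0, lf_amp=0.0, hf_amp=0.1)
        beats = generate_rr(proto)
        rr = np.diff(beats)
        tg = np.arange(beats[1], beats[-1], 0.25)
        rrg = np.interp(tg, beats[1:], rr)
        f, p = welch(rrg - rrg.mean(), fs=4.0, nperseg=1024)
        in_band = p[(f >= 0.22) & (f <= 0.28)].sum()
        assert in_band / p.sum() >= 0.8


class TestGenerateEda:
    def test_zero_rate_returns_tonic_exactly(self):
        proto = flat_protocol(60.0, scr_rate=0.0, tonic_level=1.5)
        eda, scrs, tonic, phasic = generate_eda(proto, rate=50.0)
        assert scrs.size == 0
        np.testing.assert_array_equal(eda, tonic)
        assert np.all(phasic == 0)

    def test_single_impulse_peak_at_closed_form_time(self):
        proto = flat_protocol(60.0, scr_rate=0.0)
        rate = 50.0
        eda, _, tonic, phasic = generate_eda(
            proto, rate=rate, driver_times=np.array([10.0]),
            driver_amps=np.array([1.0]))
        t_peak = np.argmax(phasic) / rate
        expected = 10.0 + bateman_peak_time(0.7, 3.0)
        assert abs(t_peak - expected) <= 1.0 / rate

    def test_doubling_amplitudes_doubles_phasic(self):
        proto = flat_protocol(90.0, scr_rate=0.0)
        times = np.array([5.0, 20.0, 44.0])
        _, _, _, ph1 = generate_eda(proto, rate=50.0, driver_times=times,
                                    driver_amps=np.array([0.2, 0.4, 0.1]))
        _, _, _, ph2 = generate_eda(proto, rate=50.0, driver_times=times,
                                    driver_amps=np.array([0.4, 0.8, 0.2]))
        np.testing.assert_allclose(ph2, 2.0 * ph1, rtol=1e-12)

    def test_negative_amplitude_rejected(self):
        proto = flat_protocol(60.0)
        with pytest.raises(ValueError):
            generate_eda(proto, driver_times=np.array([5.0]),
                         driver_amps=np.array([-1.0]))

    def test_output_is_tonic_plus_phasic(self):
        proto = flat_protocol(120.0, scr_rate=6.0, seed=3)
        eda, _, tonic, phasic = generate_eda(proto, rate=50.0)
        np.testing.assert_allclose(eda, tonic + phasic, atol=1e-12)


class TestGenerateEcg:
    def test_peaks_at_beat_times_noise_free(self):
        rate = 500.0
        beats = np.array([1.0, 2.0, 3.0])
        ecg = generate_ecg(beats, rate=rate, duration=4.0)
        for bt in beats:
            c = int(round(bt * rate))
            w = ecg[c - 50:c + 51]
            assert abs((c - 50 + np.argmax(w)) / rate - bt) <= 0.002

    def test_sample_count(self):
        beats = np.arange(1.0, 299.0)
        ecg = generate_ecg(beats, rate=500.0, duration=300.0)
        assert ecg.size == 150000

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_ecg(np.array([1.0, 2.0]), rate=80.0)


class TestGenerateCohort:
    def test_reproducible(self):
        proto = default_protocol(0, rest=60.0, cpt=45.0, include_emotion=False)
        a = generate_cohort(3, seed=5, base_protocol=proto, render_ecg=False)
        b = generate_cohort(3, seed=5, base_protocol=proto, render_ecg=False)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.true_beat_times,
                                          rb.true_beat_times)
            np.testing.assert_array_equal(ra.eda, rb.eda)

    def test_rejects_single_subject(self):
        with pytest.raises(ValueError):
            generate_cohort(1, seed=0)

    def test_cpt_effect_applied(self):
        proto = default_protocol(0, rest=60.0, cpt=60.0, include_emotion=False)
        eff = CohortEffect(mu_rr_drop=100.0)
        cohort = generate_cohort(4, eff, seed=2, base_protocol=proto,
                                 render_ecg=False, jitter_cv=0.0,
                                 rr_noise_amp=0.0)
        for rec in cohort:
            segs = {s.label: s for s in rec.protocol.segments}
            assert segs["cpt"].mean_rr == segs["rest"].mean_rr - 100.0
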