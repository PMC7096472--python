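import numpy as np
import pytest

from ansindex.eda import (compute_edasymp, decompose_scr,
                          eda_time_frequency, scr_features)
from ansindex.preprocess import EdaSeries, preprocess_eda
from ansindex.synth import generate_eda

from conftest import flat_protocol


def _sine_series(freq, duration=180.0, fs=50.0, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    x = amp * np.sin(2 * np.pi * freq * t)
    return EdaSeries(x, fs)


class TestTimeFrequency:
    def test_step_count(self):
        tf = eda_time_frequency(_sine_series(0.1, duration=180.0))
        assert tf.times.size == 180 - 60 + 1

    def test_peak_at_signal_frequency(self):
        tf = eda_time_frequency(_sine_series(0.1))
        for row in tf.power[::20]:
            peak = tf.frequencies[np.argmax(row)]
            assert abs(peak - 0.1) <= 0.01

    def test_white_noise_total_power(self, rng):
        x = rng.standard_normal(9000)
        tf = eda_time_frequency(EdaSeries(x, 50.0))
        total = np.trapezoid(tf.power, tf.frequencies, axis=1).mean()
        assert abs(total - x.var()) / x.var() < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            eda_time_frequency(_sine_series(0.1, duration=30.0))

    def test_power_nonnegative(self, rng):
        tf = eda_time_frequency(EdaSeries(rng.standard_normal(5000), 50.0))
        assert np.all(tf.power >= 0)


class TestEdasymp:
    def test_in_band_capture_at_0p1(self):
        tf = eda_time_frequency(_sine_series(0.1))
        symp = compute_edasymp(tf)
        sel = tf.frequencies <= 0.5
        total = np.trapezoid(tf.power[:, sel], tf.frequencies[sel], axis=1)
        assert np.all(symp.values / total >= 0.90)

    def test_out_of_band_rejection_at_0p5(self):
        tf = eda_time_frequency(_sine_series(0.5))
        symp = compute_edasymp(tf)
        total = np.trapezoid(tf.power, tf.frequencies, axis=1)
        assert np.all(symp.values / total <= 0.05)

    def test_zero_signal(self):
        tf = eda_time_frequency(EdaSeries(np.zeros(5000), 50.0))
        symp = compute_edasymp(tf)
        assert np.all(symp.values == 0)

    def test_band_outside_grid_rejected(self):
        tf = eda_time_frequency(_sine_series(0.1))
        with pytest.raises(ValueError):
            compute_edasymp(tf, band=(0.045, 100.0))

    def test_invariant_to_constant_offset(self, rng):
        raw = rng.standard_normal(60000) * 0.3 + 5.0
        a = compute_edasymp(eda_time_frequency(preprocess_eda(raw, 500.0)))
        b = compute_edasymp(eda_time_frequency(
            preprocess_eda(raw + 42.0, 500.0)))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)


class TestDecomposeScr:
    def test_single_scr_localized(self):
        proto = flat_protocol(60.0, scr_rate=0.0)
        eda, _, _, _ = generate_eda(proto, rate=50.0,
                                    driver_times=np.array([25.0]),
                                    driver_amps=np.array([0.8]))
        dec = decompose_scr(EdaSeries(eda, 50.0))
        assert dec.peak_times.size == 1
        assert abs(dec.peak_times[0] - 25.0) < 0.5

    def test_drift_only_small_phasic(self):
        t = np.arange(0, 120, 1 / 50.0)
        drift = 2.0 + 0.3 * np.sin(2 * np.pi * t / 240.0)
        dec = decompose_scr(EdaSeries(drift, 50.0))
        assert np.linalg.norm(dec.phasic) / np.linalg.norm(drift) < 0.05

    def test_driver_nonnegative(self):
        proto = flat_protocol(90.0, scr_rate=6.0, seed=2)
        eda, *_ = generate_eda(proto, rate=50.0)
        dec = decompose_scr(EdaSeries(eda, 50.0))
        assert np.all(dec.driver >= 0)

    def test_residual_small_on_generator_output(self):
        proto = flat_protocol(120.0, scr_rate=6.0, seed=4)
        eda, *_ = generate_eda(proto, rate=50.0)
        dec = decompose_scr(EdaSeries(eda, 50.0))
        assert dec.residual < 0.1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            decompose_scr(EdaSeries(np.zeros(500), 50.0))


@pytest.fixture(scope="module")
def three_scr_decomp():
    proto = flat_protocol(120.0, scr_rate=0.0, tonic_level=1.0)
    eda, *_ = generate_eda(proto, rate=50.0,
                           driver_times=np.array([20.0, 50.0, 80.0]),
                           driver_amps=np.array([0.3, 0.5, 0.2]))
    return decompose_scr(EdaSeries(eda, 50.0))


class TestScrFeatures:

    def test_no_scrs_zero_counts(self):
        t = np.arange(0, 60, 1 / 50.0)
        dec = decompose_scr(EdaSeries(np.full(t.size, 1.0), 50.0))
        f = scr_features(dec, (0.0, 60.0))
        assert f["EDA.nSCR"] == 0.0
        assert f["EDA.SumAmpSCR"] == 0.0

    def test_three_scrs_counted_and_summed(self, three_scr_decomp):
        f = scr_features(three_scr_decomp, (0.0, 120.0))
        assert f["EDA.nSCR"] == pytest.approx(3 / 2.0)  # per minute
        assert f["EDA.SumAmpSCR"] == pytest.approx(1.0, rel=0.10)

    def test_doubling_amplitude_scales_features(self):
        proto = flat_protocol(120.0, scr_rate=0.0, tonic_level=1.0)
        times = np.array([20.0, 50.0, 80.0])
        amps = np.array([0.3, 0.5, 0.2])
        e1, *_ = generate_eda(proto, rate=50.0, driver_times=times,
                              driver_amps=amps)
        e2, *_ = generate_eda(proto, rate=50.0, driver_times=times,
                              driver_amps=2 * amps)
        f1 = scr_features(decompose_scr(EdaSeries(e1, 50.0)), (0.0, 120.0))
        f2 = scr_features(decompose_scr(EdaSeries(e2, 50.0)), (0.0, 120.0))
        assert f2["EDA.SumAmpSCR"] / f1["EDA.SumAmpSCR"] == pytest.approx(
            2.0, rel=0.05)
        assert f2["EDA.PhasicMax"] / f1["EDA.PhasicMax"] == pytest.approx(
            2.0, rel=0.05)

    def test_empty_segment_rejected(self, three_scr_decomp):
        with pytest.raises(ValueError):
            scr_features(three_scr_decomp, (10.0, 10.0))

    def test_tonic_mean(self, three_scr_decomp):
        f = scr_features(three_scr_decomp, (0.0, 120.0))
        assert f["EDA.Tonic"] == pytest.approx(1.0, abs=0.05)
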