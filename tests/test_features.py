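import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon

from ansindex.features import (normality_check, normalize_by_neutral,
                               paired_wilcoxon, pnn50, rmssd, robust_summary,
                               window_average)


class TestRmssd:
    def test_constant(self):
        assert rmssd(np.array([0.8, 0.8, 0.8])) == 0.0

    def test_single_difference(self):
        assert rmssd(np.array([0.8, 0.9])) == pytest.approx(0.1)

    def test_matches_bruteforce(self, rng):
        rr = rng.uniform(0.6, 1.1, size=50)
        expected = np.sqrt(np.mean([(rr[i + 1] - rr[i]) ** 2
                                    for i in range(49)]))
        assert rmssd(rr) == pytest.approx(expected, rel=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            rmssd(np.array([0.8]))


class TestPnn50:
    def test_no_changes(self):
        assert pnn50(np.array([0.8, 0.8, 0.8])) == 0.0

    def test_two_of_three(self):
        rr = np.cumsum(np.array([0.0, 0.060, 0.040, 0.070])) + 0.8
        assert pnn50(rr) == pytest.approx(100.0 * 2 / 3)

    def test_matches_counting_oracle(self, rng):
        rr = rng.uniform(0.6, 1.1, size=80)
        d = np.abs(np.diff(rr))
        expected = 100.0 * np.sum(d > 0.050) / d.size
        assert pnn50(rr) == pytest.approx(expected)


class TestWindowAverage:
    def test_constant(self):
        t = np.arange(100.0)
        out = window_average(t, np.full(100, 5.0), [(10.0, 20.0)])
        assert out[0] == 5.0

    def test_step_function_plateaus(self):
        t = np.arange(100.0)
        v = np.where(t < 50, 1.0, 3.0)
        out = window_average(t, v, [(0.0, 50.0), (50.0, 100.0)])
        np.testing.assert_allclose(out, [1.0, 3.0])

    def test_matches_mean_oracle(self, rng):
        t = np.arange(200.0)
        v = rng.standard_normal(200)
        out = window_average(t, v, [(37.0, 151.0)])
        assert out[0] == pytest.approx(v[37:151].mean())

    def test_empty_window_is_nan(self):
        out = window_average(np.arange(10.0), np.ones(10), [(20.0, 30.0)])
        assert np.isnan(out[0])


class TestNormalizeByNeutral:
    def _table(self):
        return pd.DataFrame({
            "subject": [0, 0, 0, 1, 1, 1],
            "session": ["neutral", "pleasant", "unpleasant"] * 2,
            "f1": [2.0, 3.0, 4.0, 1.0, 1.0, 0.5],
            "f2": [1.0, 1.0, 2.0, 4.0, 2.0, 8.0],
        })

    def test_values(self):
        out = normalize_by_neutral(self._table())
        row = out[(out.subject == 0) & (out.session == "pleasant")].iloc[0]
        assert row.f1 == 1.5
        assert row.f2 == 1.0

    def test_identity_when_equal(self):
        t = self._table()
        t["f1"] = 2.0
        out = normalize_by_neutral(t)
        assert (out.f1 == 1.0).all()

    def test_matches_division_oracle(self, rng):
        t = self._table()
        out = normalize_by_neutral(t)
        for subj in (0, 1):
            base = t[(t.subject == subj) & (t.session == "neutral")].iloc[0]
            for ses in ("pleasant", "unpleasant"):
                raw = t[(t.subject == subj) & (t.session == ses)].iloc[0]
                nrm = out[(out.subject == subj) & (out.session == ses)].iloc[0]
                assert nrm.f1 == raw.f1 / base.f1
                assert nrm.f2 == raw.f2 / base.f2

    def test_zero_neutral_masked(self):
        t = self._table()
        t.loc[0, "f1"] = 0.0
        out = normalize_by_neutral(t)
        assert out[out.subject == 0].f1.isna().all()
        assert out[out.subject == 1].f1.notna().all()

    def test_missing_neutral_rejected(self):
        t = self._table()
        with pytest.raises(ValueError):
            normalize_by_neutral(t[t.session != "neutral"])


def wilcoxon_bruteforce(x, y):
    """Independent enumeration oracle over all 2^n sign patterns."""
    d = x - y
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)]
    sums = np.asarray(sums, dtype=float)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


class TestPairedWilcoxon:
    def test_identical_samples(self):
        x = np.arange(8.0)
        res = paired_wilcoxon(x, x)
        assert res.p_value == 1.0
        assert res.n_used == 0

    def test_all_positive_n8_exact(self):
        x = np.arange(1.0, 9.0)
        y = x - 1.0
        res = paired_wilcoxon(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(2.0 / 2**8)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(5, 13)
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            res = paired_wilcoxon(x, y)
            assert res.p_value == pytest.approx(wilcoxon_bruteforce(x, y),
                                                abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            ours = paired_wilcoxon(x, y).p_value
            ref = wilcoxon(x, y, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_n_normal_approx_close_to_scipy(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40) + 0.3
        ours = paired_wilcoxon(x, y)
        ref = wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert not ours.exact
        assert ours.p_value == pytest.approx(ref, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.ones(6), np.ones(5))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.ones(3), np.zeros(3))


class TestNormalityCheck:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_check(np.array([1.0, 2.0, 3.0]))

    def test_constant_sample_fails(self):
        assert normality_check(np.full(20, 1.0)) is False

    def test_calibration_near_nominal(self):
        rejections = 0
        n_rep = 300
        rng = np.random.default_rng(0)
        for _ in range(n_rep):
            if not normality_check(rng.standard_normal(200)):
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        rejections = sum(not normality_check(rng.exponential(size=200))
                         for _ in range(200))
        assert rejections / 200 >= 0.95


class TestRobustSummary:
    def test_constant(self):
        assert robust_summary(np.array([1.0, 1.0, 1.0])) == (1.0, 0.0)

    def test_known_values(self):
        med, disp = robust_summary(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert med == 3.0
        assert disp == pytest.approx(1.4826 / np.sqrt(5), rel=1e-9)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(31)
        m1, d1 = robust_summary(x)
        m2, d2 = robust_summary(3.0 * x)
        assert m2 == pytest.approx(3.0 * m1)
        assert d2 == pytest.approx(3.0 * d1)


class TestBhAdjust:
    def test_monotone_and_bounded(self, rng):
        from ansindex.features import bh_adjust
        p = rng.uniform(0, 1, size=20)
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= p - 1e-15)
        # BH preserves the p-value ordering
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_known_example(self):
        from ansindex.features import bh_adjust
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])
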