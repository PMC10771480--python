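"""Voltage-dye pipeline: fading fit, normalization, peaks, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from excitep import trace_analysis as ta

FRAMES = np.arange(80) * 0.036
PULSE = 0.324


def _trace(F, **kw):
    return ta.FluorescenceTrace(times=FRAMES, F=np.asarray(F, float), **kw)


def _resp(R, pulse_time=PULSE):
    return ta.ResponseTrace(times=FRAMES.copy(), R=np.asarray(R, float),
                            pulse_time=pulse_time)


class TestFitFading:
    def test_constant_control(self):
        k = ta.fit_fading(_trace(np.full(80, 100.0), is_control=True))
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear(self):
        k = ta.fit_fading(_trace(100.0 - 5.0 * FRAMES, is_control=True))
        assert k == pytest.approx(-5.0)

    def test_noisy_slope_within_three_se(self):
        """Monte-Carlo over seeds: fitted slope within 3 SE of the truth."""
        sigma = 0.5
        t = FRAMES
        se = sigma / np.sqrt(((t - t.mean()) ** 2).sum())
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = 100.0 - 5.0 * t + rng.normal(0, sigma, t.size)
            k = ta.fit_fading(_trace(f, is_control=True))
            assert abs(k + 5.0) < 3 * se

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ta.fit_fading(
                ta.FluorescenceTrace(times=np.array([0.0]), F=np.array([1.0]),
                                     is_control=True)
            )


class TestNormalize:
    def test_pure_fading_gives_zero_response(self):
        f0 = 100.0 - 5.0 * FRAMES
        resp = ta.normalize(_trace(f0), k=-5.0)
        assert np.max(np.abs(resp.R)) < 1e-12

    def test_single_frame_dip(self):
        f = np.full(80, 100.0)
        f[20] = 95.0
        resp = ta.normalize(_trace(f), k=0.0)
        assert resp.R[20] == pytest.approx(0.05)
        assert resp.R[19] == pytest.approx(0.0, abs=1e-12)

    def test_negative_baseline_rejected(self):
        f = np.full(80, 1.0)
        with pytest.raises(ValueError):
            ta.normalize(_trace(f), k=-5.0)  # baseline crosses zero

    def test_requires_ten_pre_pulse_frames(self):
        t = FRAMES[8:]
        with pytest.raises(ValueError):
            ta.normalize(
                ta.FluorescenceTrace(times=t, F=np.full(t.size, 100.0),
                                     pulse_time=PULSE),
                k=0.0,
            )


class TestDetectPeaks:
    def test_flat_has_no_peaks(self):
        assert ta.detect_peaks(_resp(np.zeros(80))) == []

    def test_clean_bump_found_at_apex(self):
        r = 0.05 * np.exp(-((FRAMES - 0.7) ** 2) / (2 * 0.1**2))
        peaks = ta.detect_peaks(_resp(r))
        assert len(peaks) == 1
        assert abs(FRAMES[peaks[0]] - 0.7) <= 0.036

    def test_monotone_plateau_fallback(self):
        r = 0.04 * np.clip((FRAMES - PULSE) / 0.5, 0, 1)
        peaks = ta.detect_peaks(_resp(r))
        assert len(peaks) == 1
        assert abs(peaks[0] - int(np.argmax(r))) <= 1  # at the maximum (+- smoothing)
        assert r[peaks[0]] == pytest.approx(0.04)

    def test_subthreshold_response_ignored(self):
        r = 0.005 * np.clip((FRAMES - PULSE) / 0.5, 0, 1)
        assert ta.detect_peaks(_resp(r)) == []


class TestExtractParams:
    def test_no_peaks(self):
        p = ta.extract_params(_resp(np.zeros(80)), [])
        assert p.n_peaks == 0
        assert p.max_response is None and p.t50 is None

    def test_triangle_recovery_times(self):
        """Closed-form triangle: apex 0.04 at 0.5 s, linear to 0 at 1.5 s."""
        apex_t, end_t, amp = 0.504, 1.5, 0.04
        r = np.where(
            FRAMES <= apex_t,
            amp * np.clip((FRAMES - PULSE) / (apex_t - PULSE), 0, 1),
            amp * np.clip((end_t - FRAMES) / (end_t - apex_t), 0, 1),
        )
        resp = _resp(r)
        peaks = ta.detect_peaks(resp)
        p = ta.extract_params(resp, peaks)
        # Linear decay over ~1 s: x% recovery at x% of the way down.
        slope = (end_t - apex_t)  # seconds per full decay
        for name, frac in (("t25", 0.25), ("t50", 0.50), ("t90", 0.90)):
            expected = frac * slope
            got = getattr(p, name)
            assert got == pytest.approx(expected, abs=0.037), name
        assert p.time_to_first_peak == pytest.approx(apex_t - PULSE, abs=0.037)

    def test_plateau_t25_not_reached(self):
        r = 0.04 * (FRAMES >= PULSE)  # steps up, never decays
        resp = _resp(r.astype(float))
        p = ta.extract_params(resp, ta.detect_peaks(resp))
        assert p.t25 is None and p.t50 is None and p.t90 is None

    def test_peak_to_peak_mean(self):
        r = np.zeros(80)
        for c in (0.6, 1.2, 1.8):
            r += 0.05 * np.exp(-((FRAMES - c) ** 2) / (2 * 0.05**2))
        resp = _resp(r)
        p = ta.extract_params(resp, ta.detect_peaks(resp))
        assert p.n_peaks == 3
        assert p.mean_peak_to_peak == pytest.approx(0.6, abs=0.037)


class TestClassify:
    def _params(self, **kw):
        base = dict(n_peaks=1, max_response=0.05, t25=0.1, t50=0.3, t90=0.45)
        base.update(kw)
        return ta.ResponseParams(**base)

    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(n_peaks=0, max_response=None, t25=None, t50=None, t90=None),
             "no_response"),
            (dict(), "single_AP"),
            (dict(n_peaks=3), "multiple_APs"),
            (dict(n_peaks=2, t50=None, t90=None), "multiple_APs"),
            (dict(max_response=0.015), "sustained_depolarization"),
            (dict(t50=None), "sustained_depolarization"),
            (dict(t50=0.71), "sustained_depolarization"),
            (dict(t50=0.3, t90=0.61), "sustained_depolarization"),  # ratio >= 2
            (dict(t90=None), "sustained_depolarization"),
            (dict(max_response=0.021, t50=0.699, t90=1.39), "single_AP"),
        ],
    )
    def test_stated_rules(self, kw, expected):
        assert ta.classify(self._params(**kw)).value == expected

    def test_total_function(self):
        """Every parameter combination maps to exactly one class."""
        for n in (0, 1, 2, 5):
            for mr in (None, 0.001, 0.05):
                for t50 in (None, 0.2, 1.0):
                    for t90 in (None, 0.3, 2.0):
                        p = ta.ResponseParams(
                            n_peaks=n, max_response=mr, t50=t50, t90=t90
                        )
                        assert ta.classify(p) in ta.ResponseClass


class TestPipelineInvariances:
    def _ap_trace(self, k=-5.0, scale=1.0):
        r_true = 0.05 * np.exp(-((FRAMES - 0.7) ** 2) / (2 * 0.1**2))
        f = scale * (100.0 + k * FRAMES) * (1 - r_true)
        ctrl = scale * (100.0 + k * FRAMES)
        return _trace(f), _trace(ctrl, is_control=True)

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_intensity_scale_invariance(self, c):
        tr1, ct1 = self._ap_trace(scale=1.0)
        tr2, ct2 = self._ap_trace(scale=c)
        p1, c1 = ta.analyze_trace(tr1, ta.fit_fading(ct1))
        p2, c2 = ta.analyze_trace(tr2, ta.fit_fading(ct2))
        assert c1 == c2
        assert p1.max_response == pytest.approx(p2.max_response, rel=1e-9)
        assert p1.t50 == p2.t50 and p1.peak_times == p2.peak_times

    def test_fading_trend_invariance(self):
        tr_flat, ct_flat = self._ap_trace(k=0.0)
        tr_fade, ct_fade = self._ap_trace(k=-8.0)
        p1, c1 = ta.analyze_trace(tr_flat, ta.fit_fading(ct_flat))
        p2, c2 = ta.analyze_trace(tr_fade, ta.fit_fading(ct_fade))
        assert c1 == c2
        assert p1.max_response == pytest.approx(p2.max_response, abs=1e-6)
        assert p1.t50 == p2.t50


class TestBatch:
    def test_all_quiet_batch(self):
        quiet = [(126.0, _trace(100.0 - 5.0 * FRAMES)) for _ in range(5)]
        ctrl = [_trace(100.0 - 5.0 * FRAMES, is_control=True)]
        out = ta.analyze_batch(quiet, ctrl)
        assert list(out["pct_responding"]) == [0.0]
        assert list(out["n_no_response"]) == [5]

    def test_requires_controls(self):
        with pytest.raises(ValueError):
            ta.analyze_batch([(126.0, _trace(np.full(80, 100.0)))], [])


def test_membrane_trace_normalization(rest):
    t = np.arange(0, 2.0, 0.036)
    um = np.full(t.size, rest.Um)
    um[20:] = rest.Um + 0.09  # full-amplitude depolarization
    resp = ta.from_membrane_trace(t, um, rest=rest.Um, pulse_time=t[19])
    assert resp.R[:19] == pytest.approx(0.0)
    assert resp.R[25] == pytest.approx(0.05)
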