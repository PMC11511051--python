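"""SQI statistics, fuzzy comprehensive grading, and the decision workflow."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioqc import Signal
from bioqc.ecg_quality import (DEFAULT_FUZZY_CONFIG, REFERENCE_SCORE,
                               REFERENCE_TRIPLETS, SQITriplet, bassqi,
                               calibrate_bassqi_residual_knot, fuzzy_evaluate,
                               grade_from_v, ksqi, psqi, quality_decision)


def _tone(freq, fs=1000.0, dur=60.0, amp=1.0):
    t = np.arange(0, dur, 1 / fs)
    return Signal(amp * np.sin(2 * np.pi * freq * t), fs)


def _brickwall_white(lo, hi, n=2 ** 17, fs=1000.0, seed=0):
    """White noise with an ideally flat spectrum restricted to [lo, hi] Hz."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    return Signal(np.fft.irfft(spec, n), fs)


class TestKsqi:
    def test_gaussian_kurtosis_is_three(self):
        rng = np.random.default_rng(1)
        sig = Signal(rng.standard_normal(10 ** 6), 1000.0)
        assert ksqi(sig) == pytest.approx(3.0, abs=0.1)

    def test_sine_kurtosis_is_three_halves(self):
        assert ksqi(_tone(10.0)) == pytest.approx(1.5, abs=0.05)

    def test_clean_ecg_exceeds_excellent_threshold(self, filtered_ecg_60bpm):
        filt, _ = filtered_ecg_60bpm
        assert ksqi(filt) > 5.0

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ksqi(Signal(np.ones(2000), 1000.0))

    def test_excess_convention_flag(self):
        rng = np.random.default_rng(2)
        sig = Signal(rng.standard_normal(10 ** 5), 1000.0)
        assert ksqi(sig, excess=True) == pytest.approx(0.0, abs=0.15)


class TestSpectralSQIs:
    def test_pure_tone_in_qrs_band(self):
        sig = _tone(10.0)
        assert psqi(sig) == pytest.approx(1.0, abs=0.01)
        assert bassqi(sig) == pytest.approx(1.0, abs=0.01)

    def test_tone_outside_qrs_band(self):
        assert psqi(_tone(30.0)) == pytest.approx(0.0, abs=0.01)

    def test_baseline_tone(self):
        assert bassqi(_tone(0.5, dur=120.0)) == pytest.approx(0.0, abs=0.01)

    def test_white_noise_band_ratio(self):
        sig = _brickwall_white(0.0, 500.0, seed=3)
        assert psqi(sig) == pytest.approx(10.0 / 35.0, abs=0.02)

    def test_bandlimited_white_noise_bassqi(self):
        sig = _brickwall_white(0.0, 40.0, seed=4)
        assert bassqi(sig) == pytest.approx(1 - 1 / 40, abs=0.01)

    def test_amplitude_scale_invariance(self, filtered_ecg_60bpm):
        filt, _ = filtered_ecg_60bpm
        scaled = filt.replace_samples(filt.samples * 37.5)
        assert psqi(scaled) == pytest.approx(psqi(filt), rel=1e-9)
        assert bassqi(scaled) == pytest.approx(bassqi(filt), rel=1e-9)


class TestFuzzyEvaluate:
    def test_reference_triplets_share_printed_score(self):
        vs = [fuzzy_evaluate(SQITriplet(*t)).v for t in REFERENCE_TRIPLETS]
        for v in vs:
            assert v == pytest.approx(REFERENCE_SCORE, abs=0.02)
        assert max(vs) - min(vs) < 1e-9
        assert all(fuzzy_evaluate(SQITriplet(*t)).grade_name == "Excellent"
                   for t in REFERENCE_TRIPLETS)

    def test_all_bad_triplet_unacceptable(self):
        res = fuzzy_evaluate(SQITriplet(2.0, 0.10, 0.40))
        assert res.grade == "U"

    def test_grade_boundaries_closed_as_printed(self):
        assert grade_from_v(1.50) == "E"
        assert grade_from_v(1.50 + 1e-9) == "B"
        assert grade_from_v(2.40 - 1e-9) == "B"
        assert grade_from_v(2.40) == "U"

    def test_calibration_recovers_frozen_knot(self):
        d = calibrate_bassqi_residual_knot(grid=(1.04, 1.06, 2001))
        assert d == pytest.approx(DEFAULT_FUZZY_CONFIG.bassqi_traps[1][3],
                                  abs=1e-4)

    @settings(deadline=None, max_examples=200)
    @given(k=st.floats(1.0, 20.0), p=st.floats(0.0, 1.0),
           b=st.floats(0.0, 1.0))
    def test_score_range_property(self, k, p, b):
        """v always lies in [1, 3]; the fuzzy vector in [0, 1]^3."""
        res = fuzzy_evaluate(SQITriplet(k, p, b))
        assert 1.0 <= res.v <= 3.0
        assert np.all((res.s >= 0) & (res.s <= 1))

    def test_score_extremes_iff_single_level(self):
        cfg = DEFAULT_FUZZY_CONFIG
        # a perfect triplet cannot reach v=1 with this config because the
        # residual level-2 memberships never vanish; check the identity on
        # the formula instead via a synthetic one-level vector
        res = fuzzy_evaluate(SQITriplet(7.0, 0.67, 0.99))
        assert res.v > 1.0 and res.s[1] > 0
        res_bad = fuzzy_evaluate(SQITriplet(1.0, 0.05, 0.0))
        assert res_bad.v == pytest.approx(3.0, abs=0.05)

    @pytest.mark.parametrize("p,b", [(0.67, 0.99), (0.45, 0.92),
                                     (0.3, 0.5), (0.95, 0.75)])
    def test_ksqi_monotonicity(self, p, b):
        """Improving kSQI toward its excellent region never raises v."""
        ks = np.linspace(1.0, 7.0, 301)
        vs = [fuzzy_evaluate(SQITriplet(k, p, b)).v for k in ks]
        assert all(v2 <= v1 + 1e-10 for v1, v2 in zip(vs, vs[1:]))

    @pytest.mark.parametrize("k,p", [(7.33, 0.67), (4.0, 0.45),
                                     (1.5, 0.05), (5.0, 0.85)])
    def test_bassqi_monotonicity(self, k, p):
        """Improving basSQI toward 1 never raises v."""
        bs = np.linspace(0.0, 1.0, 501)
        vs = [fuzzy_evaluate(SQITriplet(k, p, b)).v for b in bs]
        assert all(v2 <= v1 + 1e-10 for v1, v2 in zip(vs, vs[1:]))

    @pytest.mark.parametrize("k,b", [(7.33, 0.99), (2.0, 0.5)])
    def test_psqi_monotonicity(self, k, b):
        """Moving pSQI toward [0.5, 0.8] from either side never raises v."""
        toward_from_below = [0.05, 0.2, 0.35, 0.42, 0.45, 0.55, 0.65]
        toward_from_above = [0.98, 0.92, 0.85, 0.78, 0.7]
        for seq in (toward_from_below, toward_from_above):
            vs = [fuzzy_evaluate(SQITriplet(k, p, b)).v for p in seq]
            assert all(v2 <= v1 + 1e-10 for v1, v2 in zip(vs, vs[1:]))


class TestQualityDecision:
    @staticmethod
    def _eval(k, p, b):
        t = SQITriplet(k, p, b)
        return fuzzy_evaluate(t), t

    def test_excellent_accepted(self):
        res, t = self._eval(*REFERENCE_TRIPLETS[0])
        assert quality_decision(res, t) == "accept"

    def test_unacceptable_psqi_failure_means_rerecord(self):
        res, t = self._eval(2.0, 0.10, 0.40)
        assert res.grade == "U"
        assert quality_decision(res, t) == "rerecord"

    def test_unacceptable_noise_failure_means_denoise(self):
        # With the calibrated defaults an in-window pSQI anchors enough
        # level-1/2 mass that the grade stops at B, so exercise the routing
        # of a U result with qualifying pSQI directly: noise/artifact
        # failures (kSQI, basSQI) must route to denoising, not re-recording.
        from bioqc.ecg_quality import FuzzyResult
        t = SQITriplet(1.2, 0.6, 0.2)
        forced_u = FuzzyResult(membership=np.zeros((3, 3)),
                               s=np.array([0.0, 0.1, 0.9]), v=2.8, grade="U")
        assert quality_decision(forced_u, t) == "denoise_and_reevaluate"

    def test_barely_acceptable_reassessed_once(self):
        res, t = self._eval(6.0, 0.3, 0.99)
        assert res.grade == "B"
        assert quality_decision(res, t) == "reassess"
        # persisting on the rerun: handled by the U rules (pSQI fails here)
        assert quality_decision(res, t, rerun=True) == "rerecord"

    def test_rerun_with_qualifying_psqi_goes_to_denoise(self):
        res, t = self._eval(2.0, 0.6, 0.5)
        assert res.grade == "B"
        assert quality_decision(res, t, rerun=True) == "denoise_and_reevaluate"
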