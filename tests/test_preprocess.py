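import numpy as np
import pytest

from macross import (
    AngleTrace,
    ConfigurationError,
    DataError,
    Recording,
    TrialRecord,
    band_power_course,
    bandpass,
    detect_movement_onset,
    detrend_epoch,
    epoch_trials,
    fit_baseline,
)

from conftest import make_epoch

RATE = 300.0


def trial(prep_onset, label="cue_go", index=0):
    return TrialRecord(index=index, prep_onset=prep_onset, cue_label=label,
                       cue_onset=prep_onset + 2.0)


class TestEpochTrials:
    def test_default_window_yields_11s_epoch(self):
        rec = Recording(samples=np.zeros(6000), rate=RATE)
        eps = epoch_trials(rec, [trial(8.0)])
        assert len(eps) == 1
        assert len(eps[0]) == 3300
        assert eps[0].rel_times[0] == pytest.approx(-6.0, abs=1 / RATE)

    def test_out_of_bounds_trial_dropped(self):
        rec = Recording(samples=np.zeros(6000), rate=RATE)
        eps = epoch_trials(rec, [trial(3.0)])
        assert eps == []

    def test_nogo_skipped_unless_requested(self):
        rec = Recording(samples=np.zeros(9000), rate=RATE)
        trials = [trial(8.0), trial(22.0, label="cue_nogo", index=1)]
        assert len(epoch_trials(rec, trials)) == 1
        assert len(epoch_trials(rec, trials, include_nogo=True)) == 2

    def test_window_must_straddle_zero(self):
        rec = Recording(samples=np.zeros(6000), rate=RATE)
        with pytest.raises(ConfigurationError):
            epoch_trials(rec, [trial(8.0)], window=(1.0, 5.0))


class TestBaselineFit:
    def test_exact_line_recovered(self):
        ep = make_epoch(2.0 + 3.0 * (-6.0 + np.arange(3300) / RATE))
        fit = fit_baseline(ep)
        assert fit.slope == pytest.approx(3.0, abs=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_baseline(self):
        fit = fit_baseline(make_epoch(np.zeros(3300)))
        assert fit.slope == 0.0 and fit.intercept == 0.0

    def test_matches_closed_form_ols(self):
        # independent oracle: slope = cov(t, y) / var(t)
        rng = np.random.default_rng(7)
        t = -6.0 + np.arange(3300) / RATE
        y = 1.5 - 0.8 * t + rng.normal(0, 2.0, size=3300)
        ep = make_epoch(y)
        fit = fit_baseline(ep)
        mask = t < 0
        tb, yb = t[mask], y[mask]
        slope = np.sum((tb - tb.mean()) * (yb - yb.mean())) / np.sum(
            (tb - tb.mean()) ** 2)
        intercept = yb.mean() - slope * tb.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        # seeded noise: recovered slope within 3 standard errors of truth
        resid = yb - (intercept + slope * tb)
        se = np.sqrt(np.sum(resid**2) / (len(tb) - 2)
                     / np.sum((tb - tb.mean()) ** 2))
        assert abs(fit.slope - (-0.8)) < 3 * se

    def test_too_few_baseline_samples(self):
        ep = make_epoch(np.zeros(33), start=-0.01, end=0.1, rate=RATE)
        with pytest.raises(DataError):
            fit_baseline(ep)


class TestDetrend:
    def test_pure_line_detrends_to_zero(self):
        t = -6.0 + np.arange(3300) / RATE
        ep = make_epoch(4.0 - 1.5 * t)
        out = detrend_epoch(ep, fit_baseline(ep))
        assert np.max(np.abs(out.samples)) < 1e-9

    def test_detrended_baseline_mean_vanishes(self):
        t = -6.0 + np.arange(3300) / RATE
        ep = make_epoch(-2.0 + 0.7 * t)
        out = detrend_epoch(ep, fit_baseline(ep))
        assert abs(np.mean(out.samples[out.baseline_mask])) < 1e-6

    def test_idempotent_in_noiseless_case(self):
        t = -6.0 + np.arange(3300) / RATE
        ep = make_epoch(1.0 + 2.0 * t)
        once = detrend_epoch(ep, fit_baseline(ep))
        twice = detrend_epoch(once, fit_baseline(once))
        assert np.allclose(once.samples, twice.samples, atol=1e-9)

    def test_preserves_count_and_timebase(self, flat_epoch):
        out = detrend_epoch(flat_epoch, fit_baseline(flat_epoch))
        assert len(out) == len(flat_epoch)
        assert np.array_equal(out.rel_times, flat_epoch.rel_times)


class TestBandpass:
    def _tone(self, hz):
        t = np.arange(3300) / RATE
        return make_epoch(np.sin(2 * np.pi * hz * t))

    def test_stopband_tone_suppressed(self):
        out = bandpass(self._tone(10.0), 0.5, 5.0)
        core = out.samples[300:-300]  # avoid filter edges
        assert np.sqrt(np.mean(core**2)) < 0.05 * np.sqrt(0.5)

    def test_passband_tone_preserved(self):
        out = bandpass(self._tone(2.0), 0.5, 5.0)
        core = out.samples[300:-300]
        assert np.sqrt(np.mean(core**2)) == pytest.approx(np.sqrt(0.5),
                                                          rel=0.10)

    def test_dc_removed(self):
        out = bandpass(make_epoch(np.full(3300, 7.0)), 0.5, 5.0)
        assert np.max(np.abs(out.samples[300:-300])) < 1e-3

    def test_invalid_band(self, flat_epoch):
        with pytest.raises(ConfigurationError):
            bandpass(flat_epoch, 5.0, 0.5)
        with pytest.raises(ConfigurationError):
            bandpass(flat_epoch, 1.0, 200.0)


class TestBandPowerCourse:
    def _alpha_epoch(self, movement_gain=1.0):
        t = -6.0 + np.arange(3300) / RATE
        amp = np.where((t > 2.0) & (t < 4.0), movement_gain, 1.0)
        return make_epoch(4.0 * amp * np.sin(2 * np.pi * 10.0 * t))

    def test_stationary_signal_is_flat(self):
        course = band_power_course(self._alpha_epoch(1.0))
        assert np.max(np.abs(course.erd_percent)) < 5.0

    def test_halved_amplitude_gives_minus_75(self):
        course = band_power_course(self._alpha_epoch(0.5))
        mid = (course.times > 2.3) & (course.times < 3.7)
        assert np.mean(course.erd_percent[mid]) == pytest.approx(-75.0,
                                                                 abs=10.0)

    def test_out_of_band_tone_leaks_little(self):
        base = band_power_course(self._alpha_epoch(1.0))
        t = -6.0 + np.arange(3300) / RATE
        ep = make_epoch(self._alpha_epoch(1.0).samples
                        + 4.0 * np.sin(2 * np.pi * 25.0 * t))
        with_tone = band_power_course(ep)
        assert np.max(np.abs(with_tone.erd_percent - base.erd_percent)) < 5.0

    def test_window_too_short_for_band(self, flat_epoch):
        with pytest.raises(ConfigurationError):
            band_power_course(flat_epoch, band=(8.0, 13.0), window_s=0.2)


class TestMovementOnset:
    def _ramp_trace(self, corner, rate=RATE, n=3000, slope=20.0, shift=0.0):
        t = np.arange(n) / rate + shift
        ang = np.clip(t - (corner + shift), 0.0, None) * slope
        return AngleTrace(samples=ang, rate=rate, start_time=shift)

    def test_flat_trace_has_no_onset(self):
        trace = AngleTrace(samples=np.zeros(3000), rate=RATE)
        mo = detect_movement_onset(trace, cue_onset=2.0, search_end=8.0)
        assert not mo.present

    def test_ramp_onset_recovered(self):
        trace = self._ramp_trace(corner=3.4)
        mo = detect_movement_onset(trace, cue_onset=3.0, search_end=8.0)
        # first supra-threshold velocity sample sits within one sample of
        # the corner; the hold only delays confirmation, not the onset
        assert 0.4 - 1.5 / RATE <= (mo.time - 3.0) <= 0.4 + 0.1

    def test_movement_before_cue_ignored(self):
        trace = self._ramp_trace(corner=1.0)
        # ramp plateaus long before the search window opens
        flat_after = np.minimum(trace.samples, 5.0)
        trace = AngleTrace(samples=flat_after, rate=RATE)
        mo = detect_movement_onset(trace, cue_onset=6.0, search_end=9.0)
        assert not mo.present

    @pytest.mark.parametrize("shift", [0.0, 3.7, -1.25])
    def test_translation_equivariance(self, shift):
        base = detect_movement_onset(self._ramp_trace(3.4),
                                     cue_onset=3.0, search_end=8.0)
        moved = detect_movement_onset(self._ramp_trace(3.4, shift=shift),
                                      cue_onset=3.0 + shift,
                                      search_end=8.0 + shift)
        assert moved.time == pytest.approx(base.time + shift, abs=1e-9)

    def test_empty_search_window(self):
        trace = AngleTrace(samples=np.zeros(3000), rate=RATE)
        with pytest.raises(ConfigurationError):
            detect_movement_onset(trace, cue_onset=5.0, search_end=5.0)
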