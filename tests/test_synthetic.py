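import numpy as np
import pytest

from macross import (
    ERDModel,
    MRCPModel,
    NoiseModel,
    ParadigmConfig,
    ReactionModel,
    detect_movement_onset,
    make_angle_trace,
    make_erd_oscillation,
    make_mrcp_waveform,
    make_pink_noise,
    segment_trials,
    simulate_session,
)
from macross.errors import ConfigurationError

RATE = 300.0


class TestPinkNoise:
    def test_zero_sd_is_silent(self):
        assert np.all(make_pink_noise(1000, RATE,
                                      NoiseModel(noise_sd_uv=0.0),
                                      seed=1) == 0)

    def test_seed_reproducible(self):
        a = make_pink_noise(5000, RATE, seed=42)
        b = make_pink_noise(5000, RATE, seed=42)
        assert np.array_equal(a, b)

    def test_exponent_zero_matches_white_variance(self):
        x = make_pink_noise(100_000, RATE,
                            NoiseModel(pink_exponent=0.0, noise_sd_uv=2.0),
                            seed=9)
        assert np.var(x) == pytest.approx(4.0, rel=0.10)

    def test_pink_spectrum_slopes_down(self):
        x = make_pink_noise(60_000, RATE, NoiseModel(pink_exponent=1.0),
                            seed=3)
        f = np.fft.rfftfreq(len(x), 1 / RATE)
        p = np.abs(np.fft.rfft(x)) ** 2
        band = lambda lo, hi: p[(f >= lo) & (f < hi)].mean()
        assert band(1.0, 3.0) > 5 * band(30.0, 90.0)


class TestMRCPWaveform:
    def test_knot_values(self):
        model = MRCPModel()
        mv = 3.0
        w = make_mrcp_waveform(RATE, model, movement_rel_s=mv,
                               duration_s=6.0)
        t = np.arange(len(w)) / RATE
        at = lambda s: w[int(round(s * RATE))]
        assert at(mv - model.early_onset_s) == pytest.approx(0.0, abs=0.05)
        assert at(mv) == pytest.approx(model.trough_amp_uv, abs=0.05)
        assert t[np.argmin(w)] == pytest.approx(mv, abs=2 / RATE)

    def test_steep_segment_steeper_than_early(self):
        model = MRCPModel()
        w = make_mrcp_waveform(RATE, model, movement_rel_s=3.0,
                               duration_s=6.0)
        slope = np.gradient(w, 1 / RATE)
        early = slice(int(1.6 * RATE), int(2.5 * RATE))
        steep = slice(int(2.6 * RATE), int(2.99 * RATE))
        assert np.abs(slope[steep]).mean() > 2 * np.abs(slope[early]).mean()

    def test_reversal_is_sharp(self):
        # the post-trough upstroke must be steeper than the descent so the
        # fast average can catch the slow one promptly
        model = MRCPModel()
        w = make_mrcp_waveform(RATE, model, movement_rel_s=3.0,
                               duration_s=6.0)
        slope = np.gradient(w, 1 / RATE)
        i0 = int(3.0 * RATE)
        assert slope[i0 + 3] > abs(slope[i0 - 5])


class TestERDOscillation:
    def test_zero_attenuation_is_stationary(self):
        x = make_erd_oscillation(RATE, ERDModel(attenuation_frac=0.0),
                                 movement_rel_s=5.0, duration_s=10.0,
                                 seed=4)
        first, second = x[:1500], x[1500:3000]
        assert np.std(second) == pytest.approx(np.std(first), rel=0.35)

    def test_band_power_drop_matches_attenuation(self):
        # long suppressed/baseline spans and a few realizations keep the
        # power-ratio estimate well inside the analytic tolerance
        model = ERDModel(attenuation_frac=0.5, erd_onset_s=6.0,
                         recovery_s=6.0)
        ratios = []
        for seed in (8, 9, 10):
            x = make_erd_oscillation(RATE, model, movement_rel_s=24.0,
                                     duration_s=32.0, seed=seed)
            t = np.arange(len(x)) / RATE
            base = x[(t > 1.0) & (t < 17.0)]
            drop = x[(t > 18.5) & (t < 29.5)]
            ratios.append(np.mean(drop**2) / np.mean(base**2))
        assert np.mean(ratios) == pytest.approx((1 - 0.5) ** 2, rel=0.15)

    def test_seed_reproducible(self):
        a = make_erd_oscillation(RATE, seed=5, duration_s=3.0)
        b = make_erd_oscillation(RATE, seed=5, duration_s=3.0)
        assert np.array_equal(a, b)


class TestAngleTrace:
    @pytest.mark.parametrize("rt", [0.15, 0.4, 0.8, 1.2, 1.5])
    def test_noiseless_onset_recovered_within_50ms(self, rt):
        cue = 2.0
        trace = make_angle_trace(RATE, onset_s=cue + rt, noise_sd_deg=0.0,
                                 duration_s=cue + rt + 2.0, seed=0)
        mo = detect_movement_onset(trace, cue_onset=cue,
                                   search_end=cue + 1.6)
        assert mo.present
        assert abs(mo.time - (cue + rt)) < 0.050

    def test_zero_amplitude_never_detected(self):
        trace = make_angle_trace(RATE, onset_s=2.5, amplitude_deg=0.0,
                                 noise_sd_deg=0.0, duration_s=6.0, seed=0)
        mo = detect_movement_onset(trace, cue_onset=2.0, search_end=4.0)
        assert not mo.present

    def test_pre_onset_stays_within_noise_band(self):
        trace = make_angle_trace(RATE, onset_s=5.0, noise_sd_deg=0.2,
                                 duration_s=8.0, seed=6)
        pre = trace.samples[:int(4.5 * RATE)]
        assert np.max(np.abs(pre)) <= 3 * 0.2 * 1.5  # 3 sd + band margin


class TestSimulateSession:
    def test_trial_phase_durations(self):
        session = simulate_session(ParadigmConfig(n_go_trials=5, seed=2))
        evs = list(session.events)
        rests = [t for lbl, t in evs if lbl == "rest_start"]
        preps = [t for lbl, t in evs if lbl == "prep_start"]
        cues = [t for lbl, t in evs if lbl in ("cue_go", "cue_nogo")]
        feeds = [t for lbl, t in evs if lbl == "feedback_start"]
        assert len(session.events.of_label("cue_go")) == 5
        tol = 1 / 300.0
        for r, p, c, f in zip(rests, preps, cues, feeds):
            assert p - r == pytest.approx(8.0, abs=tol)
            assert c - p == pytest.approx(2.0, abs=tol)
            assert f - c == pytest.approx(3.0, abs=tol)

    def test_rest_period_is_pure_carrier_when_noiseless(self):
        session = simulate_session(
            ParadigmConfig(n_go_trials=3, seed=7),
            erd=ERDModel(attenuation_frac=0.0),
            noise=NoiseModel(noise_sd_uv=0.0),
        )
        # during rest the only content is the band-limited carrier: no
        # power outside the alpha band, and no MRCP trend
        rest = session.recording.samples[int(1.0 * RATE):int(7.0 * RATE)]
        f = np.fft.rfftfreq(len(rest), 1 / RATE)
        p = np.abs(np.fft.rfft(rest - rest.mean())) ** 2
        in_band = p[(f >= 7.0) & (f <= 14.0)].sum()
        out_band = p[(f < 6.0) | (f > 16.0)].sum()
        assert out_band < 0.01 * in_band

    def test_ground_truth_onsets_obey_reaction_bounds(self):
        session = simulate_session(ParadigmConfig(n_go_trials=10, seed=1))
        rm = ReactionModel()
        for tr in session.truth.trials:
            rt = tr.movement_onset_s - tr.cue_onset_s
            assert rm.min_s <= rt <= rm.max_s

    def test_seed_determinism(self):
        a = simulate_session(ParadigmConfig(n_go_trials=3, seed=13))
        b = simulate_session(ParadigmConfig(n_go_trials=3, seed=13))
        assert np.array_equal(a.recording.samples, b.recording.samples)
        assert np.array_equal(a.angle.samples, b.angle.samples)
        assert a.events.events == b.events.events
        assert a.truth == b.truth

    def test_nogo_fraction_near_quarter(self):
        session = simulate_session(ParadigmConfig(n_go_trials=150, seed=21))
        trials = segment_trials(session.events)
        frac = sum(not tr.is_go for tr in trials) / len(trials)
        # binomial 4-sigma band around 0.25 at ~200 trials
        assert 0.13 <= frac <= 0.37

    def test_invalid_nogo_prob_rejected(self):
        with pytest.raises(ConfigurationError):
            ParadigmConfig(nogo_prob=1.5)
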