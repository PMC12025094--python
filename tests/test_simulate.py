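import numpy as np
import pytest
from scipy.signal import find_peaks

from gaitbbs.data_io import RIGHT_GZ
from gaitbbs.errors import ConfigError, RangeError
from gaitbbs.preprocessing import PreprocessConfig, build_dataset, detect_trigger
from gaitbbs.simulate import (
    SimConfig,
    gait_waveform,
    read_cohort,
    simulate_cohort,
    simulate_subject,
    simulate_subjects,
    stride_phase,
    write_cohort,
)


def _interval_cv(signal, fs=100.0, cycle=1.6):
    # one dominant crest per stride: same height rule as trigger detection
    peaks, _ = find_peaks(signal, distance=int(0.7 * cycle * fs),
                          height=0.5 * signal.max())
    intervals = np.diff(peaks)
    return intervals.std() / intervals.mean()


class TestGaitWaveform:
    def test_clean_max_score_signal_has_exact_cycle_period(self):
        cfg = SimConfig(duration_seconds=30.0, stride_cv_at_56=0.0,
                        asymmetry_at_56=0.0, noise_sd=0.0)
        t = np.arange(3000) / 100.0
        x = gait_waveform(56.0, RIGHT_GZ, t, cfg, np.random.default_rng(0))
        # autocorrelation peaks at one gait cycle = 1.6 s = 160 samples
        lags = np.arange(40, 320)
        ac = [np.dot(x[:-l], x[l:]) for l in lags]
        assert lags[int(np.argmax(ac))] == 160

    def test_stride_variability_larger_at_low_score(self):
        cfg = SimConfig(duration_seconds=120.0, noise_sd=0.0, tremor_amp_at_0=0.0)
        t = np.arange(12000) / 100.0
        cv_low = _interval_cv(gait_waveform(0.0, RIGHT_GZ, t, cfg,
                                            np.random.default_rng(42)))
        cv_high = _interval_cv(gait_waveform(56.0, RIGHT_GZ, t, cfg,
                                             np.random.default_rng(42)))
        assert cv_low > cv_high

    def test_stride_cv_non_increasing_across_scores(self):
        cfg = SimConfig(duration_seconds=160.0, noise_sd=0.0, tremor_amp_at_0=0.0)
        t = np.arange(16000) / 100.0
        cvs = [_interval_cv(gait_waveform(s, RIGHT_GZ, t, cfg,
                                          np.random.default_rng(7)))
               for s in (0.0, 14.0, 28.0, 42.0, 56.0)]
        assert all(a >= b - 1e-9 for a, b in zip(cvs, cvs[1:]))

    def test_left_right_asymmetry_non_increasing_in_score(self):
        cfg = SimConfig(duration_seconds=60.0, noise_sd=0.0, tremor_amp_at_0=0.0)
        ratios = []
        for s in (0.0, 14.0, 28.0, 42.0, 56.0):
            sub = simulate_subject(s, SimConfig(duration_seconds=60.0, noise_sd=0.0,
                                                tremor_amp_at_0=0.0,
                                                score_range=(0, 56)),
                                   np.random.default_rng(3))
            left = sub.recording.walking[:, 5] - sub.recording.walking[:, 5].mean()
            right = sub.recording.walking[:, 11] - sub.recording.walking[:, 11].mean()
            ratios.append(np.sqrt((left ** 2).mean() / (right ** 2).mean()))
        assert all(a >= b - 1e-9 for a, b in zip(ratios, ratios[1:]))

    def test_tremor_band_power_larger_at_low_score(self):
        cfg = SimConfig(duration_seconds=60.0, noise_sd=0.0, score_range=(0, 56))
        rng_lo, rng_hi = np.random.default_rng(5), np.random.default_rng(5)
        t = np.arange(6000) / 100.0
        for score, rng in ((10.0, rng_lo), (56.0, rng_hi)):
            x = gait_waveform(score, 0, t, cfg, rng)
            f = np.fft.rfftfreq(len(x), 1 / 100.0)
            p = np.abs(np.fft.rfft(x)) ** 2
            band = p[(f >= 3.8) & (f <= 6.2)].sum()
            if score == 10.0:
                band_low = band
        assert band_low > 10 * band

    def test_same_seed_same_signal(self):
        cfg = SimConfig(duration_seconds=10.0)
        t = np.arange(1000) / 100.0
        a = gait_waveform(40.0, 3, t, cfg, np.random.default_rng(9))
        b = gait_waveform(40.0, 3, t, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestStridePhase:
    def test_phase_is_monotone_and_spans_strides(self):
        cfg = SimConfig(duration_seconds=30.0)
        t = np.arange(3000) / 100.0
        phase = stride_phase(t, 56.0, cfg, np.random.default_rng(0))
        assert np.all(np.diff(phase) > 0)
        assert phase[-1] == pytest.approx(t[-1] / cfg.cycle_seconds, rel=0.1)


class TestSimulateSubject:
    def test_default_shapes(self):
        sub = simulate_subject(50.0, SimConfig(), np.random.default_rng(0))
        assert sub.recording.walking.shape == (30000, 12)
        assert sub.recording.static.shape == (1000, 12)

    def test_static_channels_have_positive_sd(self):
        sub = simulate_subject(40.0, SimConfig(duration_seconds=20.0),
                               np.random.default_rng(1))
        assert np.all(sub.recording.static.std(axis=0) > 0)

    def test_trigger_detectable_on_gz(self):
        sub = simulate_subject(45.0, SimConfig(duration_seconds=20.0),
                               np.random.default_rng(2))
        idx = detect_trigger(sub.recording.walking, PreprocessConfig())
        assert 0 <= idx < 400  # within the first couple of strides

    def test_full_pipeline_yields_120_segments(self):
        sub = simulate_subject(50.0, SimConfig(), np.random.default_rng(3))
        ds = build_dataset([sub.recording], [sub.label], PreprocessConfig())
        assert len(ds) == 120
        assert ds.X.shape == (120, 200, 12)

    def test_score_outside_range_rejected(self):
        with pytest.raises(RangeError):
            simulate_subject(10.0, SimConfig(score_range=(30, 56)),
                             np.random.default_rng(0))


class TestCohorts:
    def test_reference_cohort_composition(self):
        cfg = SimConfig(duration_seconds=4.0, static_seconds=10.0, score_range=(0, 56))
        subs = simulate_cohort(cfg=cfg, seed=0)
        assert len(subs) == 40
        counts = {}
        for s in subs:
            counts[s.label.group] = counts.get(s.label.group, 0) + 1
        assert counts == {"young_hc": 12, "elderly_hc": 8, "pd": 8, "stroke": 12}
        assert all(0 <= s.label.bbs_score <= 56 for s in subs)

    def test_cohort_is_deterministic(self):
        cfg = SimConfig(duration_seconds=4.0, score_range=(0, 56))
        a = simulate_cohort(cfg=cfg, seed=4)
        b = simulate_cohort(cfg=cfg, seed=4)
        assert [s.label.bbs_score for s in a] == [s.label.bbs_score for s in b]
        np.testing.assert_array_equal(a[0].recording.walking, b[0].recording.walking)

    def test_uniform_draw_respects_score_range(self):
        subs = simulate_subjects(20, SimConfig(duration_seconds=4.0,
                                               score_range=(30, 56)), seed=1)
        assert all(30 <= s.label.bbs_score <= 56 for s in subs)

    def test_cohort_round_trip_through_csv(self, tmp_path):
        cfg = SimConfig(duration_seconds=4.0)
        subs = simulate_subjects(2, cfg, seed=2)
        write_cohort(subs, tmp_path / "cohort", cfg=cfg)
        recs, labels = read_cohort(tmp_path / "cohort")
        assert len(recs) == 2
        np.testing.assert_allclose(recs[0].walking, subs[0].recording.walking,
                                   atol=1e-9)
        assert labels[0].bbs_score == subs[0].label.bbs_score


class TestSimConfigValidation:
    def test_bad_cycle_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(cycle_seconds=0.0)

    def test_bad_score_range_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(score_range=(40, 30))
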