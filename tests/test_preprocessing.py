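import numpy as np
import pytest

from gaitbbs.data_io import ImuRecording, SubjectLabel
from gaitbbs.errors import (
    ConfigError,
    DegenerateBaselineError,
    LengthError,
    MissingLabelError,
    RangeError,
    TooShortError,
    TriggerNotFoundError,
)
from gaitbbs.preprocessing import (
    PreprocessConfig,
    build_dataset,
    denormalize_score,
    detect_trigger,
    lowpass_filter,
    normalize_score,
    segment_matrix,
    standardize,
    truncate_and_segment,
)

FS = 100.0


def _sine(freq, seconds=10.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, 12))


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        x = np.full((500, 12), 3.7)
        np.testing.assert_allclose(lowpass_filter(x, FS), x, atol=1e-6)

    def test_stopband_sinusoid_is_attenuated(self):
        x = _sine(40.0)
        y = lowpass_filter(x, FS)
        assert np.sqrt((y ** 2).mean()) < 0.05 * np.sqrt((x ** 2).mean())

    def test_passband_sinusoid_is_preserved(self):
        x = _sine(2.0)
        y = lowpass_filter(x, FS)
        ratio = np.sqrt((y ** 2).mean()) / np.sqrt((x ** 2).mean())
        assert abs(ratio - 1.0) < 0.02

    def test_zero_phase_no_lag(self):
        # cross-correlation of filtered vs clean passband sinusoid peaks at lag 0
        x = _sine(2.0)[:, 0]
        y = lowpass_filter(x[:, None].repeat(12, 1), FS)[:, 0]
        lags = np.arange(-20, 21)
        xc = [np.dot(np.roll(y, l)[50:-50], x[50:-50]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_shape_preserved(self, rng):
        x = rng.normal(size=(333, 12))
        assert lowpass_filter(x, FS).shape == x.shape

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            lowpass_filter(np.zeros((100, 12)), FS, PreprocessConfig(cutoff_hz=50.0))

    def test_too_short_signal_rejected(self):
        with pytest.raises(LengthError):
            lowpass_filter(np.zeros((10, 12)), FS)


class TestStandardize:
    def test_self_standardization(self, rng):
        static = rng.normal(2.0, 1.5, size=(1000, 12))
        out = standardize(static, static)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_unit_baseline_is_identity(self, rng):
        walking = rng.normal(size=(500, 12))
        static = rng.normal(size=(100000, 12))
        static = (static - static.mean(axis=0)) / static.std(axis=0)
        np.testing.assert_allclose(standardize(walking, static), walking, atol=1e-9)

    def test_hand_case(self):
        walking = np.full((10, 12), 5.0)
        static = np.zeros((4, 12))
        static[:2] = -1.0
        static[2:] = 3.0  # mean 1, sd 2 per channel
        out = standardize(walking, static)
        np.testing.assert_allclose(out, 2.0)

    def test_degenerate_baseline_rejected(self, rng):
        static = np.ones((100, 12))
        with pytest.raises(DegenerateBaselineError):
            standardize(rng.normal(size=(100, 12)), static)


class TestScoreNormalization:
    @pytest.mark.parametrize("s,expected", [(56, 1.0), (0, 0.0), (42, 0.75)])
    def test_known_values(self, s, expected):
        assert normalize_score(s) == expected

    def test_round_trip_exact_on_all_integers(self):
        for s in range(57):
            assert denormalize_score(normalize_score(s)) == s

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            normalize_score(57)

    def test_denormalize_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert denormalize_score(1.07) == 56.0
        assert denormalize_score(1.0) == 56.0
        assert denormalize_score(0.5) == 28.0


class TestDetectTrigger:
    def test_first_crest_of_slow_sinusoid(self):
        t = np.arange(500) / FS
        x = np.zeros((500, 12))
        x[:, 11] = np.sin(2 * np.pi * 0.625 * t)  # first crest at t = 0.4 s
        assert detect_trigger(x) == 40

    def test_monotone_ramp_has_no_trigger(self):
        x = np.tile(np.linspace(0, 1, 300)[:, None], (1, 12))
        with pytest.raises(TriggerNotFoundError):
            detect_trigger(x)

    def test_sub_threshold_crest_is_skipped(self):
        x = np.zeros((400, 12))
        t = np.arange(400)
        x[:, 11] = 0.3 * np.exp(-0.5 * ((t - 100) / 10.0) ** 2) \
            + 1.0 * np.exp(-0.5 * ((t - 300) / 10.0) ** 2)
        assert abs(detect_trigger(x) - 300) <= 1


class TestSegmentation:
    def test_five_minute_recording_gives_120_segments(self, rng):
        x = rng.normal(size=(30000, 12))
        segs = segment_matrix(x, FS, PreprocessConfig(), "s00")
        assert len(segs) == 120
        assert all(s.values.shape == (200, 12) for s in segs)

    def test_exactly_one_window(self, rng):
        x = rng.normal(size=(200, 12))
        segs = segment_matrix(x, FS, PreprocessConfig(end_trim_seconds=0.0))
        assert len(segs) == 1

    def test_below_one_window_fails(self, rng):
        x = rng.normal(size=(199, 12))
        with pytest.raises(TooShortError):
            segment_matrix(x, FS, PreprocessConfig(end_trim_seconds=0.0))

    @pytest.mark.parametrize("n", [200, 399, 400, 1234, 5000])
    def test_count_is_floor_of_truncated_length(self, rng, n):
        x = rng.normal(size=(n, 12))
        segs = segment_matrix(x, FS, PreprocessConfig(end_trim_seconds=0.0))
        assert len(segs) == n // 200

    def test_trigger_policy_starts_at_peak(self):
        t = np.arange(3000) / FS
        x = np.zeros((3000, 12))
        x[:, 11] = np.sin(2 * np.pi * 0.625 * t)
        cfg = PreprocessConfig(trim_policy="trigger_plus_fixed", end_trim_seconds=0.0)
        segs = segment_matrix(x, FS, cfg)
        # trigger at sample 40, 2960 samples remain -> 14 windows
        assert len(segs) == 14
        np.testing.assert_allclose(segs[0].values[:, 11], x[40:240, 11])

    def test_overlapping_stride(self, rng):
        x = rng.normal(size=(600, 12))
        cfg = PreprocessConfig(end_trim_seconds=0.0, stride_seconds=1.0)
        segs = segment_matrix(x, FS, cfg)
        assert len(segs) == (600 - 200) // 100 + 1

    def test_truncate_and_segment_uses_recording(self, rng):
        rec = ImuRecording("s9", rng.normal(size=(1000, 12)),
                           rng.normal(size=(1000, 12)))
        segs = truncate_and_segment(rec, PreprocessConfig(end_trim_seconds=1.0))
        assert len(segs) == (1000 - 200) // 200
        assert segs[0].subject_id == "s9"


class TestBuildDataset:
    def _recording(self, rng, sid, n=1000):
        return ImuRecording(sid, rng.normal(size=(n, 12)),
                            rng.normal(0, 0.05, size=(1000, 12)))

    def test_perfect_score_labels_every_window_one(self, rng):
        rec = self._recording(rng, "s00")
        ds = build_dataset([rec], [SubjectLabel("s00", 56)],
                           PreprocessConfig(end_trim_seconds=0.0))
        assert len(ds) == 5
        np.testing.assert_allclose(ds.y, 1.0)

    def test_missing_label_is_join_error(self, rng):
        rec = self._recording(rng, "s00")
        with pytest.raises(MissingLabelError):
            build_dataset([rec], [SubjectLabel("other", 10)], PreprocessConfig())

    def test_label_multiset_matches_segment_counts(self, rng):
        recs = [self._recording(rng, "a", 1000), self._recording(rng, "b", 1400)]
        labels = [SubjectLabel("a", 28), SubjectLabel("b", 42)]
        ds = build_dataset(recs, labels, PreprocessConfig(end_trim_seconds=0.0))
        counts = ds.manifest["segments_per_subject"]
        assert counts == {"a": 5, "b": 7}
        assert sorted(ds.y) == sorted([0.5] * 5 + [0.75] * 7)
        assert ds.X.shape == (12, 200, 12)

    def test_dataset_save_load_round_trip(self, rng, tmp_path):
        rec = self._recording(rng, "s00")
        ds = build_dataset([rec], [SubjectLabel("s00", 40, "pd")],
                           PreprocessConfig(end_trim_seconds=0.0))
        ds.save(tmp_path / "ds")
        from gaitbbs.preprocessing import GaitDataset
        back = GaitDataset.load(tmp_path / "ds")
        np.testing.assert_allclose(back.X, ds.X)
        np.testing.assert_allclose(back.y, ds.y)
        assert back.manifest["segments_per_subject"] == {"s00": 5}
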