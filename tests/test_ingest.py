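"""Ingest: filename metadata, resampling, rain screening, 12-s segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile

from soundscape_ae import (
    Recording,
    load_recording,
    parse_aru_filename,
    rain_filter,
    segment_recording,
)
from soundscape_ae.ingest import (
    SEGMENT_SAMPLES,
    TARGET_RATE,
    MetadataError,
    build_segment_index,
)


def _write_wav(path, wave, rate, stereo=False):
    pcm = np.round(np.clip(wave, -1, 1) * 32767).astype(np.int16)
    if stereo:
        pcm = np.stack([pcm, pcm], axis=1)
    wavfile.write(str(path), rate, pcm)
    return path


def _recording(n_samples=5 * SEGMENT_SAMPLES, hour=6):
    from datetime import datetime

    return Recording(
        path="JAG01_20180511_063000.wav",
        recorder_id="JAG01",
        timestamp=datetime(2018, 5, 11, hour, 30, 0),
        cover_label="forest",
        sample_rate=TARGET_RATE,
        n_samples=n_samples,
    )


class TestMetadata:
    def test_aru_filename_parses(self):
        rec_id, ts = parse_aru_filename("JAG01_20180511_063000.wav")
        assert rec_id == "JAG01"
        assert (ts.year, ts.month, ts.day, ts.hour) == (2018, 5, 11, 6)

    @pytest.mark.parametrize("bad", ["whatever.wav", "A_B_C.wav", "JAG01_20181399_256100.wav"])
    def test_unparseable_filename_raises(self, bad):
        with pytest.raises(MetadataError):
            parse_aru_filename(bad)


class TestLoadRecording:
    def test_resamples_44100_to_22050(self, tmp_path):
        rng = np.random.default_rng(0)
        path = _write_wav(tmp_path / "JAG01_20180511_063000.wav",
                          0.1 * rng.standard_normal(60 * 44_100), 44_100)
        rec, wave = load_recording(path)
        assert rec.sample_rate == TARGET_RATE
        assert abs(len(wave) - 60 * TARGET_RATE) <= 1
        assert rec.recorder_id == "JAG01" and rec.hour == 6

    def test_stereo_identical_channels_match_mono(self, tmp_path):
        rng = np.random.default_rng(1)
        sig = 0.1 * rng.standard_normal(TARGET_RATE)
        mono = _write_wav(tmp_path / "REC01_20240101_000000.wav", sig, TARGET_RATE)
        stereo = _write_wav(tmp_path / "REC02_20240101_000000.wav", sig, TARGET_RATE, stereo=True)
        _, w_mono = load_recording(mono)
        _, w_stereo = load_recording(stereo)
        np.testing.assert_allclose(w_mono, w_stereo, atol=1e-12)

    def test_unreadable_file_raises_ioerror(self, tmp_path):
        bad = tmp_path / "REC01_20240101_000000.wav"
        bad.write_bytes(b"not a wav at all")
        with pytest.raises(IOError):
            load_recording(bad)

    def test_manifest_row_overrides_filename(self, tmp_path):
        path = _write_wav(tmp_path / "X_20200101_000000.wav", np.zeros(100), TARGET_RATE)
        rec, _ = load_recording(path, manifest_row={
            "recorder_id": "REC09", "timestamp_iso": "2018-05-11T06:30:00", "cover_label": "forest",
        })
        assert rec.recorder_id == "REC09" and rec.hour == 6 and rec.cover_label == "forest"


class TestRainFilter:
    def test_zero_signal_kept_with_sentinel_score(self):
        keep, score = rain_filter(np.zeros(1000), TARGET_RATE, threshold_db=-60)
        assert keep and score == float("-inf")

    def test_broadband_noise_scores_above_tone_at_equal_rms(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(12 * TARGET_RATE)
        noise /= np.sqrt(np.mean(noise**2))
        t = np.arange(12 * TARGET_RATE) / TARGET_RATE
        tone = np.sqrt(2.0) * np.sin(2 * np.pi * 2_000 * t)  # unit RMS, outside rain band
        _, s_noise = rain_filter(noise, TARGET_RATE, -60)
        _, s_tone = rain_filter(tone, TARGET_RATE, -60)
        assert s_noise > s_tone

    def test_discards_most_rain_files_on_labeled_corpus(self, tmp_path):
        """Threshold tuned on 10 files separates rain from biophony >=90%."""
        from soundscape_ae import SoundComponent, SyntheticCorpusSpec, generate_corpus

        spec = SyntheticCorpusSpec(
            n_recorders=1, n_days=1, recordings_per_hour=1, duration_s=12.0,
            components=(
                SoundComponent(kind="rain", amplitude=0.4, active_hours=frozenset(range(12))),
                SoundComponent(kind="anuran_pulses", center_freq=2_000, bandwidth=300,
                               amplitude=0.4, pulse_rate=4.0, active_hours=frozenset(range(12, 24))),
            ),
            noise_floor=0.001, seed=4,
        )
        manifest = generate_corpus(spec, tmp_path / "rain")
        scores, is_rain = [], []
        for _, row in manifest.iterrows():
            _, wave = load_recording(row["path"], manifest_row=row)
            _, s = rain_filter(wave, TARGET_RATE, 0.0)
            scores.append(s)
            is_rain.append("rain" in row["components"])
        scores, is_rain = np.array(scores), np.array(is_rain)
        # tune on 10 files (5 per class): midpoint between class means
        tune = np.concatenate([np.flatnonzero(is_rain)[:5], np.flatnonzero(~is_rain)[:5]])
        tune_s, tune_r = scores[tune], is_rain[tune]
        threshold = 0.5 * (tune_s[tune_r].mean() + tune_s[~tune_r].mean())
        discarded = scores > threshold
        assert np.mean(discarded[is_rain]) >= 0.9
        assert np.mean(~discarded[~is_rain]) >= 0.9

    def test_deterministic_and_order_independent(self):
        rng = np.random.default_rng(2)
        waves = [rng.standard_normal(TARGET_RATE) for _ in range(3)]
        first = [rain_filter(w, TARGET_RATE, -30) for w in waves]
        second = [rain_filter(w, TARGET_RATE, -30) for w in reversed(waves)]
        assert first == list(reversed(second))


class TestSegmentation:
    def test_60s_recording_yields_five_segments(self):
        wave = np.arange(5 * SEGMENT_SAMPLES, dtype=float)
        segs = segment_recording(_recording(), wave)
        assert len(segs) == 5
        assert [s.index for s in segs] == [0, 1, 2, 3, 4]

    def test_batch_of_14_recordings_yields_70_segments(self):
        wave = np.zeros(5 * SEGMENT_SAMPLES)
        total = sum(len(segment_recording(_recording(), wave)) for _ in range(14))
        assert total == 70

    def test_trailing_remainder_dropped(self):
        wave = np.zeros(71 * TARGET_RATE)  # 71 s -> floor(71/12) = 5
        assert len(segment_recording(_recording(), wave)) == 5

    def test_concatenation_reproduces_waveform_prefix(self):
        rng = np.random.default_rng(3)
        wave = rng.standard_normal(5 * SEGMENT_SAMPLES + 1234)
        segs = segment_recording(_recording(), wave)
        np.testing.assert_array_equal(
            np.concatenate([s.waveform for s in segs]), wave[: 5 * SEGMENT_SAMPLES]
        )

    def test_too_short_waveform_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_recording(_recording(), np.zeros(SEGMENT_SAMPLES - 1))

    @given(duration_s=st.integers(min_value=12, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_segment_count_is_floor_of_duration(self, duration_s):
        wave = np.zeros(duration_s * TARGET_RATE)
        assert len(segment_recording(_recording(), wave)) == duration_s // 12

    def test_segment_index_table(self):
        wave = np.zeros(5 * SEGMENT_SAMPLES)
        segs = segment_recording(_recording(), wave)
        table = build_segment_index(segs, kept=[True, True, False, True, True])
        assert len(table) == 5
        assert table["kept_by_rain_filter"].sum() == 4
        assert (table["recorder_id"] == "JAG01").all()
        assert table["segment_id"].is_unique
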