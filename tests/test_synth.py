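"""Synthetic soundscape generator: spectral placement, schedules, determinism."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.io import wavfile
from scipy.signal import periodogram

from soundscape_ae import SoundComponent, SyntheticCorpusSpec, component_signal, generate_corpus
from soundscape_ae.synth import SpecValidationError, render_file_waveform


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestComponentSignal:
    def test_silence_is_zero_vector(self):
        c = SoundComponent(kind="silence")
        x = component_signal(c, 3.0, 22_050, seed=0)
        assert x.shape == (3 * 22_050,)
        assert not np.any(x)

    def test_pulse_train_onset_count(self):
        """pulse_rate 2 over 3 s must produce exactly 6 pulse onsets."""
        c = SoundComponent(kind="anuran_pulses", center_freq=2_000, bandwidth=300,
                           amplitude=1.0, pulse_rate=2.0)
        x = component_signal(c, 3.0, 22_050, seed=0)
        env = np.abs(sps.hilbert(x))
        env = sps.sosfilt(sps.butter(2, 50, fs=22_050, output="sos"), env)
        thr = 0.5 * env.max()
        onsets = int(np.sum((env[1:] > thr) & (env[:-1] <= thr)))
        assert onsets == 6

    def test_rms_proportional_to_amplitude(self):
        a = component_signal(SoundComponent(kind="rain", amplitude=0.5), 5.0, 22_050, seed=7)
        b = component_signal(SoundComponent(kind="rain", amplitude=0.25), 5.0, 22_050, seed=7)
        assert _rms(a) / _rms(b) == pytest.approx(2.0, rel=0.01)

    @pytest.mark.parametrize(
        "kind,cf,bw,pr",
        [
            ("insect_band", 6_000, 1_000, 0.0),
            ("anuran_pulses", 2_000, 400, 4.0),
            ("bird_chirp", 4_750, 2_500, 2.0),
        ],
    )
    def test_spectral_placement(self, kind, cf, bw, pr):
        """Band-limited components keep >=80% of power within +/- bandwidth of center."""
        c = SoundComponent(kind=kind, center_freq=cf, bandwidth=bw, amplitude=0.5, pulse_rate=pr)
        x = component_signal(c, 12.0, 22_050, seed=3)
        f, p = periodogram(x, fs=22_050)
        in_band = p[(f >= cf - bw) & (f <= cf + bw)].sum() / p.sum()
        assert in_band >= 0.8

    def test_river_is_lowpass(self):
        x = component_signal(SoundComponent(kind="river", amplitude=1.0), 12.0, 22_050, seed=1)
        f, p = periodogram(x, fs=22_050)
        assert p[f <= 600].sum() / p.sum() >= 0.9

    def test_determinism(self):
        c = SoundComponent(kind="insect_band", center_freq=6_000, bandwidth=1_000, amplitude=0.3)
        a = component_signal(c, 2.0, 22_050, seed=5)
        b = component_signal(c, 2.0, 22_050, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_validation_errors_name_the_field(self):
        with pytest.raises(SpecValidationError, match="amplitude"):
            SoundComponent(kind="rain", amplitude=1.5)
        with pytest.raises(SpecValidationError, match="pulse_rate"):
            SoundComponent(kind="rain", pulse_rate=-1)
        with pytest.raises(SpecValidationError, match="kind"):
            SoundComponent(kind="whale_song")
        with pytest.raises(SpecValidationError, match="center_freq"):
            SoundComponent(kind="insect_band", center_freq=11_000, bandwidth=1_000).validate_against_rate(22_050)


class TestGenerateCorpus:
    def test_manifest_row_count(self, tmp_path):
        """2 recorders x 1 day x 24 h x 4 per hour = 192 files."""
        spec = SyntheticCorpusSpec(
            n_recorders=2, n_days=1, recordings_per_hour=4, duration_s=1.0,
            components=(), noise_floor=0.0, seed=0,
        )
        manifest = generate_corpus(spec, tmp_path)
        assert len(manifest) == 192
        assert sorted(manifest.columns) == sorted(
            ["path", "recorder_id", "timestamp_iso", "components", "cover_label"]
        )
        # filename convention parses back
        assert manifest["path"].str.contains(r"REC0[12]_\d{8}_\d{6}\.wav$").all()

    def test_silence_only_zero_noise_floor_gives_zero_waveforms(self, tmp_path):
        spec = SyntheticCorpusSpec(
            n_recorders=1, n_days=1, recordings_per_hour=1, duration_s=1.0,
            components=(SoundComponent(kind="silence"),), noise_floor=0.0, seed=0,
        )
        manifest = generate_corpus(spec, tmp_path)
        for path in manifest["path"]:
            _, data = wavfile.read(path)
            assert not np.any(data)

    def test_single_component_peak_frequency(self, tmp_path):
        spec = SyntheticCorpusSpec(
            n_recorders=1, n_days=1, recordings_per_hour=1, duration_s=2.0,
            components=(SoundComponent(kind="insect_band", center_freq=6_000,
                                       bandwidth=1_000, amplitude=0.5),),
            noise_floor=0.0, seed=1,
        )
        manifest = generate_corpus(spec, tmp_path)
        for path in manifest["path"].head(5):
            rate, data = wavfile.read(path)
            f, p = periodogram(data / 32768.0, fs=rate)
            assert abs(f[np.argmax(p)] - 6_000) <= 1_000

    def test_schedule_fidelity_inactive_hours_are_silent(self):
        """A component scheduled 12:00-17:00 contributes zero energy at 03:00."""
        spec = SyntheticCorpusSpec(
            n_recorders=1, n_days=1, recordings_per_hour=1, duration_s=1.0,
            components=(SoundComponent(kind="insect_band", center_freq=6_000, bandwidth=1_000,
                                       amplitude=0.5, active_hours=frozenset(range(12, 18))),),
            noise_floor=0.0, seed=2,
        )
        silent, active_kinds = render_file_waveform(spec, file_index=3, hour=3)
        assert not np.any(silent) and active_kinds == []
        loud, kinds = render_file_waveform(spec, file_index=13, hour=13)
        assert _rms(loud) > 0 and kinds == ["insect_band"]

    def test_corpus_byte_identical_under_same_seed(self, tmp_path):
        spec = SyntheticCorpusSpec(
            n_recorders=1, n_days=1, recordings_per_hour=1, duration_s=1.0,
            components=(SoundComponent(kind="rain", amplitude=0.4),), noise_floor=0.01, seed=9,
        )
        m1 = generate_corpus(spec, tmp_path / "a")
        m2 = generate_corpus(spec, tmp_path / "b")
        for p1, p2 in zip(m1["path"], m2["path"]):
            with open(p1, "rb") as f1, open(p2, "rb") as f2:
                assert f1.read() == f2.read()

    def test_invalid_spec_fields_rejected(self):
        with pytest.raises(SpecValidationError, match="duration_s"):
            SyntheticCorpusSpec(duration_s=0.0001, sample_rate=22_050)
        with pytest.raises(SpecValidationError, match="n_recorders"):
            SyntheticCorpusSpec(n_recorders=0)
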