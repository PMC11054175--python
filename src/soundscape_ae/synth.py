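"""Synthetic soundscape corpora with known composition.

Field recordings from passive acoustic monitoring mix biophonies (insect
choruses, anuran calls, bird song), geophonies (rain, rivers) and silence,
scheduled over the diel cycle.  This module emulates that structure with
simple, spectrally controllable signal models so that every downstream
stage — segmentation, spectrograms, autoencoder, clustering, diel
histograms — can be exercised against ground truth:

* ``insect_band`` — band-passed white noise around a carrier (e.g. a 6 kHz
  cicada-like chorus),
* ``anuran_pulses`` — an amplitude-modulated pulse train on a ~2 kHz carrier,
* ``bird_chirp`` — repeated linear FM sweeps in the 3.5–6 kHz band,
* ``rain`` — broadband white noise,
* ``river`` — low-passed noise below 500 Hz,
* ``silence`` — zeros.

Each component carries an ``active_hours`` schedule; a generated file
contains exactly the components active at the file's hour of day, mixed
over a Gaussian noise floor.  Generation is fully deterministic in the
corpus seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "COMPONENT_KINDS",
    "SoundComponent",
    "SyntheticCorpusSpec",
    "component_signal",
    "generate_corpus",
    "SpecValidationError",
]

COMPONENT_KINDS = (
    "insect_band",
    "anuran_pulses",
    "bird_chirp",
    "rain",
    "river",
    "silence",
)

#: kinds whose energy is expected to sit inside [center_freq - bw, center_freq + bw]
BAND_LIMITED_KINDS = ("insect_band", "anuran_pulses", "bird_chirp")

MANIFEST_COLUMNS = ["path", "recorder_id", "timestamp_iso", "components", "cover_label"]

_CORPUS_EPOCH = datetime(2024, 1, 1, 0, 0, 0)


class SpecValidationError(ValueError):
    """A corpus or component specification field is invalid."""


@dataclass(frozen=True)
class SoundComponent:
    """One schedulable sound source of the synthetic soundscape."""

    kind: str
    center_freq: float = 0.0
    bandwidth: float = 0.0
    amplitude: float = 1.0
    pulse_rate: float = 0.0
    active_hours: frozenset = field(default_factory=lambda: frozenset(range(24)))

    def __post_init__(self):
        if self.kind not in COMPONENT_KINDS:
            raise SpecValidationError(
                f"kind: unknown component kind {self.kind!r}; expected one of {COMPONENT_KINDS}"
            )
        if not 0.0 <= self.amplitude <= 1.0:
            raise SpecValidationError(f"amplitude: {self.amplitude} not in [0, 1]")
        if self.pulse_rate < 0:
            raise SpecValidationError(f"pulse_rate: {self.pulse_rate} must be >= 0")
        hours = frozenset(int(h) for h in self.active_hours)
        if any(h < 0 or h > 23 for h in hours):
            raise SpecValidationError("active_hours: entries must be hour-of-day integers 0-23")
        object.__setattr__(self, "active_hours", hours)

    def validate_against_rate(self, sample_rate: float) -> None:
        """Check the band-edge invariant against a concrete Nyquist frequency."""
        if self.kind in BAND_LIMITED_KINDS:
            upper = self.center_freq + self.bandwidth / 2.0
            if not 0.0 < upper <= sample_rate / 2.0:
                raise SpecValidationError(
                    f"center_freq/bandwidth: band edge {upper} Hz outside (0, {sample_rate / 2} Hz]"
                )

    def active_at(self, hour: int) -> bool:
        return hour in self.active_hours


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Sampling design of a synthetic corpus.

    Defaults mirror a typical duty-cycled deployment: one-minute files,
    four per hour.  ``sample_rate`` defaults to 22,050 Hz so fast tests
    skip resampling; 44,100 Hz exercises the ingest resampler.
    """

    n_recorders: int = 1
    n_days: int = 1
    recordings_per_hour: int = 4
    duration_s: float = 60.0
    sample_rate: int = 22_050
    components: tuple = ()
    noise_floor: float = 0.001
    seed: int = 0

    def __post_init__(self):
        for name in ("n_recorders", "n_days", "recordings_per_hour"):
            if getattr(self, name) < 1:
                raise SpecValidationError(f"{name}: must be >= 1")
        if self.duration_s <= 0:
            raise SpecValidationError("duration_s: must be > 0")
        if self.sample_rate <= 0:
            raise SpecValidationError("sample_rate: must be > 0")
        n = self.duration_s * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise SpecValidationError(
                f"duration_s: {self.duration_s} s at {self.sample_rate} Hz is not an integer sample count"
            )
        if self.noise_floor < 0:
            raise SpecValidationError("noise_floor: must be >= 0")
        object.__setattr__(self, "components", tuple(self.components))
        for c in self.components:
            c.validate_against_rate(self.sample_rate)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))

    @property
    def n_files(self) -> int:
        return self.n_recorders * self.n_days * 24 * self.recordings_per_hour


def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = float(np.sqrt(np.mean(np.square(x))))
    return x if rms == 0.0 else x / rms


def component_signal(
    c: SoundComponent, duration_s: float, sample_rate: int, seed: int
) -> np.ndarray:
    """Time-domain signal of one component, RMS-normalized to ``c.amplitude``.

    The synthesis models are deliberately simple (filtered noise, pulse
    trains, FM sweeps) — they control spectral placement, not realism.
    """
    if duration_s <= 0:
        raise SpecValidationError("duration_s: must be > 0")
    n = int(round(duration_s * sample_rate))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    t = np.arange(n) / sample_rate

    if c.kind == "silence":
        return np.zeros(n)

    if c.kind == "rain":
        x = rng.standard_normal(n)
    elif c.kind == "river":
        cutoff = min(500.0, sample_rate / 2.0 * 0.9)
        sos = signal.butter(4, cutoff, btype="lowpass", fs=sample_rate, output="sos")
        x = signal.sosfilt(sos, rng.standard_normal(n))
    elif c.kind == "insect_band":
        lo = max(c.center_freq - c.bandwidth / 2.0, 1.0)
        hi = min(c.center_freq + c.bandwidth / 2.0, sample_rate / 2.0 - 1.0)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
        x = signal.sosfilt(sos, rng.standard_normal(n))
    elif c.kind == "anuran_pulses":
        # Raised-cosine pulses at regular onsets, narrowband noise carrier.
        pulse_len_s = min(0.05, 0.5 / max(c.pulse_rate, 1e-9)) if c.pulse_rate > 0 else duration_s
        env = np.zeros(n)
        if c.pulse_rate > 0:
            onsets = np.arange(0.0, duration_s - 1e-12, 1.0 / c.pulse_rate)
            m = int(round(pulse_len_s * sample_rate))
            pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / max(m - 1, 1)))
            for onset in onsets:
                i0 = int(round(onset * sample_rate))
                i1 = min(i0 + m, n)
                env[i0:i1] = np.maximum(env[i0:i1], pulse[: i1 - i0])
        else:
            env[:] = 1.0
        carrier = np.sin(2 * np.pi * c.center_freq * t + rng.uniform(0, 2 * np.pi))
        x = env * carrier
    elif c.kind == "bird_chirp":
        f0 = max(c.center_freq - c.bandwidth / 2.0, 1.0)
        f1 = min(c.center_freq + c.bandwidth / 2.0, sample_rate / 2.0 - 1.0)
        if c.pulse_rate > 0:
            chirp_len_s = min(0.2, 0.8 / c.pulse_rate)
            m = int(round(chirp_len_s * sample_rate))
            tc = np.arange(m) / sample_rate
            one = signal.chirp(tc, f0=f0, f1=f1, t1=chirp_len_s, method="linear")
            one *= np.hanning(m)
            x = np.zeros(n)
            for onset in np.arange(0.0, duration_s - 1e-12, 1.0 / c.pulse_rate):
                i0 = int(round(onset * sample_rate))
                i1 = min(i0 + m, n)
                x[i0:i1] += one[: i1 - i0]
        else:
            x = signal.chirp(t, f0=f0, f1=f1, t1=duration_s, method="linear")
    else:  # pragma: no cover - guarded in __post_init__
        raise SpecValidationError(f"kind: unknown component kind {c.kind!r}")

    return c.amplitude * _unit_rms(x)


def _file_seed(corpus_seed: int, file_index: int, component_index: int) -> int:
    ss = np.random.SeedSequence([corpus_seed & 0x7FFFFFFF, file_index, component_index])
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def render_file_waveform(spec: SyntheticCorpusSpec, file_index: int, hour: int) -> tuple:
    """Mix the components active at ``hour`` over the noise floor.

    Returns ``(waveform, active_kinds)``; deterministic in (seed, file_index).
    """
    n = spec.n_samples
    wave = np.zeros(n)
    active = []
    for ci, comp in enumerate(spec.components):
        if not comp.active_at(hour):
            continue
        wave += component_signal(comp, spec.duration_s, spec.sample_rate, _file_seed(spec.seed, file_index, ci))
        if comp.kind != "silence" and comp.amplitude > 0:
            active.append(comp.kind)
    if spec.noise_floor > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, file_index, 0xFFFF])
        )
        wave += spec.noise_floor * noise_rng.standard_normal(n)
    return wave, active


def _iter_schedule(spec: SyntheticCorpusSpec) -> Iterable[tuple]:
    """Yield (file_index, recorder_id, timestamp) over the sampling design."""
    minutes = [int(round(i * 60.0 / spec.recordings_per_hour)) for i in range(spec.recordings_per_hour)]
    idx = 0
    for r in range(spec.n_recorders):
        recorder_id = f"REC{r + 1:02d}"
        for d in range(spec.n_days):
            for h in range(24):
                for m in minutes:
                    ts = _CORPUS_EPOCH + timedelta(days=d, hours=h, minutes=m)
                    yield idx, recorder_id, ts
                    idx += 1


def _write_wav(path: Path, wave: np.ndarray, sample_rate: int, stereo: bool = False) -> None:
    clipped = np.clip(wave, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    if stereo:
        pcm = np.stack([pcm, pcm], axis=1)
    wavfile.write(str(path), sample_rate, pcm)


def generate_corpus(spec: SyntheticCorpusSpec, out_dir, stereo: bool = False):
    """Write the corpus WAV files and manifest; return the manifest table.

    Filenames follow the ARU convention ``<RECORDER>_<YYYYMMDD>_<HHMMSS>.wav``.
    Cover labels alternate by recorder (odd recorder index = forest).
    The returned object is a pandas DataFrame with columns
    ``path, recorder_id, timestamp_iso, components, cover_label`` (absolute
    paths); the same table is written to ``out_dir/manifest.csv`` with paths
    relative to the manifest, so a corpus directory is relocatable.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, recorder_id, ts in _iter_schedule(spec):
        wave, active = render_file_waveform(spec, idx, ts.hour)
        fname = f"{recorder_id}_{ts.strftime('%Y%m%d_%H%M%S')}.wav"
        _write_wav(out_dir / fname, wave, spec.sample_rate, stereo=stereo)
        cover = "forest" if int(recorder_id[3:]) % 2 == 1 else "non_forest"
        rows.append(
            {
                "path": fname,
                "recorder_id": recorder_id,
                "timestamp_iso": ts.isoformat(),
                "components": ";".join(sorted(active)),
                "cover_label": cover,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    return manifest.assign(path=[str(out_dir / p) for p in manifest["path"]])
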