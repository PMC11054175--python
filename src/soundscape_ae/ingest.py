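"""Recording ingest: WAV reading, resampling, rain screening, segmentation.

The analysis operates at 22,050 Hz (the sound types of interest sit below
~11 kHz), on non-overlapping 12-s segments of one-minute files.  Metadata
(recorder ID, timestamp, optional forest/non-forest cover label) is parsed
from ARU-style filenames ``<RECORDER>_<YYYYMMDD>_<HHMMSS>.wav`` or taken
from a manifest row.

Heavy-rain screening is a pluggable band-energy heuristic: mean power
spectral density in the 600-1,200 Hz band (a standard rain signature band)
in dB against a threshold.  It stands behind a stable interface so a more
elaborate detector can be substituted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from datetime import datetime
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "TARGET_RATE",
    "SEGMENT_SECONDS",
    "SEGMENT_SAMPLES",
    "Recording",
    "Segment",
    "MetadataError",
    "parse_aru_filename",
    "load_recording",
    "rain_filter",
    "segment_recording",
    "build_segment_index",
]

TARGET_RATE = 22_050
SEGMENT_SECONDS = 12
SEGMENT_SAMPLES = SEGMENT_SECONDS * TARGET_RATE  # 264,600

RAIN_BAND = (600.0, 1_200.0)

_FNAME_RE = re.compile(r"^(?P<rec>[A-Za-z0-9-]+)_(?P<date>\d{8})_(?P<time>\d{6})$")


class MetadataError(ValueError):
    """Recording metadata could not be determined."""


@dataclass(frozen=True)
class Recording:
    path: str
    recorder_id: str
    timestamp: datetime
    cover_label: Optional[str]
    sample_rate: int
    n_samples: int

    def __post_init__(self):
        if self.sample_rate <= 0 or self.n_samples <= 0:
            raise ValueError("sample_rate and n_samples must be positive")
        if self.cover_label not in (None, "forest", "non_forest"):
            raise ValueError(f"cover_label: {self.cover_label!r} not in {{forest, non_forest}}")

    @property
    def hour(self) -> int:
        return self.timestamp.hour


@dataclass(frozen=True)
class Segment:
    """A 12-s slice of a recording with inherited metadata."""

    parent: Recording
    index: int
    waveform: np.ndarray
    start_s: float

    def __post_init__(self):
        if len(self.waveform) != SEGMENT_SAMPLES:
            raise ValueError(
                f"segment waveform must have {SEGMENT_SAMPLES} samples, got {len(self.waveform)}"
            )

    @property
    def segment_id(self) -> str:
        return f"{Path(self.parent.path).stem}#{self.index}"

    @property
    def hour(self) -> int:
        return self.parent.hour


def parse_aru_filename(name: str):
    """Parse ``<RECORDER>_<YYYYMMDD>_<HHMMSS>`` → (recorder_id, timestamp)."""
    m = _FNAME_RE.match(Path(name).stem)
    if m is None:
        raise MetadataError(f"filename {name!r} does not match <RECORDER>_<YYYYMMDD>_<HHMMSS>.wav")
    try:
        ts = datetime.strptime(m.group("date") + m.group("time"), "%Y%m%d%H%M%S")
    except ValueError as exc:
        raise MetadataError(f"filename {name!r}: invalid timestamp ({exc})") from exc
    return m.group("rec"), ts


def _to_float(data: np.ndarray) -> np.ndarray:
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:  # 24-bit WAV is delivered as int32
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64)


def resample_to_target(waveform: np.ndarray, sample_rate: int, target: int = TARGET_RATE) -> np.ndarray:
    """Polyphase resampling at the exact rational rate ratio (1/2 from 44.1 kHz)."""
    if sample_rate == target:
        return waveform
    ratio = Fraction(target, sample_rate).limit_denominator(1000)
    return signal.resample_poly(waveform, ratio.numerator, ratio.denominator)


def load_recording(path, manifest_row=None, target_rate: int = TARGET_RATE):
    """Read a WAV file → (Recording, mono waveform at ``target_rate``).

    Stereo is collapsed by channel averaging.  Metadata comes from the
    manifest row when given (keys ``recorder_id, timestamp_iso,
    cover_label``), else from the filename.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, FileNotFoundError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    wave = _to_float(np.asarray(data))
    if wave.ndim == 2:
        wave = wave.mean(axis=1)
    wave = resample_to_target(wave, rate, target_rate)

    if manifest_row is not None:
        recorder_id = str(manifest_row["recorder_id"])
        timestamp = datetime.fromisoformat(str(manifest_row["timestamp_iso"]))
        cover = manifest_row.get("cover_label") if hasattr(manifest_row, "get") else manifest_row["cover_label"]
        cover = None if cover in (None, "", float("nan")) or (isinstance(cover, float) and math.isnan(cover)) else str(cover)
    else:
        recorder_id, timestamp = parse_aru_filename(path.name)
        cover = None

    rec = Recording(
        path=str(path),
        recorder_id=recorder_id,
        timestamp=timestamp,
        cover_label=cover,
        sample_rate=target_rate,
        n_samples=len(wave),
    )
    return rec, wave


def rain_filter(waveform: np.ndarray, sample_rate: int, threshold_db: float = -50.0):
    """Score a waveform for heavy rain; discard when the band PSD exceeds the threshold.

    Returns ``(keep, score_db)`` where ``score_db`` is the mean Welch PSD in
    the 600-1,200 Hz band in dB.  An all-zero signal scores ``-inf`` and is
    kept.  Deterministic and order-independent across files.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size == 0:
        raise ValueError("waveform is empty")
    if not np.any(waveform):
        return True, float("-inf")
    nperseg = min(2048, waveform.size)
    freqs, psd = signal.welch(waveform, fs=sample_rate, nperseg=nperseg)
    band = (freqs >= RAIN_BAND[0]) & (freqs <= RAIN_BAND[1])
    if not np.any(band):
        return True, float("-inf")
    mean_psd = float(np.mean(psd[band]))
    score = 10.0 * np.log10(mean_psd + 1e-20)
    return score <= threshold_db, score


def segment_recording(rec: Recording, waveform: np.ndarray, segment_s: float = SEGMENT_SECONDS):
    """Split into consecutive non-overlapping 12-s segments; remainder dropped."""
    seg_len = int(round(segment_s * TARGET_RATE))
    if len(waveform) < seg_len:
        raise ValueError(
            f"waveform of {len(waveform)} samples is shorter than one {segment_s}-s segment ({seg_len})"
        )
    n_seg = len(waveform) // seg_len
    return [
        Segment(
            parent=rec,
            index=i,
            waveform=np.asarray(waveform[i * seg_len : (i + 1) * seg_len]),
            start_s=i * segment_s,
        )
        for i in range(n_seg)
    ]


def build_segment_index(segments: Sequence[Segment], kept: Optional[Sequence[bool]] = None):
    """Segment metadata table (``segment_id, path, recorder_id, timestamp_iso,
    segment_index, kept_by_rain_filter``) used by diel analysis and exports."""
    import pandas as pd

    if kept is None:
        kept = [True] * len(segments)
    rows = [
        {
            "segment_id": s.segment_id,
            "path": Path(s.parent.path).name,  # basename: index stays relocatable
            "recorder_id": s.parent.recorder_id,
            "timestamp_iso": s.parent.timestamp.isoformat(),
            "segment_index": s.index,
            "kept_by_rain_filter": bool(k),
        }
        for s, k in zip(segments, kept)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "segment_id",
            "path",
            "recorder_id",
            "timestamp_iso",
            "segment_index",
            "kept_by_rain_filter",
        ],
    )
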