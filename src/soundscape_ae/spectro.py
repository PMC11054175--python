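"""Square 515×515 spectrograms of 12-s segments.

A 12-s segment at 22,050 Hz (264,600 samples) is transformed with a
short-time Fourier transform using a 1,028-point Hamming window and a hop
of half the window.  With the transform length equal to the window length,
the one-sided spectrum has 1,028/2 + 1 = 515 frequency bins; centered
framing (reflect padding by half a window on each side) yields
1 + floor(264,600/514) = 515 time frames, so the output is square.

Magnitudes are compressed to decibels and min-max scaled to [0, 1] per
spectrogram.  dB compression keeps weak high-frequency biophonies from
being numerically crushed; the [0, 1] range matches the sigmoidal output
of the autoencoder's decoder.  The dB shift introduced by any positive
rescaling of the waveform is removed by the min-max step, so spectrograms
are invariant to overall gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ingest import SEGMENT_SAMPLES, TARGET_RATE, Segment

__all__ = [
    "N_BINS",
    "WINDOW_LEN",
    "HOP",
    "HAMMING_A0",
    "HAMMING_A1",
    "Spectrogram",
    "hamming_window",
    "stft_spectrogram",
    "save_spectrograms",
    "load_spectrograms",
]

WINDOW_LEN = 1_028
HOP = WINDOW_LEN // 2  # 514
N_BINS = WINDOW_LEN // 2 + 1  # 515
DB_EPS = 1e-10

# "Exact" Hamming coefficients (not the rounded 0.54/0.46 pair).
HAMMING_A0 = 0.53836
HAMMING_A1 = 0.46164


@dataclass(frozen=True)
class Spectrogram:
    """Normalized magnitude spectrogram: rows = frequency (ascending), cols = time."""

    values: np.ndarray
    segment_id: Optional[str] = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (N_BINS, N_BINS):
            raise ValueError(f"spectrogram shape {v.shape} != ({N_BINS}, {N_BINS})")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("spectrogram entries must lie in [0, 1]")

    @property
    def freq_resolution(self) -> float:
        """Hz per frequency bin (22,050 / 1,028 ≈ 21.45)."""
        return TARGET_RATE / WINDOW_LEN

    @property
    def time_hop(self) -> float:
        """Seconds per time frame (514 / 22,050)."""
        return HOP / TARGET_RATE


def hamming_window(n: int) -> np.ndarray:
    """Hamming window ``a0 - a1*cos(2*pi*k/(n-1))`` with a0=0.53836, a1=0.46164."""
    if n < 2:
        raise ValueError(f"window length must be >= 2, got {n}")
    k = np.arange(n)
    return HAMMING_A0 - HAMMING_A1 * np.cos(2.0 * np.pi * k / (n - 1))


def _frame_centered(waveform: np.ndarray, window_len: int, hop: int) -> np.ndarray:
    """Centered frames via reflect padding; frame count = 1 + len//hop."""
    pad = window_len // 2
    padded = np.pad(waveform, pad, mode="reflect")
    n_frames = 1 + len(waveform) // hop
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return padded[idx]


def stft_magnitudes(
    waveform: np.ndarray, window_len: int = WINDOW_LEN, hop: int = HOP
) -> np.ndarray:
    """One-sided magnitude STFT (freq × time), unnormalized."""
    if hop <= 0:
        raise ValueError("hop must be positive")
    waveform = np.asarray(waveform, dtype=np.float64)
    frames = _frame_centered(waveform, window_len, hop)
    spec = np.fft.rfft(frames * hamming_window(window_len)[None, :], n=window_len, axis=1)
    return np.abs(spec).T


def normalize_db(mag: np.ndarray) -> np.ndarray:
    """dB compression then per-matrix min-max to [0, 1]; a constant matrix maps to zeros."""
    db = 20.0 * np.log10(mag + DB_EPS)
    lo, hi = db.min(), db.max()
    if hi - lo < 1e-12:
        return np.zeros_like(db)
    return (db - lo) / (hi - lo)


def stft_spectrogram(
    segment, window_len: int = WINDOW_LEN, hop: int = HOP
) -> Spectrogram:
    """515×515 normalized spectrogram of a 12-s segment.

    Accepts a :class:`~soundscape_ae.ingest.Segment` or a bare waveform of
    exactly 264,600 samples at 22,050 Hz.
    """
    if isinstance(segment, Segment):
        waveform, seg_id = segment.waveform, segment.segment_id
    else:
        waveform, seg_id = np.asarray(segment), None
    if len(waveform) != SEGMENT_SAMPLES:
        raise ValueError(
            f"segment must have exactly {SEGMENT_SAMPLES} samples (12 s at {TARGET_RATE} Hz), "
            f"got {len(waveform)}"
        )
    mag = stft_magnitudes(waveform, window_len, hop)
    return Spectrogram(values=normalize_db(mag), segment_id=seg_id)


def save_spectrograms(path, spectrograms: Sequence[Spectrogram]) -> None:
    """Write a batch to HDF5: dataset ``spectrograms`` (n×515×515 float32) +
    string dataset ``segment_ids``."""
    import h5py

    arr = np.stack([np.asarray(s.values, dtype=np.float32) for s in spectrograms])
    ids = [s.segment_id or "" for s in spectrograms]
    with h5py.File(path, "w") as f:
        f.create_dataset("spectrograms", data=arr)
        f.create_dataset("segment_ids", data=np.array(ids, dtype=h5py.string_dtype()))


def load_spectrograms(path):
    """Read an HDF5 batch → (array n×515×515 float32, list of segment ids)."""
    import h5py

    with h5py.File(path, "r") as f:
        arr = f["spectrograms"][:]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["segment_ids"][:]]
    return arr, ids
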