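"""From a one-minute recording to five square spectrograms.

A 60-s waveform at 22,050 Hz splits into five 12-s segments; each becomes
a 515×515 spectrogram (1,028-point Hamming window, hop 514, dB-compressed
and min-max scaled to [0, 1]).  A pure tone lands in the predicted
frequency bin: bin = f · 1,028 / 22,050.
"""

import numpy as np

from soundscape_ae import stft_spectrogram
from soundscape_ae.ingest import SEGMENT_SAMPLES, TARGET_RATE

t = np.arange(60 * TARGET_RATE) / TARGET_RATE
wave = np.sin(2 * np.pi * 5_512.5 * t)  # 5,512.5 Hz -> bin 257 exactly

segments = wave.reshape(-1, SEGMENT_SAMPLES)  # five 12-s slices
print(f"{len(segments)} segments of {SEGMENT_SAMPLES} samples")

spec = stft_spectrogram(segments[0])
peak_bin = int(np.argmax(spec.values.mean(axis=1)))
print(f"spectrogram shape: {spec.values.shape}")
print(f"value range: [{spec.values.min():.1f}, {spec.values.max():.1f}]")
print(f"tone peak at frequency bin {peak_bin} "
      f"(predicted {5_512.5 * 1_028 / 22_050:.0f}, {spec.freq_resolution:.2f} Hz/bin)")
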