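"""Train the convolutional autoencoder on a handful of spectrograms.

The encoder compresses each 515×515 spectrogram (265,225 pixels) to a
5,184-dimensional latent code — about 2% of the input — through four
strided convolutions; the decoder reconstructs the input from the code.
Training minimizes mean squared reconstruction error with Adam; here a
tiny tone dataset is memorized in a few dozen steps.
"""

import numpy as np

from soundscape_ae import AutoencoderConfig, build_autoencoder, stft_spectrogram, train
from soundscape_ae.ingest import SEGMENT_SAMPLES, TARGET_RATE

t = np.arange(SEGMENT_SAMPLES) / TARGET_RATE
spec = stft_spectrogram(np.sin(2 * np.pi * 2_000 * t)).values.astype(np.float32)
data = np.repeat(spec[None], 24, axis=0)

cfg = AutoencoderConfig(epochs=2, batch_segments=4, learning_rate=3e-3, seed=0)
model = build_autoencoder(cfg)
print("encoder spatial trace:", " -> ".join(map(str, model.trace)))

log = train(model, data, cfg)
train_mse = [r["mse"] for r in log if r["split"] == "train"]
print(f"train MSE: first step {train_mse[0]:.4f}, last step {train_mse[-1]:.4f}")

embedding = model.encode(spec)
print(f"embedding: length {len(embedding)}, "
      f"compression {len(embedding) / spec.size:.2%} of the input pixels")
recon = model.decode(embedding)
print(f"reconstruction shape {recon.shape}, values in [{recon.min():.2f}, {recon.max():.2f}]")
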