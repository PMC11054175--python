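"""Vanilla convolutional autoencoder over 515×515 spectrograms.

The encoder is four strided convolutions with ReLU activations; with the
default schedule (kernel 3, strides 3/3/3/2, paddings 1/1/1/0, channels
1→16→32→64→64) the spatial trace is 515 → 172 → 58 → 20 → 9, so the
flattened latent code has 64·9·9 = 5,184 features — about 2% of the
265,225 input pixels.  The decoder mirrors the encoder with four
transposed convolutions (ReLU between, sigmoid last, output padding chosen
automatically so the reconstruction is exactly 515×515).  Training
minimizes mean squared reconstruction error with Adam; a held-out 2% of
the data tracks generalization each epoch.

The latent code (post-ReLU, hence non-negative) is the embedding consumed
by projection, clustering and classification; the decoder additionally
turns cluster-centroid feature vectors into prototype spectrograms.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .spectro import N_BINS, Spectrogram

__all__ = [
    "EMBEDDING_DIM",
    "AutoencoderConfig",
    "ConvAutoencoder",
    "build_autoencoder",
    "train",
    "encode",
    "decode",
    "save_checkpoint",
    "load_checkpoint",
]

EMBEDDING_DIM = 5_184  # 64 × 9 × 9
LATENT_SHAPE = (64, 9, 9)


@dataclass(frozen=True)
class AutoencoderConfig:
    """Architecture and training hyperparameters.

    The kernel/stride/padding schedule must take 515 down to a 9×9 feature
    map; construction validates the trace and reports it on mismatch.
    """

    channel_progression: Tuple[int, ...] = (16, 32, 64, 64)
    kernel: int = 3
    strides: Tuple[int, ...] = (3, 3, 3, 2)
    paddings: Tuple[int, ...] = (1, 1, 1, 0)
    epochs: int = 10
    batch_segments: int = 70  # 14 one-minute files × 5 segments
    learning_rate: float = 1e-3
    train_fraction: float = 0.98
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "channel_progression", tuple(self.channel_progression))
        object.__setattr__(self, "strides", tuple(self.strides))
        object.__setattr__(self, "paddings", tuple(self.paddings))
        n = len(self.channel_progression)
        if len(self.strides) != n or len(self.paddings) != n:
            raise ValueError("channel_progression, strides and paddings must have equal length")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction {self.train_fraction} not in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_segments < 1:
            raise ValueError("epochs and batch_segments must be >= 1")

    def spatial_trace(self, input_size: int = N_BINS) -> List[int]:
        sizes = [input_size]
        for s, p in zip(self.strides, self.paddings):
            sizes.append(nn.conv_output_size(sizes[-1], self.kernel, s, p))
        return sizes


class ConvAutoencoder:
    """Encoder/decoder pair with a flattened latent embedding."""

    def __init__(self, cfg: AutoencoderConfig):
        trace = cfg.spatial_trace()
        if trace[-1] != LATENT_SHAPE[1] or cfg.channel_progression[-1] != LATENT_SHAPE[0]:
            raise ValueError(
                f"configuration does not reach a {LATENT_SHAPE[0]}×{LATENT_SHAPE[1]}×{LATENT_SHAPE[2]} "
                f"feature map: spatial trace {trace}, final channels {cfg.channel_progression[-1]}"
            )
        self.cfg = cfg
        self.trace = trace
        rng = np.random.default_rng(cfg.seed)

        enc_layers: List[nn.Layer] = []
        channels = (1,) + cfg.channel_progression
        for i, (s, p) in enumerate(zip(cfg.strides, cfg.paddings)):
            enc_layers.append(nn.Conv2d(channels[i], channels[i + 1], cfg.kernel, s, p, rng=rng))
            enc_layers.append(nn.ReLU())
        self.encoder = nn.Sequential(enc_layers)

        dec_layers: List[nn.Layer] = []
        rev_channels = channels[::-1]
        rev_strides = cfg.strides[::-1]
        rev_pads = cfg.paddings[::-1]
        rev_trace = trace[::-1]  # decoder must walk back up this trace
        for i in range(len(rev_strides)):
            target = rev_trace[i + 1]
            base = nn.conv_transpose_output_size(rev_trace[i], cfg.kernel, rev_strides[i], rev_pads[i], 0)
            op = target - base
            if not 0 <= op < rev_strides[i]:
                raise ValueError(
                    f"decoder layer {i}: cannot reach size {target} from {rev_trace[i]} "
                    f"(base {base}, stride {rev_strides[i]})"
                )
            dec_layers.append(
                nn.ConvTranspose2d(
                    rev_channels[i], rev_channels[i + 1], cfg.kernel, rev_strides[i], rev_pads[i], op, rng=rng
                )
            )
            dec_layers.append(nn.Sigmoid() if i == len(rev_strides) - 1 else nn.ReLU())
        self.decoder = nn.Sequential(dec_layers)

    # -- inference ---------------------------------------------------------
    def _as_batch(self, spectrograms) -> np.ndarray:
        arr = np.asarray(
            spectrograms.values if isinstance(spectrograms, Spectrogram) else spectrograms,
            dtype=nn.DTYPE,
        )
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3 or arr.shape[1:] != (N_BINS, N_BINS):
            raise ValueError(f"expected (n, {N_BINS}, {N_BINS}) spectrograms, got {arr.shape}")
        return arr[:, None]  # add channel axis

    def encode(self, spectrograms) -> np.ndarray:
        """Spectrogram(s) → embedding(s) of length 5,184 (non-negative, post-ReLU)."""
        single = isinstance(spectrograms, Spectrogram) or np.asarray(
            spectrograms.values if isinstance(spectrograms, Spectrogram) else spectrograms
        ).ndim == 2
        x = self._as_batch(spectrograms)
        z = self.encoder.forward(x)
        flat = z.reshape(z.shape[0], -1)
        if flat.shape[1] != EMBEDDING_DIM:
            raise AssertionError(f"latent dimension {flat.shape[1]} != {EMBEDDING_DIM}")
        return flat[0] if single else flat

    def decode(self, embeddings) -> np.ndarray:
        """Embedding(s) of length 5,184 → 515×515 matrices in [0, 1]."""
        arr = np.asarray(embeddings, dtype=nn.DTYPE)
        single = arr.ndim == 1
        if single:
            arr = arr[None]
        if arr.shape[1] != EMBEDDING_DIM:
            raise ValueError(f"embedding length {arr.shape[1]} != {EMBEDDING_DIM}")
        z = arr.reshape(arr.shape[0], *LATENT_SHAPE)
        y = self.decoder.forward(z)[:, 0]
        return y[0] if single else y

    def reconstruct(self, spectrograms) -> np.ndarray:
        x = self._as_batch(spectrograms)
        return self.decoder.forward(self.encoder.forward(x))[:, 0]

    # -- training ----------------------------------------------------------
    def _loss_on(self, batch: np.ndarray) -> float:
        x = batch[:, None].astype(nn.DTYPE)
        y = self.decoder.forward(self.encoder.forward(x))
        loss, _ = nn.mse_loss(y, x)
        return loss

    def evaluate(self, spectrograms: np.ndarray, batch: int = 16) -> float:
        """Mean reconstruction MSE over a dataset (inference only)."""
        losses, weights = [], []
        for i in range(0, len(spectrograms), batch):
            chunk = spectrograms[i : i + batch]
            losses.append(self._loss_on(chunk))
            weights.append(len(chunk))
        return float(np.average(losses, weights=weights))

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()

    def state_dict(self):
        return {"encoder": self.encoder.state_dict(), "decoder": self.decoder.state_dict()}

    def load_state_dict(self, state):
        self.encoder.load_state_dict(state["encoder"])
        self.decoder.load_state_dict(state["decoder"])


def build_autoencoder(cfg: AutoencoderConfig = AutoencoderConfig()) -> ConvAutoencoder:
    """Construct a seeded autoencoder, validating the spatial trace."""
    return ConvAutoencoder(cfg)


def split_train_test(
    n: int, train_fraction: float, seed: int, groups: Optional[Sequence] = None
):
    """Seeded shuffle split → (train_idx, test_idx); test size = max(1, floor(n·(1−f))).

    With ``groups`` (e.g. recording ids) the split is made at group level so
    near-duplicate segments of one recording never straddle the split.
    """
    n_test = max(1, int(np.floor(n * (1.0 - train_fraction))))
    rng = np.random.default_rng(seed)
    if groups is None:
        order = rng.permutation(n)
        return np.sort(order[n_test:]), np.sort(order[:n_test])
    groups = np.asarray(groups)
    uniq = np.array(sorted(set(groups.tolist())), dtype=object)
    g_order = rng.permutation(len(uniq))
    test_idx: List[int] = []
    for gi in g_order:
        members = np.flatnonzero(groups == uniq[gi])
        test_idx.extend(members.tolist())
        if len(test_idx) >= n_test:
            break
    test = np.array(sorted(test_idx), dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return np.flatnonzero(mask), test


def train(
    model: ConvAutoencoder,
    spectrograms: np.ndarray,
    cfg: Optional[AutoencoderConfig] = None,
    groups: Optional[Sequence] = None,
    checkpoint_dir=None,
):
    """Train in place; return the log as a list of dicts
    (``iteration, epoch, split, mse``).

    Per-iteration rows record the train-batch MSE; one ``test`` row per
    epoch records the held-out MSE.  Raises on NaN loss.
    """
    import pandas as pd

    cfg = cfg or model.cfg
    data = np.asarray(spectrograms, dtype=nn.DTYPE)
    if data.ndim != 3 or len(data) < 10:
        raise ValueError("need at least 10 spectrograms shaped (n, 515, 515)")

    train_idx, test_idx = split_train_test(len(data), cfg.train_fraction, cfg.seed, groups)
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    log: List[dict] = []
    iteration = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        for i in range(0, len(order), cfg.batch_segments):
            x = data[order[i : i + cfg.batch_segments]][:, None]
            y = model.decoder.forward(model.encoder.forward(x))
            loss, dy = nn.mse_loss(y, x)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} at iteration {iteration} (epoch {epoch})"
                )
            model.encoder.backward(model.decoder.backward(dy.astype(nn.DTYPE)))
            optimizer.step()
            log.append({"iteration": iteration, "epoch": epoch, "split": "train", "mse": loss})
            iteration += 1
        test_mse = model.evaluate(data[test_idx])
        log.append({"iteration": iteration, "epoch": epoch, "split": "test", "mse": test_mse})
        if checkpoint_dir is not None:
            save_checkpoint(Path(checkpoint_dir) / f"epoch{epoch:03d}.npz", model)
    if checkpoint_dir is not None:
        pd.DataFrame(log).to_csv(Path(checkpoint_dir) / "training_log.csv", index=False)
    return log


def encode(model: ConvAutoencoder, spectrogram) -> np.ndarray:
    return model.encode(spectrogram)


def decode(model: ConvAutoencoder, embedding) -> np.ndarray:
    return model.decode(embedding)


def save_checkpoint(path, model: ConvAutoencoder) -> None:
    """Single-file npz archive with a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = {}
    for scope, state in model.state_dict().items():
        for k, v in state.items():
            flat[f"{scope}/{k}"] = v
    np.savez(path, **flat)
    with open(path.with_suffix(".json"), "w") as f:
        json.dump(asdict(model.cfg), f, indent=2, sort_keys=True)


def load_checkpoint(path) -> ConvAutoencoder:
    path = Path(path)
    with open(path.with_suffix(".json")) as f:
        cfg = AutoencoderConfig(**json.load(f))
    model = ConvAutoencoder(cfg)
    with np.load(path) as archive:
        state = {"encoder": {}, "decoder": {}}
        for key in archive.files:
            scope, name = key.split("/", 1)
            state[scope][name] = archive[key]
    model.load_state_dict(state)
    return model
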