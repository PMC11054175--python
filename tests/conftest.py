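"""Shared fixtures: tiny synthetic corpora and spectrogram batches.

Session-scoped so the expensive artifacts (WAV corpora, STFTs) are built
once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from soundscape_ae import (
    SoundComponent,
    SyntheticCorpusSpec,
    generate_corpus,
    load_recording,
    segment_recording,
    stft_spectrogram,
)

NOCTURNAL_HOURS = frozenset([18, 19, 20, 21, 22, 23, 0, 1, 2, 3, 4, 5])
BIRD_HOURS = frozenset([6, 7, 8, 9, 10, 11])
INSECT_HOURS = frozenset([12, 13, 14, 15, 16, 17])


def three_class_components(amplitude: float = 0.5):
    """Three biophonies in disjoint spectral bands and disjoint diel windows:
    each hour of day is dominated by exactly one component class."""
    return (
        SoundComponent(kind="anuran_pulses", center_freq=2_000, bandwidth=400,
                       amplitude=amplitude, pulse_rate=4.0, active_hours=NOCTURNAL_HOURS),
        SoundComponent(kind="bird_chirp", center_freq=4_750, bandwidth=2_500,
                       amplitude=amplitude, pulse_rate=2.0, active_hours=BIRD_HOURS),
        SoundComponent(kind="insect_band", center_freq=6_000, bandwidth=1_000,
                       amplitude=amplitude, active_hours=INSECT_HOURS),
    )


@pytest.fixture(scope="session")
def three_class_corpus(tmp_path_factory):
    """48 one-minute files (2 recorders × 24 h), one dominant class per hour.

    Returns (manifest DataFrame, corpus spec, directory).
    """
    out = tmp_path_factory.mktemp("corpus3")
    spec = SyntheticCorpusSpec(
        n_recorders=2,
        n_days=1,
        recordings_per_hour=1,
        duration_s=60.0,
        sample_rate=22_050,
        components=three_class_components(),
        noise_floor=0.001,
        seed=11,
    )
    manifest = generate_corpus(spec, out)
    return manifest, spec, out


@pytest.fixture(scope="session")
def three_class_segments(three_class_corpus):
    """Segments + spectrograms + per-segment class labels from the corpus.

    Labels name the dominant component kind scheduled at the segment's hour.
    """
    manifest, spec, _ = three_class_corpus
    segments, spectra, labels, hours = [], [], [], []
    for _, row in manifest.iterrows():
        rec, wave = load_recording(row["path"], manifest_row=row)
        for seg in segment_recording(rec, wave):
            segments.append(seg)
            spectra.append(stft_spectrogram(seg).values)
            labels.append(row["components"])
            hours.append(seg.hour)
    return {
        "segments": segments,
        "spectra": np.asarray(spectra, dtype=np.float32),
        "labels": np.asarray(labels),
        "hours": np.asarray(hours),
    }


@pytest.fixture(scope="session")
def tone_spectrogram():
    """Spectrogram of a clean 2 kHz tone — a simple, highly structured target."""
    t = np.arange(264_600) / 22_050
    return stft_spectrogram(np.sin(2 * np.pi * 2_000 * t)).values.astype(np.float32)


@pytest.fixture(scope="session")
def small_spectrogram_batch(three_class_segments):
    """200 spectrograms for autoencoder learning-sanity checks."""
    spectra = three_class_segments["spectra"]
    reps = int(np.ceil(200 / len(spectra)))
    return np.concatenate([spectra] * reps, axis=0)[:200]


def tiny_pipeline_config(seed: int = 0):
    """One recorder, 24 one-minute files, 1 epoch, 8-d projections: small
    enough for repeated end-to-end runs."""
    from soundscape_ae import AutoencoderConfig, PipelineConfig
    from soundscape_ae.pipeline import ClusterStage, ProjectStage, SynthStage

    return PipelineConfig(
        seed=seed,
        synth=SynthStage(n_recorders=1, recordings_per_hour=1,
                         components=three_class_components()),
        cae=AutoencoderConfig(epochs=1, batch_segments=10, seed=0),
        project=ProjectStage(methods=("pca", "umap"), n_components=8),
        cluster=ClusterStage(space="umap", k=3),
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One completed end-to-end run of the tiny pipeline."""
    from soundscape_ae import run_pipeline

    out = tmp_path_factory.mktemp("run1")
    config = tiny_pipeline_config()
    return config, run_pipeline(config, out)
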