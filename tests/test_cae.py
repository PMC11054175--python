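"""Autoencoder: architecture contracts, encode/decode, splitting, checkpoints."""

import dataclasses

import numpy as np
import pytest

from soundscape_ae import (
    EMBEDDING_DIM,
    AutoencoderConfig,
    build_autoencoder,
    load_checkpoint,
    save_checkpoint,
    train,
)
from soundscape_ae.cae import split_train_test


@pytest.fixture(scope="module")
def model():
    return build_autoencoder(AutoencoderConfig(seed=0))


class TestArchitecture:
    def test_default_spatial_trace_reaches_9x9(self):
        cfg = AutoencoderConfig()
        assert cfg.spatial_trace() == [515, 172, 58, 20, 9]

    def test_bad_schedule_reports_achieved_trace(self):
        cfg = AutoencoderConfig(strides=(2, 2, 2, 2), paddings=(1, 1, 1, 1))
        with pytest.raises(ValueError, match=r"spatial trace \[515"):
            build_autoencoder(cfg)

    def test_same_seed_gives_identical_initial_weights(self):
        a = build_autoencoder(AutoencoderConfig(seed=3))
        b = build_autoencoder(AutoencoderConfig(seed=3))
        for (_, la, ka), (_, lb, kb) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(la.params[ka], lb.params[kb])

    def test_invalid_config_fields(self):
        with pytest.raises(ValueError, match="train_fraction"):
            AutoencoderConfig(train_fraction=1.2)
        with pytest.raises(ValueError, match="learning_rate"):
            AutoencoderConfig(learning_rate=0)


class TestEncodeDecode:
    def test_embedding_dimension_and_nonnegativity(self, model):
        rng = np.random.default_rng(0)
        z = model.encode(rng.random((515, 515)))
        assert z.shape == (EMBEDDING_DIM,) == (5_184,)
        assert np.all(z >= 0)  # post-ReLU

    def test_compression_ratio_is_about_two_percent(self):
        assert EMBEDDING_DIM / (515 * 515) <= 0.02

    def test_zero_input_gives_zero_embedding_in_zero_bias_model(self):
        # with biases zeroed, conv(0) = 0 and ReLU(0) = 0 through every layer
        m = build_autoencoder(AutoencoderConfig(seed=1))
        for _, layer, key in m.encoder.parameters():
            if key == "b":
                layer.params[key][:] = 0
        z = m.encode(np.zeros((515, 515)))
        assert not np.any(z)

    def test_encode_is_deterministic(self, model):
        rng = np.random.default_rng(1)
        x = rng.random((515, 515))
        np.testing.assert_array_equal(model.encode(x), model.encode(x))

    def test_decode_shape_and_sigmoid_range(self, model):
        rng = np.random.default_rng(2)
        y = model.decode(rng.standard_normal(EMBEDDING_DIM))
        assert y.shape == (515, 515)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_roundtrip_shape_contract(self, model):
        rng = np.random.default_rng(3)
        x = rng.random((2, 515, 515))
        assert model.decode(model.encode(x)).shape == (2, 515, 515)

    def test_wrong_embedding_length_raises(self, model):
        with pytest.raises(ValueError, match="5,?184|5184"):
            model.decode(np.zeros(100))

    def test_wrong_spectrogram_shape_raises(self, model):
        with pytest.raises(ValueError):
            model.encode(np.zeros((100, 100)))


class TestSplit:
    def test_two_percent_of_100_gives_two_test_items(self):
        train_idx, test_idx = split_train_test(100, 0.98, seed=0)
        assert len(test_idx) == 2 and len(train_idx) == 98

    def test_minimum_one_test_item(self):
        _, test_idx = split_train_test(12, 0.99, seed=0)
        assert len(test_idx) == 1

    def test_group_split_keeps_recordings_together(self):
        groups = [f"rec{i // 5}" for i in range(50)]  # 10 recordings x 5 segments
        train_idx, test_idx = split_train_test(50, 0.9, seed=1, groups=groups)
        train_groups = {groups[i] for i in train_idx}
        test_groups = {groups[i] for i in test_idx}
        assert not train_groups & test_groups

    def test_split_is_deterministic(self):
        a = split_train_test(40, 0.9, seed=5)
        b = split_train_test(40, 0.9, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestTraining:
    def test_needs_at_least_ten_spectrograms(self, model):
        with pytest.raises(ValueError, match="at least 10"):
            train(model, np.zeros((5, 515, 515), dtype=np.float32))

    def test_training_log_and_reproducibility(self, tone_spectrogram):
        """Two runs with identical seed and data produce identical logs."""
        data = np.repeat(tone_spectrogram[None], 12, axis=0)
        cfg = AutoencoderConfig(epochs=1, batch_segments=6, seed=7)
        logs = []
        for _ in range(2):
            m = build_autoencoder(cfg)
            logs.append(train(m, data, cfg))
        assert logs[0] == logs[1]
        splits = [row["split"] for row in logs[0]]
        assert splits.count("test") == 1 and splits[-1] == "test"

    def test_checkpoint_round_trip(self, tone_spectrogram, tmp_path):
        data = np.repeat(tone_spectrogram[None], 12, axis=0)
        cfg = AutoencoderConfig(epochs=1, batch_segments=6, seed=8)
        m = build_autoencoder(cfg)
        train(m, data, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(path, m)
        m2 = load_checkpoint(path)
        assert m2.cfg == cfg
        x = data[0]
        np.testing.assert_array_equal(m.encode(x), m2.encode(x))
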