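"""Architecture contracts: shapes, determinism, simplex head, persistence."""

import math

import numpy as np
import pytest

from stainclust.losses import (
    affine_kl_t,
    conditional_entropy_t,
    marginal_entropy_t,
    reconstruction_mse_t,
)
from stainclust.model import AutoencoderClusterer, ModelConfig, load_model, reduced_config
from stainclust.nn import Tensor


@pytest.fixture(scope="module")
def default_model():
    return AutoencoderClusterer(ModelConfig(n_clusters=14, seed=0))


@pytest.fixture(scope="module")
def small_model():
    return AutoencoderClusterer(reduced_config(4, seed=0))


@pytest.fixture
def batch():
    rng = np.random.default_rng(1)
    return rng.uniform(0, 1, size=(3, 15, 64, 64)).astype(np.float32)


@pytest.fixture
def small_batch():
    rng = np.random.default_rng(2)
    return rng.uniform(0, 1, size=(4, 15, 32, 32)).astype(np.float32)


class TestEncoder:
    def test_single_patch_gives_196_features(self, default_model, batch):
        assert default_model.encode(batch[:1]).shape == (1, 196)

    def test_deterministic(self, default_model, batch):
        np.testing.assert_array_equal(
            default_model.encode(batch), default_model.encode(batch)
        )

    def test_per_sample_independence(self, small_model, small_batch):
        doubled = np.concatenate([small_batch, small_batch])
        out = small_model.encode(doubled)
        np.testing.assert_allclose(out[: len(small_batch)], out[len(small_batch) :], atol=1e-5)

    def test_channel_mismatch_rejected(self, default_model):
        with pytest.raises(ValueError):
            default_model.encode(np.zeros((1, 6, 64, 64), dtype=np.float32))


class TestClassifier:
    def test_rows_on_simplex(self, default_model, batch):
        p = default_model.classify(default_model.encode(batch))
        assert p.shape == (3, 14)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_two_cluster_head(self):
        m = AutoencoderClusterer(reduced_config(2, seed=1))
        x = np.random.default_rng(0).uniform(size=(2, 15, 32, 32)).astype(np.float32)
        assert m.classify(m.encode(x)).shape == (2, 2)

    def test_row_entropy_bounded_by_log_k(self, default_model, batch):
        p = default_model.classify(default_model.encode(batch))
        ent = -(p * np.log(np.maximum(p, 1e-12))).sum(axis=1)
        # float32 forward pass: allow round-off at the uniform bound
        assert (ent <= math.log(14) + 1e-5).all()

    def test_dimension_mismatch_rejected(self, default_model):
        with pytest.raises(ValueError):
            default_model.classify(np.zeros((2, 17), dtype=np.float32))


class TestDecoder:
    def test_sigmoid_range_and_dims(self, small_model, small_batch):
        upper = small_model.encode(small_batch)
        lower = small_model.classify(upper)
        recon = small_model.decode(upper, lower)
        side = small_model.config.encoder_side
        assert recon.shape == (len(small_batch), 15, side, side)
        assert recon.min() >= 0 and recon.max() <= 1

    def test_deterministic(self, small_model, small_batch):
        upper = small_model.encode(small_batch)
        lower = small_model.classify(upper)
        np.testing.assert_array_equal(
            small_model.decode(upper, lower), small_model.decode(upper, lower)
        )

    def test_batch_length_mismatch_rejected(self, small_model, small_batch):
        upper = small_model.encode(small_batch)
        lower = small_model.classify(upper)
        with pytest.raises(ValueError):
            small_model.decode(upper[:2], lower)


def test_save_load_round_trip(tmp_path, small_model, small_batch):
    path = tmp_path / "ckpt.npz"
    small_model.save(path)
    restored = load_model(path)
    np.testing.assert_array_equal(
        small_model.encode(small_batch), restored.encode(small_batch)
    )
    upper = small_model.encode(small_batch)
    np.testing.assert_array_equal(
        small_model.classify(upper), restored.classify(upper)
    )


def test_every_parameter_receives_gradient(small_model, small_batch):
    """Under the combined objective every learnable tensor gets a gradient."""
    x = Tensor(small_model.prepare_input(small_batch))
    xt = Tensor(small_model.prepare_input(small_batch[::-1].copy()))
    upper = small_model.encode_t(x)
    p = small_model.classify_t(upper)
    p_t = small_model.classify_t(small_model.encode_t(xt))
    recon = small_model.decode_t(upper, p)
    total = (
        reconstruction_mse_t(x, recon)
        - (0.1 * marginal_entropy_t(p) - 0.03 * conditional_entropy_t(p))
        + 0.03 * affine_kl_t(p, p_t)
    )
    total.backward()
    for i, param in enumerate(small_model.parameters()):
        assert param.grad is not None, f"parameter {i} missing gradient"
        assert np.abs(param.grad).max() > 0, f"parameter {i} has zero gradient"


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_clusters=1)
    with pytest.raises(ValueError):
        ModelConfig(upper_dim=4, n_clusters=10)
    with pytest.raises(ValueError):
        ModelConfig(input_size=60)  # not divisible by the conv stage count


def test_rescale_preprocessing():
    cfg = reduced_config(3, seed=0)
    m = AutoencoderClusterer(cfg)
    x = np.random.default_rng(3).uniform(size=(2, 15, 32, 32)).astype(np.float32)
    prepared = m.prepare_input(x)
    assert prepared.shape == (2, 15, 16, 16)
    # block-mean downscale of a constant image is exact
    const = np.full((1, 15, 32, 32), 0.25, dtype=np.float32)
    np.testing.assert_allclose(m.prepare_input(const), 0.25, atol=1e-7)
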