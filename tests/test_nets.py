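"""Architectures, losses and training protocol contracts."""

import numpy as np
import pytest

from chorioseg.nets import (
    PatchModelConfig,
    SemanticModelConfig,
    SEMANTIC_VARIANTS,
    TrainConfig,
    build_patch_model,
    build_semantic_model,
    dice_overlap_loss,
    select_best,
    train_patch_classifier,
)
from chorioseg.nets.autodiff import Tensor
from chorioseg.nets.models import SqueezeExcite
from chorioseg.nets.training import EpochRecord


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


class TestPatchModels:
    @pytest.mark.parametrize("arch", ["cifar_cnn", "complex_cnn", "renet_rnn"])
    @pytest.mark.parametrize("size", [(32, 32), (64, 32)])
    def test_output_is_probability_vector(self, arch, size):
        model = build_patch_model(PatchModelConfig(arch, *size, seed=0))
        x = Tensor(np.random.default_rng(0).random((3, 1, *size)).astype(np.float32))
        probs = softmax(model(x, training=False).data)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (3, 4)

    def test_rnn_has_fewest_parameters(self):
        """Structural ordering: the recurrent classifier is the smallest
        model, the deeper CNN the largest."""
        sizes = {arch: build_patch_model(
            PatchModelConfig(arch, 32, 32, seed=0)).n_parameters()
            for arch in ("cifar_cnn", "complex_cnn", "renet_rnn")}
        assert sizes["renet_rnn"] < sizes["cifar_cnn"] < sizes["complex_cnn"]

    def test_same_seed_same_initial_weights(self):
        a = build_patch_model(PatchModelConfig("cifar_cnn", 32, 32, seed=5))
        b = build_patch_model(PatchModelConfig("cifar_cnn", 32, 32, seed=5))
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_odd_patch_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            PatchModelConfig("cifar_cnn", 33, 32)


class TestSemanticModels:
    def test_encoder_filter_progression(self):
        config = SemanticModelConfig(base_filters=8, n_pool=4)
        assert config.encoder_filters == (8, 16, 32, 64, 128)

    @pytest.mark.parametrize("variant", SEMANTIC_VARIANTS)
    def test_output_shape_and_normalisation(self, variant):
        model = build_semantic_model(SemanticModelConfig(variant=variant, seed=0))
        img = np.random.default_rng(0).random((32, 48)) * 255
        probs = model.predict_probs(img)
        assert probs.shape == (32, 48, 4)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_indivisible_input_reports_padding(self):
        model = build_semantic_model(SemanticModelConfig(seed=0))
        x = Tensor(np.zeros((1, 1, 30, 48), dtype=np.float32))
        with pytest.raises(ValueError, match="pad"):
            model(x, training=False)

    def test_scse_is_elementwise_max_of_cse_and_sse(self):
        rng = np.random.default_rng(0)
        scse = SqueezeExcite(8, "scse", rng, combine="max")
        x = Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
        combined = scse(x).data
        np.testing.assert_allclose(
            combined, np.maximum(scse._cse(x).data, scse._sse(x).data),
            atol=1e-7)

    def test_residual_variant_has_projection_shortcuts(self):
        std = build_semantic_model(SemanticModelConfig("standard", seed=0))
        res = build_semantic_model(SemanticModelConfig("residual", seed=0))
        assert res.n_parameters() > std.n_parameters()
        assert res.enc_blocks[0].project is not None


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        target = np.zeros((1, 8, 8), dtype=int)
        target[:, 4:] = 2
        onehot = np.zeros((1, 4, 8, 8), dtype=np.float32)
        for c in range(4):
            onehot[:, c] = target == c
        loss = float(dice_overlap_loss(onehot, target, smooth=1e-9).data)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_balanced_classes(self):
        """Uniform 0.25 probabilities against equal class areas: soft Dice
        per class is 2*0.25*A / (0.0625*4A + A) = 0.4, hence loss 0.6."""
        h = w = 8
        target = np.repeat(np.arange(4), h * w // 4).reshape(1, h, w)
        probs = np.full((1, 4, h, w), 0.25, dtype=np.float64)
        loss = float(dice_overlap_loss(probs, target, smooth=1e-12).data)
        assert loss == pytest.approx(0.6, abs=1e-6)

    def test_flip_invariance(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(1, 4, 6, 10))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        target = rng.integers(0, 4, size=(1, 6, 10))
        a = float(dice_overlap_loss(probs, target).data)
        b = float(dice_overlap_loss(probs[..., ::-1].copy(),
                                    target[..., ::-1].copy()).data)
        assert a == pytest.approx(b, rel=1e-9)

    def test_loss_in_unit_interval_and_gradient_flows(self):
        rng = np.random.default_rng(1)
        logits = Tensor(rng.normal(size=(2, 4, 8, 8)))
        from chorioseg.nets.autodiff import log_softmax
        probs = log_softmax(logits, axis=1).exp()
        target = rng.integers(0, 4, size=(2, 8, 8))
        loss = dice_overlap_loss(probs, target)
        assert 0.0 <= float(loss.data) <= 1.0
        loss.backward()
        assert np.isfinite(logits.grad).all()
        assert np.abs(logits.grad).max() > 0


class TestTrainingProtocol:
    def test_argmax_validation_selection(self):
        log = [EpochRecord(1, 1.0, 1.0, 0.7),
               EpochRecord(2, 0.8, 0.9, 0.9),
               EpochRecord(3, 0.6, 1.1, 0.8)]
        assert select_best(log) == 1

    def test_separable_toy_patches_reach_perfect_accuracy(self):
        """Bright vs dark 16x16 patches mapped onto two of the four classes
        are linearly separable; the small CNN must fit them perfectly."""
        rng = np.random.default_rng(0)
        n = 64
        x = np.empty((n, 16, 16), dtype=np.float32)
        y = np.empty(n, dtype=int)
        for i in range(n):
            bright = i % 2 == 0
            base = 200.0 if bright else 40.0
            x[i] = base + rng.normal(0, 10, (16, 16))
            y[i] = 0 if bright else 3
        x = np.clip(x, 0, 255)
        model = build_patch_model(PatchModelConfig("cifar_cnn", 16, 16, seed=0))
        config = TrainConfig(max_epochs=20, batch_size=16, seed=0)
        model, log = train_patch_classifier(model, x[:48], y[:48],
                                            x[48:], y[48:], config)
        assert len(log) == 20
        assert [rec.epoch for rec in log] == list(range(1, 21))
        assert max(rec.val_metric for rec in log) == pytest.approx(1.0)

    def test_training_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = (rng.random((32, 16, 16)) * 255).astype(np.float32)
        y = rng.integers(0, 4, 32)

        def run():
            model = build_patch_model(
                PatchModelConfig("cifar_cnn", 16, 16, seed=1))
            _, log = train_patch_classifier(
                model, x[:24], y[:24], x[24:], y[24:],
                TrainConfig(max_epochs=3, batch_size=8, seed=1))
            return [rec.train_loss for rec in log]

        assert run() == run()
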