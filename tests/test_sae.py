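"""Stacked autoencoder: gradients, shapes, reconstruction, training."""

import numpy as np
import pytest

from netgene.sae import (
    SAEConfig,
    SAEModel,
    encode,
    reconstruct,
    reconstruction_loss,
    sae_loss_and_grads,
    train_sae,
)

from oracles import finite_difference_grad, relative_error


def _manual_model(weights, biases, dims, activation="tanh"):
    return SAEModel(layer_dims=dims, activation=activation,
                    weights=[np.asarray(w, dtype=float) for w in weights],
                    biases=[np.asarray(b, dtype=float) for b in biases],
                    mean_=None, scale_=None)


class TestGradients:
    @pytest.mark.parametrize("activation", ["tanh", "sigmoid"])
    def test_backprop_matches_finite_differences(self, activation):
        """[8,4,2] autoencoder: analytic parameter gradients of the summed
        squared reconstruction error vs central differences."""
        rng = np.random.default_rng(0)
        dims = [8, 4, 2]
        Ws = [rng.normal(scale=0.5, size=(4, 8)), rng.normal(scale=0.5, size=(2, 4)),
              rng.normal(scale=0.5, size=(4, 2)), rng.normal(scale=0.5, size=(8, 4))]
        bs = [rng.normal(scale=0.1, size=s) for s in (4, 2, 4, 8)]
        X = rng.normal(size=(5, 8))
        loss, gWs, gbs = sae_loss_and_grads(Ws, bs, activation, X)
        for analytic, param in list(zip(gWs, Ws)) + list(zip(gbs, bs)):
            fd = finite_difference_grad(
                lambda: sae_loss_and_grads(Ws, bs, activation, X)[0], param
            )
            assert relative_error(analytic, fd) < 1e-5


class TestStructure:
    def test_deep_encoder_stack_yields_64_codes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 512))
        model = train_sae(X, SAEConfig(layer_dims=[512, 256, 128, 64],
                                       epochs=2, pretrain=False, seed=0))
        assert model.n_encoder_layers == 3
        assert model.bottleneck_dim == 64
        assert encode(model, X).shape == (100, 64)

    def test_zero_model_gives_zero_codes(self):
        """tanh(0) = 0: an all-zero model maps every input to zero codes."""
        m = _manual_model(
            [np.zeros((2, 4)), np.zeros((4, 2))], [np.zeros(2), np.zeros(4)], [4, 2]
        )
        codes = encode(m, np.random.default_rng(0).normal(size=(7, 4)))
        assert np.array_equal(codes, np.zeros((7, 2)))

    def test_encode_is_row_wise(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 8))
        model = train_sae(X, SAEConfig(layer_dims=[8, 3], epochs=5, seed=1))
        perm = rng.permutation(20)
        assert np.allclose(encode(model, X[perm]), encode(model, X)[perm])

    def test_width_mismatch_errors(self):
        X = np.zeros((10, 8))
        model = train_sae(np.random.default_rng(0).normal(size=(10, 8)),
                          SAEConfig(layer_dims=[8, 2], epochs=1, seed=0))
        with pytest.raises(ValueError):
            encode(model, np.zeros((3, 9)))
        with pytest.raises(ValueError):
            train_sae(X, SAEConfig(layer_dims=[9, 2], epochs=1))

    @pytest.mark.parametrize("bad_dims", [[64], [64, 128], [64, 64]])
    def test_non_decreasing_layer_dims_rejected(self, bad_dims):
        with pytest.raises(ValueError):
            SAEConfig(layer_dims=bad_dims)

    def test_non_finite_input_rejected(self):
        X = np.zeros((5, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_sae(X, SAEConfig(layer_dims=[4, 2], epochs=1))


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        # decoder bias equal to the constant input row reproduces it exactly
        row = np.array([1.0, -2.0, 0.5])
        m = _manual_model([np.zeros((2, 3)), np.zeros((3, 2))],
                          [np.zeros(2), row.copy()], [3, 2])
        X = np.tile(row, (4, 1))
        assert reconstruction_loss(m, X) == 0.0

    def test_zero_output_model_gives_input_norm(self):
        m = _manual_model([np.zeros((2, 3)), np.zeros((3, 2))],
                          [np.zeros(2), np.zeros(3)], [3, 2])
        X = np.random.default_rng(3).normal(size=(6, 3))
        assert np.isclose(reconstruction_loss(m, X), (X ** 2).sum())

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 8))
        model = train_sae(X, SAEConfig(layer_dims=[8, 4], epochs=10, seed=2))
        Xhat = reconstruct(model, X)
        naive = 0.0
        for i in range(X.shape[0]):
            for j in range(X.shape[1]):
                naive += (Xhat[i, j] - X[i, j]) ** 2
        assert abs(reconstruction_loss(model, X) - naive) < 1e-10


class TestTraining:
    def test_loss_history_non_increasing_within_tolerance(self):
        rng = np.random.default_rng(5)
        # low-rank structure so there is something to learn
        X = rng.normal(size=(200, 8)) @ rng.normal(size=(8, 64))
        model = train_sae(X, SAEConfig(layer_dims=[64, 32, 16], epochs=50,
                                       pretrain=True, seed=3))
        hist = np.asarray(model.loss_history)
        running_min = np.minimum.accumulate(hist)
        assert np.all(hist <= 1.05 * running_min)

    def test_training_beats_untrained_on_held_out_rows(self):
        rng = np.random.default_rng(6)
        basis = rng.normal(size=(6, 32))
        train = rng.normal(size=(150, 6)) @ basis
        held = rng.normal(size=(40, 6)) @ basis
        cfg = SAEConfig(layer_dims=[32, 16, 8], epochs=80, seed=4)
        trained = train_sae(train, cfg)
        untrained = train_sae(train, SAEConfig(layer_dims=[32, 16, 8], epochs=1,
                                               learning_rate=1e-12, pretrain=False,
                                               seed=4))
        assert reconstruction_loss(trained, held) < reconstruction_loss(untrained, held)

    def test_seed_determinism(self):
        X = np.random.default_rng(7).normal(size=(30, 10))
        cfg = SAEConfig(layer_dims=[10, 4], epochs=10, seed=8)
        a, b = train_sae(X, cfg), train_sae(X, cfg)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_checkpoint_round_trip(self, tmp_path):
        X = np.random.default_rng(8).normal(size=(20, 6))
        model = train_sae(X, SAEConfig(layer_dims=[6, 2], epochs=3, seed=0))
        p = tmp_path / "sae.npz"
        model.save(p)
        loaded = SAEModel.load(p)
        assert np.allclose(encode(loaded, X), encode(model, X))
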