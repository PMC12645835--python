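import numpy as np
import pytest

import demuxsig as dx
from demuxsig._nn import softmax
from demuxsig.architecture import (
    fusion_forward,
    head_forward,
    init_params,
    model_forward,
    tcn_forward,
    transformer_forward,
)
from oracles import fusion_loop


def small_random_config(rng, n_layers=1):
    return dx.ModelConfig(
        input_length=16,
        fusion_channels=(2, 3, 3),
        residual_channels=2,
        kernel_sizes=(3, 3, 3, 3),
        d_model=8,
        n_heads=2,
        n_transformer_layers=n_layers,
        ff_dim=8,
        tcn_channels=6,
        tcn_kernel=3,
        tcn_dilations=(1, 2),
        dropout=0.0,
        n_classes=3,
        mlp_hidden=5,
    )


def randomized_state(state, rng):
    """BN running stats that are not the trivial 0/1, to exercise the math."""
    for entry in state.values():
        entry["mean"] = rng.randn(*entry["mean"].shape) * 0.3
        entry["var"] = 0.5 + rng.rand(*entry["var"].shape)
    return state


class TestConfigValidation:
    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError, match="pool_factor"):
            dx.ModelConfig(input_length=510)  # not divisible by p^2
        with pytest.raises(ValueError, match="n_heads"):
            dx.ModelConfig(d_model=100, n_heads=3)
        with pytest.raises(ValueError, match="dilations"):
            dx.ModelConfig(tcn_dilations=())

    def test_param_count_is_reproducible(self, tiny_config):
        assert dx.param_count(tiny_config) == dx.param_count(tiny_config)
        model = dx.DemuxTransModel(tiny_config, seed=9)
        assert model.n_parameters() == dx.param_count(tiny_config)


class TestFusion:
    def test_path_lengths(self, tiny_config, rng):
        params, state = init_params(tiny_config, seed=0)
        x = rng.randn(2, 1, 16)
        fused = fusion_forward(x, tiny_config, params, state, mode="eval")
        assert fused.path_lengths == {"x1": 8, "x2": 4, "x3": 4,
                                      "r1": 4, "r2": 4, "fused": 4}
        assert fused.features.shape == (2, tiny_config.fused_channels, 4)

    def test_all_ones_unit_weights(self):
        # single-channel paths, kernel 1, unit weights, identity BN:
        # every stream stays exactly at ELU(1)=1
        cfg = dx.ModelConfig(
            input_length=16, fusion_channels=(1, 1, 1), residual_channels=1,
            kernel_sizes=(1, 1, 1, 1), d_model=4, n_heads=1, ff_dim=4,
            tcn_channels=4, tcn_dilations=(1,), n_classes=2, mlp_hidden=3,
        )
        params, state = init_params(cfg, seed=0)
        for conv in ("conv1", "conv2", "conv3", "convr1"):
            params["fusion"][conv]["W"] = np.ones_like(params["fusion"][conv]["W"])
            params["fusion"][conv]["b"] = np.zeros_like(params["fusion"][conv]["b"])
        x = np.ones((1, 1, 16))
        fused = fusion_forward(x, cfg, params, state, mode="eval")
        np.testing.assert_allclose(fused.features, 1.0, atol=1e-4)

    def test_matches_loop_oracle(self):
        # vectorized implementation vs straight-line re-derivation
        rng = np.random.RandomState(42)
        worst = 0.0
        for trial in range(20):
            cfg = small_random_config(rng)
            params, state = init_params(cfg, seed=trial)
            randomized_state(state, rng)
            x = rng.randn(rng.randint(1, 3), 1, cfg.input_length)
            fused = fusion_forward(x, cfg, params, state, mode="eval")
            expected = fusion_loop(x, params, state, cfg.pool_factor)
            worst = max(worst, float(np.max(np.abs(fused.features - expected))))
        assert worst < 1e-5

    def test_length_mismatch_errors(self, tiny_config, rng):
        params, state = init_params(tiny_config, seed=0)
        with pytest.raises(ValueError, match="length"):
            fusion_forward(rng.randn(1, 1, 20), tiny_config, params, state)


class TestTransformer:
    def test_attention_shape_and_rows(self, tiny_config, rng):
        params, state = init_params(tiny_config, seed=1)
        x = rng.randn(3, 1, 16)
        fused = fusion_forward(x, tiny_config, params, state, mode="eval")
        out, attn = transformer_forward(fused, tiny_config, params, mode="eval")
        T = tiny_config.n_positions
        assert out.shape == (3, tiny_config.d_model, T)
        assert attn.shape == (3, 1, tiny_config.n_heads, T, T)
        assert np.all(attn >= 0)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_layers_is_projection_plus_encoding(self, rng):
        cfg = small_random_config(rng, n_layers=0)
        params, state = init_params(cfg, seed=0)
        fused = fusion_forward(rng.randn(2, 1, 16), cfg, params, state, mode="eval")
        out, attn = transformer_forward(fused, cfg, params, mode="eval")
        from demuxsig._nn import linear, sinusoidal_encoding
        h = np.transpose(fused.features, (0, 2, 1))
        expected = linear(h, params["proj"]["W"], params["proj"]["b"])
        expected = expected + sinusoidal_encoding(cfg.n_positions, cfg.d_model)[None]
        np.testing.assert_array_equal(out, np.transpose(expected, (0, 2, 1)))
        assert attn.shape[1] == 0

    def test_attention_tensor_validates_rows(self):
        bad = np.full((1, 1, 2, 2), 0.3)
        with pytest.raises(ValueError, match="sum"):
            dx.AttentionTensor(weights=bad)


class TestTCN:
    def test_strict_causality(self, rng):
        # perturbing the last position never touches earlier outputs
        cfg = small_random_config(rng)
        for trial in range(20):
            params, _ = init_params(cfg, seed=trial)
            x = rng.randn(1, cfg.d_model, 32)
            base = tcn_forward(x, cfg, params, mode="eval")
            pert = x.copy()
            pert[0, :, -1] += rng.randn(cfg.d_model)
            out2 = tcn_forward(pert, cfg, params, mode="eval")
            assert np.max(np.abs(np.asarray(base)[:, :, :-1] -
                                 np.asarray(out2)[:, :, :-1])) == 0.0

    def test_receptive_field_bound(self, rng):
        # kernel 3, dilations (1,2,4), two convs per block:
        # receptive field behind t is 2 * sum((3-1)*d) = 28
        cfg = dx.ModelConfig(
            input_length=16, fusion_channels=(2, 2, 2), residual_channels=2,
            kernel_sizes=(3, 3, 3, 3), d_model=8, n_heads=2, ff_dim=8,
            tcn_channels=8, tcn_kernel=3, tcn_dilations=(1, 2, 4),
            dropout=0.0, n_classes=2, mlp_hidden=4,
        )
        params, _ = init_params(cfg, seed=0)
        T, t = 64, 60
        x = rng.randn(1, cfg.d_model, T)
        base = np.asarray(tcn_forward(x, cfg, params, mode="eval"))
        pert = x.copy()
        pert[0, :, : t - 28] += rng.randn(cfg.d_model, t - 28)
        out = np.asarray(tcn_forward(pert, cfg, params, mode="eval"))
        assert np.max(np.abs(base[0, :, t:] - out[0, :, t:])) == 0.0
        # and a perturbation just inside the field does propagate
        pert2 = x.copy()
        pert2[0, :, t - 1] += 1.0
        out2 = np.asarray(tcn_forward(pert2, cfg, params, mode="eval"))
        assert np.max(np.abs(base[0, :, t:] - out2[0, :, t:])) > 0.0

    def test_preserves_temporal_length(self, tiny_config, rng):
        params, _ = init_params(tiny_config, seed=0)
        x = rng.randn(2, tiny_config.d_model, 11)
        out = tcn_forward(x, tiny_config, params, mode="eval")
        assert np.asarray(out).shape == (2, tiny_config.tcn_channels, 11)


class TestHeadAndModel:
    def test_constant_features_pool_to_identity(self, tiny_config, rng):
        params, _ = init_params(tiny_config, seed=0)
        vec = rng.randn(tiny_config.tcn_channels)
        x = np.tile(vec[None, :, None], (1, 1, 7))
        out = head_forward(x, tiny_config, params, mode="eval")
        from demuxsig._nn import elu, linear
        hp = params["head"]
        expected = linear(elu(linear(vec[None], hp["fc1"]["W"], hp["fc1"]["b"])),
                          hp["fc2"]["W"], hp["fc2"]["b"])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_head_weights_give_uniform_softmax(self, tiny_config, rng):
        params, state = init_params(tiny_config, seed=0)
        params["head"]["fc2"]["W"] = np.zeros_like(params["head"]["fc2"]["W"])
        params["head"]["fc2"]["b"] = np.zeros_like(params["head"]["fc2"]["b"])
        logits = model_forward(rng.randn(2, 1, 16), tiny_config, params, state)
        np.testing.assert_array_equal(logits, 0.0)
        np.testing.assert_allclose(softmax(logits, axis=1), 1 / 3, atol=1e-12)

    def test_eval_forward_deterministic_and_permutable(self, tiny_config, rng):
        model = dx.DemuxTransModel(tiny_config, seed=2)
        x = rng.randn(5, 1, 16)
        a = np.asarray(model.forward(x, mode="eval"))
        b = np.asarray(model.forward(x, mode="eval"))
        np.testing.assert_array_equal(a, b)
        # per-read independence: permuting the batch permutes the logits
        # (einsum blocking over the batch axis allows ~1e-15 float jitter)
        perm = rng.permutation(5)
        c = np.asarray(model.forward(x[perm], mode="eval"))
        np.testing.assert_allclose(c, a[perm], atol=1e-12)

    def test_batch_size_independence(self, tiny_config, rng):
        model = dx.DemuxTransModel(tiny_config, seed=2)
        x = rng.randn(8, 1, 16)
        full = np.asarray(model.forward(x, mode="eval"))
        single = np.asarray(model.forward(x[:1], mode="eval"))
        assert np.max(np.abs(full[0] - single[0])) < 1e-5


class TestCheckpoint:
    def test_roundtrip(self, tiny_config, tmp_path, rng):
        model = dx.DemuxTransModel(tiny_config, seed=5)
        path = tmp_path / "ckpt.npz"
        dx.save_checkpoint(model, path)
        back = dx.load_checkpoint(path)
        assert back.config == tiny_config
        x = rng.randn(2, 1, 16)
        np.testing.assert_array_equal(
            np.asarray(model.forward(x)), np.asarray(back.forward(x)))

    def test_rejects_non_checkpoint(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, a=np.zeros(3))
        with pytest.raises(ValueError, match="checkpoint"):
            dx.load_checkpoint(path)
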