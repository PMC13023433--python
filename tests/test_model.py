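"""Decoder architecture: parameter accounting, stage shape contracts,
patch arithmetic, attention behavior, and forward-pass invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mibci import _autodiff as ad
from mibci.model import (
    CBTNet,
    InvalidConfigError,
    DimensionError,
    ModelConfig,
    count_parameters,
    derive_temporal_length,
    estimate_macs,
    load_checkpoint,
    n_patches,
    save_checkpoint,
    sinusoidal_encoding,
)

TABLE_COUNTS = {
    "spatial_spectral": 137_696,
    "temporal_encoder": 659_456,
    "patch_embedding": 786_816,
    "transformer_encoder": 265_216,
    "classification_head": 17_028,
    "total": 1_866_212,
}


class TestParameterCounting:
    def test_default_breakdown_published_values(self):
        assert count_parameters(ModelConfig()).as_dict() == TABLE_COUNTS

    def test_counts_match_actual_arrays(self, tiny_config):
        model = CBTNet(tiny_config, seed=0)
        assert (
            model.parameter_breakdown_from_arrays().as_dict()
            == count_parameters(tiny_config).as_dict()
        )

    def test_degenerate_network_hand_enumeration(self):
        """All widths 1, kernel 1, 1 class: every scalar weight by hand."""
        cfg = ModelConfig(
            n_channels=1, n_samples=16, conv_out_channels=(1, 1, 1, 1),
            conv_kernel=1, lstm_hidden=1, lstm_layers=1, patch_size=1,
            stride=1, embed_dim=1, n_heads=1, tf_layers=1, ff_dim=2,
            n_classes=1,
        )
        pb = count_parameters(cfg)
        # conv: 4 blocks x (1 kernel + 1 bias + 2 norm) = 16
        assert pb.spatial_spectral == 16
        # lstm: 2 dirs x 4 gates x (1 in + 1 rec + 2 biases) = 32
        assert pb.temporal_encoder == 32
        # patch: (1*2*1)=2 proj + 1 bias + 2 norm = 5
        assert pb.patch_embedding == 5
        # tf: 4x(1+1) proj + (1*2+2 + 2*1+1) ff + 2x2 norms + 2 final = 21
        assert pb.transformer_encoder == 21
        # head: 1+1 and 1+1
        assert pb.classification_head == 4
        assert pb.total == 78


class TestTemporalLength:
    @pytest.mark.parametrize("T,expected", [(1000, 62), (16, 1), (160, 10)])
    def test_examples(self, T, expected):
        assert derive_temporal_length(T, ModelConfig()) == expected

    def test_collapse_raises(self):
        with pytest.raises(InvalidConfigError):
            derive_temporal_length(8, ModelConfig())

    def test_too_short_raises(self):
        with pytest.raises(InvalidConfigError):
            derive_temporal_length(3, ModelConfig())


class TestPatchArithmetic:
    @pytest.mark.parametrize(
        "tprime,p,s,expected", [(62, 24, 12, 4), (62, 62, 1, 1), (62, 10, 8, 7)]
    )
    def test_examples(self, tprime, p, s, expected):
        assert n_patches(tprime, p, s) == expected

    def test_oversized_patch_raises(self):
        with pytest.raises(InvalidConfigError):
            n_patches(10, 11, 1)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 50))
    def test_last_patch_fits_and_is_maximal(self, tprime, p, s):
        """p + (N-1)s <= T' and one more patch would overrun."""
        if p > tprime:
            return
        s = min(s, p)
        N = n_patches(tprime, p, s)
        assert p + (N - 1) * s <= tprime
        assert p + N * s > tprime
        # brute-force sliding-window enumeration agrees
        brute = sum(1 for start in range(0, tprime, s) if start + p <= tprime)
        assert N == brute


class TestConfigValidation:
    def test_head_divisibility(self):
        with pytest.raises(InvalidConfigError):
            ModelConfig(embed_dim=64, n_heads=6)

    def test_stride_bounds(self):
        with pytest.raises(InvalidConfigError):
            ModelConfig(stride=30, patch_size=24)

    def test_dropout_range(self):
        with pytest.raises(InvalidConfigError):
            ModelConfig(conv_dropout=1.0)

    def test_patch_exceeding_temporal_length(self):
        with pytest.raises(InvalidConfigError):
            ModelConfig(n_samples=64, patch_size=24)  # T' = 4 < 24


class TestStages:
    def test_spatial_spectral_default_shape(self):
        """22 x 1000 input maps to a 128 x 62 feature map."""
        model = CBTNet(ModelConfig(), seed=0)
        X = np.random.default_rng(0).normal(size=(22, 1000))
        F = model.encode_spatial_spectral(X)
        assert F.shape == (128, 62)

    def test_shape_contract_value_independent(self, tiny_model, rng):
        a = tiny_model.encode_spatial_spectral(rng.normal(size=(3, 64)))
        b = tiny_model.encode_spatial_spectral(rng.normal(size=(3, 64)) * 50)
        assert a.shape == b.shape

    def test_shape_mismatch_raises(self, tiny_model):
        with pytest.raises(DimensionError):
            tiny_model.encode_spatial_spectral(np.zeros((5, 64)))

    def test_zero_kernels_give_zero_features(self, tiny_config, rng):
        model = CBTNet(tiny_config, seed=0)
        for i in range(4):
            model.params[f"conv.{i}.W"].data[:] = 0.0
            model.params[f"conv.{i}.b"].data[:] = 0.0
            model.params[f"conv.{i}.beta"].data[:] = 0.0
        F = model.encode_spatial_spectral(rng.normal(size=(3, 64)), bn_mode="batch")
        assert np.allclose(F.data, 0.0)

    def test_temporal_output_shape(self, tiny_model, rng):
        F = rng.normal(size=(6, 4))  # D x T'
        H = tiny_model.encode_temporal(F)
        assert H.shape == (4, 2 * tiny_model.config.lstm_hidden)

    def test_temporal_default_width(self):
        cfg = ModelConfig()
        model = CBTNet(cfg, seed=0)
        F = np.random.default_rng(0).normal(size=(128, 62)) * 0.1
        H = model.encode_temporal(F)
        assert H.shape == (62, 256)

    def test_tied_weights_time_reversal_symmetry(self, rng):
        """With backward weights tied to forward ones, reversing the input
        in time and swapping the output halves reproduces the output.
        (Single recurrent layer: deeper layers see direction-ordered
        inputs, which breaks the symmetry by construction.)"""
        tiny_config = ModelConfig(
            n_channels=3, n_samples=64, conv_out_channels=(4, 4, 6, 6),
            lstm_hidden=5, lstm_layers=1, patch_size=2, stride=1, embed_dim=8,
            tf_layers=1, n_heads=2, n_classes=3, conv_dropout=0.0,
            lstm_dropout=0.0, tf_dropout=0.0,
        )
        model = CBTNet(tiny_config, seed=2)
        for layer in range(tiny_config.lstm_layers):
            for name in ("Wx", "Wh", "bx", "bh"):
                model.params[f"lstm.l{layer}.bw.{name}"] = model.params[
                    f"lstm.l{layer}.fw.{name}"
                ]
        F = rng.normal(size=(6, 4))
        H = model.encode_temporal(F).data
        H_rev = model.encode_temporal(F[:, ::-1].copy()).data
        dh = tiny_config.lstm_hidden
        swapped = np.concatenate([H_rev[::-1, dh:], H_rev[::-1, :dh]], axis=1)
        np.testing.assert_allclose(H, swapped, atol=1e-12)

    def test_zero_recurrence_rows_identical(self, tiny_config):
        """No input/state coupling: every time step sits at the bias-driven
        fixed point, identical across t."""
        model = CBTNet(tiny_config, seed=0)
        for layer in range(tiny_config.lstm_layers):
            for d in ("fw", "bw"):
                model.params[f"lstm.l{layer}.{d}.Wx"].data[:] = 0.0
                model.params[f"lstm.l{layer}.{d}.Wh"].data[:] = 0.0
        H = model.encode_temporal(np.zeros((6, 4))).data
        for t in range(1, 4):
            np.testing.assert_allclose(H[0], H[t], atol=1e-12)

    def test_tokenizer_patch_count_and_dim(self, tiny_model, rng):
        H = rng.normal(size=(4, 10))  # T'=4, 2dh=10
        Z = tiny_model.tokenize_patches(H)
        cfg = tiny_model.config
        expected_n = n_patches(4, cfg.patch_size, cfg.stride)
        assert Z.shape == (expected_n, cfg.embed_dim)

    def test_positional_encoding_deterministic(self):
        a = sinusoidal_encoding(7, 16)
        b = sinusoidal_encoding(7, 16)
        assert np.array_equal(a, b)
        assert a.shape == (7, 16)


class TestTransformer:
    def test_attention_rows_sum_to_one(self, tiny_model, rng):
        Z = rng.normal(size=(5, 8))
        att = tiny_model.attention_weights(Z, layer=0)
        np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-9)

    def test_single_token_attention_is_identity_weight(self, tiny_model, rng):
        att = tiny_model.attention_weights(rng.normal(size=(1, 8)), layer=0)
        np.testing.assert_allclose(att, 1.0, atol=1e-12)

    def test_permutation_invariance_without_positions(self, tiny_model, rng):
        """Mean-pooled output ignores token order when no positional
        information is added."""
        Z = rng.normal(size=(5, 8))
        perm = rng.permutation(5)
        a = tiny_model.apply_transformer(Z).data
        b = tiny_model.apply_transformer(Z[perm]).data
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestForward:
    def test_posterior_normalization(self, tiny_model, rng):
        post = tiny_model.forward(rng.normal(size=(3, 64)))
        assert post.shape == (3,)
        assert post.data.sum() == pytest.approx(1.0, abs=1e-6)
        assert (post.data >= 0).all()

    def test_posterior_normalization_many_random_trials(self, tiny_model, rng):
        X = rng.normal(size=(1000, 3, 64))
        probs = tiny_model.predict_proba(X, batch_size=250)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_uniform_posterior(self, tiny_config, rng):
        model = CBTNet(tiny_config, seed=0)
        model.params["head.W2"].data[:] = 0.0
        model.params["head.b2"].data[:] = 0.0
        post = model.forward(rng.normal(size=(3, 64)))
        np.testing.assert_allclose(post.data, 1.0 / 3.0, atol=1e-12)

    def test_argmax_matches_logits(self, tiny_model, rng):
        X = rng.normal(size=(8, 3, 64))
        logits = tiny_model.logits(X).data
        post = tiny_model.forward(X).data
        assert np.array_equal(logits.argmax(axis=1), post.argmax(axis=1))

    def test_forward_equals_manual_stage_chain(self, tiny_model, rng):
        X = rng.normal(size=(2, 3, 64))
        F = tiny_model.encode_spatial_spectral(X)
        H = tiny_model.encode_temporal(F)
        Z = tiny_model.tokenize_patches(H)
        pooled = tiny_model.apply_transformer(Z)
        h = ad.add(ad.matmul(pooled, tiny_model.params["head.W1"]),
                   tiny_model.params["head.b1"])
        h = ad.gelu(h)
        logits = ad.add(ad.matmul(h, tiny_model.params["head.W2"]),
                        tiny_model.params["head.b2"])
        manual = ad.softmax(logits, axis=-1).data
        assert np.array_equal(manual, tiny_model.forward(X).data)

    def test_seed_determinism(self, tiny_config, rng):
        X = rng.normal(size=(2, 3, 64))
        a = CBTNet(tiny_config, seed=9)
        b = CBTNet(tiny_config, seed=9)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)
        assert np.array_equal(a.forward(X).data, b.forward(X).data)


class TestMACs:
    def test_default_total_in_expected_band(self):
        total = estimate_macs(ModelConfig()).total
        assert 0.05e9 <= total <= 0.09e9

    def test_conv_macs_roughly_linear_in_T(self):
        a = estimate_macs(ModelConfig(n_samples=1000)).spatial_spectral
        b = estimate_macs(ModelConfig(n_samples=2000)).spatial_spectral
        assert b == pytest.approx(2 * a, rel=0.01)

    def test_head_macs_are_affine_map_products(self):
        cfg = ModelConfig()
        assert estimate_macs(cfg).classification_head == 128 * 128 + 128 * 4


class TestCheckpoint:
    def test_roundtrip(self, tiny_config, tmp_path, rng):
        model = CBTNet(tiny_config, seed=4)
        X = rng.normal(size=(2, 3, 64))
        before = model.forward(X).data
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == tiny_config
        np.testing.assert_array_equal(loaded.forward(X).data, before)
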