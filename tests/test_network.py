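import copy

import numpy as np
import pytest

from somnofuse.network import (
    AttentionParams,
    BackboneConfig,
    ModelConfig,
    SleepStageModel,
    attention_weights,
    block_output_lengths,
    conv_output_length,
    encode_previous_stage,
    fuse_residual,
    fuse_variant,
    uniform_stage_vector,
)
from somnofuse.training import cross_entropy_loss

FULL_BLOCKS = ((5, 3, 64), (5, 3, 64), (3, 2, 128), (3, 1, 128), (3, 1, 256))


class TestConvArithmetic:
    @pytest.mark.parametrize(
        "L,k,s,expected",
        [(3000, 5, 3, 999), (163, 3, 1, 161), (10, 1, 1, 10)],
    )
    def test_examples(self, L, k, s, expected):
        assert conv_output_length(L, k, s) == expected

    def test_input_shorter_than_kernel_errors(self):
        with pytest.raises(ValueError):
            conv_output_length(4, 5, 1)

    def test_shape_chain_100hz(self):
        assert block_output_lengths(3000, FULL_BLOCKS) == [999, 332, 165, 163, 161]

    def test_shape_chain_128hz(self):
        assert block_output_lengths(3840, FULL_BLOCKS) == [1279, 425, 212, 210, 208]


class TestBackbone:
    @pytest.mark.parametrize(
        "input_len,expected_lengths",
        [(3000, [999, 332, 165, 163, 161]), (3840, [1279, 425, 212, 210, 208])],
    )
    def test_forward_temporal_lengths_match_arithmetic(self, input_len, expected_lengths, rng):
        cfg = ModelConfig(input_len=input_len, n_channels=1, seed=0)
        model = SleepStageModel(cfg)
        cache = {}
        model.forward(rng.standard_normal((1, input_len, 1)), uniform_stage_vector(),
                      cache_out=cache)
        observed = [cache[f"branch0.block{j}.relu_mask"].shape[1] for j in range(5)]
        assert observed == expected_lengths

    def test_feature_length_is_final_filter_count(self, rng):
        cfg = ModelConfig(input_len=3000, n_channels=1, seed=0)
        model = SleepStageModel(cfg)
        v = model.extract_features(rng.standard_normal(3000))
        assert v.shape == (256,)

    def test_zero_input_gives_deterministic_nonnegative_relu_path(self, tiny_model):
        x = np.zeros(20)
        a = tiny_model.extract_features(x, branch_id=0)
        b = tiny_model.extract_features(x, branch_id=0)
        np.testing.assert_array_equal(a, b)
        assert np.isfinite(a).all()

    def test_wrong_input_length_names_expected(self, tiny_model):
        with pytest.raises(ValueError, match="20"):
            tiny_model.extract_features(np.zeros(21))

    def test_branches_have_distinct_parameters(self, tiny_model):
        w0 = tiny_model.params["branch0.block0.W"]
        w1 = tiny_model.params["branch1.block0.W"]
        assert not np.allclose(w0, w1)


def random_attention_params(rng, C, F):
    return AttentionParams(
        W_iv=[rng.standard_normal((F, F)) for _ in range(C)],
        W=rng.standard_normal((F, F * C)),
        b=rng.standard_normal(F),
        w_is=[rng.standard_normal(F) for _ in range(C)],
    )


class TestAttention:
    def test_single_channel_weight_is_one(self, rng):
        params = random_attention_params(rng, 1, 8)
        alpha = attention_weights([rng.standard_normal((3, 8))], params)
        np.testing.assert_allclose(alpha, 1.0)

    def test_identical_channels_and_params_give_uniform_weights(self, rng):
        F, C = 8, 4
        shared_Wiv = rng.standard_normal((F, F))
        shared_wis = rng.standard_normal(F)
        params = AttentionParams(
            W_iv=[shared_Wiv] * C, W=rng.standard_normal((F, F * C)),
            b=rng.standard_normal(F), w_is=[shared_wis] * C,
        )
        v = rng.standard_normal((5, F))
        alpha = attention_weights([v] * C, params)
        np.testing.assert_allclose(alpha, 0.25, atol=1e-12)

    def test_matches_straightforward_reference_evaluation(self, rng):
        # independent loop-based oracle for the score/softmax equations
        F, C, B = 6, 3, 4
        params = random_attention_params(rng, C, F)
        v = [rng.standard_normal((B, F)) for _ in range(C)]
        alpha = attention_weights(v, params)
        for b in range(B):
            V = np.concatenate([vi[b] for vi in v])
            scores = []
            for i in range(C):
                z = params.W_iv[i] @ v[i][b] + params.W @ V + params.b
                scores.append(params.w_is[i] @ np.maximum(z, 0.0))
            expected = np.exp(scores) / np.exp(scores).sum()
            np.testing.assert_allclose(alpha[b], expected, atol=1e-10)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        assert (alpha >= 0).all()

    def test_extreme_scores_stay_stable(self, rng):
        params = random_attention_params(rng, 2, 4)
        v = [rng.standard_normal((2, 4)) * 1e4 for _ in range(2)]
        alpha = attention_weights(v, params)
        assert np.isfinite(alpha).all()
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)


class TestFusion:
    def test_identical_features_fuse_to_twice_v(self, rng):
        v = rng.standard_normal((3, 8))
        alpha = rng.dirichlet(np.ones(4), size=3)
        fused = fuse_residual([v, v, v, v], alpha)
        np.testing.assert_allclose(fused, 2 * v, atol=1e-10)

    def test_one_hot_alpha_gives_avg_plus_selected(self, rng):
        v = [rng.standard_normal((2, 5)) for _ in range(3)]
        alpha = np.zeros((2, 3))
        alpha[:, 1] = 1.0
        fused = fuse_residual(v, alpha)
        v_avg = np.mean(v, axis=0)
        np.testing.assert_allclose(fused, v_avg + v[1], atol=1e-12)

    def test_zero_features_fuse_to_zero(self):
        v = [np.zeros((2, 4))] * 3
        alpha = np.full((2, 3), 1 / 3)
        np.testing.assert_array_equal(fuse_residual(v, alpha), 0.0)

    def test_alpha_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            fuse_residual([rng.standard_normal((2, 4))] * 3, np.ones((2, 2)) / 2)

    def test_average_mode(self):
        v = [np.full((1, 4), 1.0), np.full((1, 4), 3.0)]
        np.testing.assert_allclose(fuse_variant(v, "average"), 2.0)

    def test_concat_mode_length(self, rng):
        v = [rng.standard_normal((2, 256)) for _ in range(4)]
        assert fuse_variant(v, "concat").shape == (2, 1024)

    def test_attention_only_is_residual_minus_average(self, rng):
        v = [rng.standard_normal((3, 6)) for _ in range(4)]
        alpha = rng.dirichlet(np.ones(4), size=3)
        res = fuse_variant(v, "residual_attention", alpha)
        att = fuse_variant(v, "attention_only", alpha)
        avg = fuse_variant(v, "average")
        np.testing.assert_allclose(att, res - avg, atol=1e-10)

    def test_unknown_mode(self, rng):
        with pytest.raises(ValueError, match="unknown fusion mode"):
            fuse_variant([rng.standard_normal((1, 2))], "median")


class TestStageEncoder:
    def test_distinct_stages_encode_distinctly(self, rng):
        E, b = rng.standard_normal((16, 5)), rng.standard_normal(16)
        w = encode_previous_stage(np.eye(5)[0], E, b)
        rem = encode_previous_stage(np.eye(5)[4], E, b)
        assert not np.allclose(w, rem)

    def test_zero_vector_returns_bias(self, rng):
        E, b = rng.standard_normal((16, 5)), rng.standard_normal(16)
        np.testing.assert_allclose(encode_previous_stage(np.zeros(5), E, b), b)

    def test_uniform_is_mean_of_one_hots(self, rng):
        E, b = rng.standard_normal((16, 5)), rng.standard_normal(16)
        uniform = encode_previous_stage(np.full(5, 0.2), E, b)
        mean = np.mean([encode_previous_stage(np.eye(5)[k], E, b) for k in range(5)], axis=0)
        np.testing.assert_allclose(uniform, mean, atol=1e-12)

    def test_wrong_length_errors(self, rng):
        E, b = rng.standard_normal((16, 5)), rng.standard_normal(16)
        with pytest.raises(ValueError):
            encode_previous_stage(np.full(4, 0.25), E, b)


class TestClassifierHead:
    def _logits(self, model, v_c, fused):
        logits = fused @ model.params["cls.Wf"].T + model.params["cls.b"]
        logits = logits + v_c @ model.params["cls.Wc"].T
        return logits

    def test_eq5_additivity_in_inference_mode(self, tiny_model, rng):
        """logits(vc,f) - logits(0,f) - logits(vc,0) + logits(0,0) == 0."""
        F = tiny_model.config.fused_dim
        E = tiny_model.config.enc_dim
        v_c = rng.standard_normal((4, E))
        fused = rng.standard_normal((4, F))
        zeros_c, zeros_f = np.zeros_like(v_c), np.zeros_like(fused)
        combo = (
            self._logits(tiny_model, v_c, fused)
            - self._logits(tiny_model, zeros_c, fused)
            - self._logits(tiny_model, v_c, zeros_f)
            + self._logits(tiny_model, zeros_c, zeros_f)
        )
        np.testing.assert_allclose(combo, 0.0, atol=1e-5)

    def test_probability_simplex_output(self, tiny_model, rng):
        probs = tiny_model.classify(
            rng.standard_normal(tiny_model.config.enc_dim),
            rng.standard_normal(tiny_model.config.fused_dim),
        )
        assert probs.shape == (5,)
        assert (probs >= 0).all()
        assert abs(probs.sum() - 1) < 1e-6

    def test_refinement_is_active_with_zero_fusion(self, tiny_model):
        E = tiny_model.params["enc.E"]
        b = tiny_model.params["enc.b"]
        fused = np.zeros(tiny_model.config.fused_dim)
        p_w = tiny_model.classify(encode_previous_stage(np.eye(5)[0], E, b), fused)
        p_rem = tiny_model.classify(encode_previous_stage(np.eye(5)[4], E, b), fused)
        assert not np.allclose(p_w, p_rem)

    def test_dropout_only_in_train_mode(self, tiny_model, rng):
        v_c = rng.standard_normal(tiny_model.config.enc_dim)
        fused = rng.standard_normal(tiny_model.config.fused_dim)
        a = tiny_model.classify(v_c, fused, train_mode=False)
        b = tiny_model.classify(v_c, fused, train_mode=False)
        np.testing.assert_array_equal(a, b)
        c = tiny_model.classify(v_c, fused, train_mode=True,
                                rng=np.random.default_rng(1))
        d = tiny_model.classify(v_c, fused, train_mode=True,
                                rng=np.random.default_rng(2))
        assert not np.allclose(c, d)


class TestModelForward:
    def test_output_on_simplex(self, tiny_model, rng):
        probs = tiny_model.forward(
            rng.standard_normal((6, 20, 3)), uniform_stage_vector()
        )
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_channel_permutation_invariance(self, rng, tiny_config):
        """Permuting channels and branch/attention params together leaves the
        fused output unchanged."""
        model = SleepStageModel(tiny_config)
        x = rng.standard_normal((2, 20, 3))
        perm = [2, 0, 1]
        permuted = SleepStageModel(tiny_config)
        permuted.params = copy.deepcopy(model.params)
        permuted.state = copy.deepcopy(model.state)
        for new_i, old_i in enumerate(perm):
            for j in range(len(tiny_config.backbone.blocks)):
                for name in ("W", "gamma", "beta"):
                    permuted.params[f"branch{new_i}.block{j}.{name}"] = model.params[
                        f"branch{old_i}.block{j}.{name}"
                    ].copy()
                for name in ("running_mean", "running_var"):
                    permuted.state[f"branch{new_i}.block{j}.{name}"] = model.state[
                        f"branch{old_i}.block{j}.{name}"
                    ].copy()
            permuted.params[f"att.Wiv{new_i}"] = model.params[f"att.Wiv{old_i}"].copy()
            permuted.params[f"att.wis{new_i}"] = model.params[f"att.wis{old_i}"].copy()
        # shared W mixes the concatenated V: permute its column blocks too
        F = tiny_config.feature_dim
        W = model.params["att.W"]
        permuted.params["att.W"] = np.concatenate(
            [W[:, old_i * F : (old_i + 1) * F] for old_i in perm], axis=1
        )
        base = model.forward(x, uniform_stage_vector())
        swapped = permuted.forward(x[:, :, perm], uniform_stage_vector())
        np.testing.assert_allclose(base, swapped, atol=1e-10)

    @pytest.mark.parametrize("fusion", ["average", "concat", "attention_only",
                                        "residual_attention", "data"])
    def test_gradients_match_finite_differences(self, fusion, rng):
        cfg = ModelConfig(
            input_len=20, n_channels=3,
            backbone=BackboneConfig(blocks=((3, 2, 4), (3, 1, 6))),
            fusion=fusion, dropout=0.0, seed=1,
        )
        model = SleepStageModel(cfg)
        X = rng.standard_normal((4, 20, 3))
        prev = rng.dirichlet(np.ones(5), size=4)
        yi = rng.integers(0, 5, 4)
        y = np.eye(5)[yi]
        state0 = copy.deepcopy(model.state)

        def loss():
            model.state = copy.deepcopy(state0)  # keep loss a pure fn of params
            cache = {}
            probs = model.forward(X, prev, train=True, cache_out=cache)
            return cross_entropy_loss(y, probs), cache

        base_loss, cache = loss()
        grads = model.backward(cache, y)
        eps = 1e-6
        check_rng = np.random.default_rng(5)
        for key, p in model.params.items():
            flat = check_rng.integers(0, p.size)
            idx = np.unravel_index(flat, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up, _ = loss()
            p[idx] = orig - eps
            down, _ = loss()
            p[idx] = orig
            numeric = (up - down) / (2 * eps)
            denom = max(1e-6, abs(numeric) + abs(grads[key][idx]))
            assert abs(numeric - grads[key][idx]) / denom < 1e-4, key

    def test_checkpoint_roundtrip(self, tiny_model, tmp_path, rng):
        x = rng.standard_normal((2, 20, 3))
        before = tiny_model.forward(x, uniform_stage_vector())
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        fresh = SleepStageModel(tiny_model.config)
        fresh.load(path)
        np.testing.assert_array_equal(before, fresh.forward(x, uniform_stage_vector()))

    def test_invalid_fusion_mode_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_len=20, n_channels=2, fusion="sum",
                        backbone=BackboneConfig(blocks=((3, 2, 4),)))
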