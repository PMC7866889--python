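import math

import numpy as np
import pytest

from oracles import oracle_forward, oracle_lstm_step, oracle_softmax
from sixmapred.kmer import build_vocabulary, tokenize
from sixmapred.network import (
    LSTMWeights,
    ModelConfig,
    ModelParameters,
    attend,
    backward_batch,
    bilstm_forward,
    forward,
    forward_batch,
    init_parameters,
    load_checkpoint,
    lstm_step,
    save_checkpoint,
    softmax,
)
from sixmapred.network import _step
from sixmapred.training import cross_entropy_loss


def zero_weights(hidden_dim: int, input_dim: int) -> LSTMWeights:
    H = hidden_dim
    return LSTMWeights(
        w_ih=np.zeros((4 * H, input_dim)),
        w_hh=np.zeros((4 * H, H)),
        b_ih=np.zeros(4 * H),
        b_hh=np.zeros(4 * H),
    )


def toy_params(config: ModelConfig, seed: int = 0) -> ModelParameters:
    return init_parameters(config, np.random.default_rng(seed))


class TestLstmStep:
    def test_zero_weights_zero_state(self):
        w = zero_weights(3, 2)
        h, c = lstm_step(np.zeros(2), np.zeros(3), np.zeros(3), w)
        assert np.allclose(h, 0.0) and np.allclose(c, 0.0)
        # the gates themselves sit at sigmoid(0) = 0.5 / tanh(0) = 0
        _, _, (_, _, _, i, f, g, o, _) = _step(np.zeros(2), np.zeros(3), np.zeros(3), w, 3)
        assert np.allclose(i, 0.5) and np.allclose(f, 0.5) and np.allclose(o, 0.5)
        assert np.allclose(g, 0.0)

    def test_scalar_carry_through_cell(self):
        # zero weights, c_prev = 2: c = 0.5*2 = 1, h = 0.5*tanh(1)
        w = zero_weights(1, 1)
        h, c = lstm_step(np.zeros(1), np.zeros(1), np.array([2.0]), w)
        assert c[0] == pytest.approx(1.0, abs=1e-12)
        assert h[0] == pytest.approx(0.5 * math.tanh(1.0), abs=1e-12)
        assert h[0] == pytest.approx(0.38080, abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_straight_line_transcription(self, seed):
        rng = np.random.default_rng(seed)
        H, E = 3, 2
        w = LSTMWeights(
            w_ih=rng.normal(size=(4 * H, E)) * 0.5,
            w_hh=rng.normal(size=(4 * H, H)) * 0.5,
            b_ih=rng.normal(size=4 * H),
            b_hh=rng.normal(size=4 * H),
        )
        x, h_prev, c_prev = rng.normal(size=E), rng.normal(size=H), rng.normal(size=H)
        h, c = lstm_step(x, h_prev, c_prev, w)
        h_ref, c_ref = oracle_lstm_step(
            x.tolist(), h_prev.tolist(), c_prev.tolist(),
            w.w_ih.tolist(), w.w_hh.tolist(), w.b_ih.tolist(), w.b_hh.tolist(),
        )
        np.testing.assert_allclose(h, h_ref, atol=1e-6)
        np.testing.assert_allclose(c, c_ref, atol=1e-6)

    def test_shape_mismatch(self):
        w = zero_weights(3, 2)
        with pytest.raises(ValueError, match="width"):
            lstm_step(np.zeros(5), np.zeros(3), np.zeros(3), w)

    def test_gate_ranges_on_random_batches(self, rng):
        # weight/input scale kept below sigmoid's float64 saturation point
        H, E = 4, 3
        for _ in range(20):
            w = LSTMWeights(
                w_ih=rng.normal(size=(4 * H, E)) * 0.5,
                w_hh=rng.normal(size=(4 * H, H)) * 0.5,
                b_ih=rng.normal(size=4 * H),
                b_hh=rng.normal(size=4 * H),
            )
            x = rng.normal(size=(8, E))
            h_prev = rng.normal(size=(8, H))
            c_prev = rng.normal(size=(8, H))
            _, _, (_, _, _, i, f, g, o, _) = _step(x, h_prev, c_prev, w, H)
            for gate in (i, f, o):
                assert ((gate > 0) & (gate < 1)).all()
            assert ((g > -1) & (g < 1)).all()


class TestBilstmForward:
    def test_single_timestep_equals_one_step_from_zero(self):
        config = ModelConfig(k=1, embedding_dim=3, hidden_dim=2)
        params = toy_params(config)
        out = bilstm_forward(np.array([2]), params, config)
        x = params.embedding[2]
        h_f, _ = lstm_step(x, np.zeros(2), np.zeros(2), params.fwd)
        h_b, _ = lstm_step(x, np.zeros(2), np.zeros(2), params.bwd)
        np.testing.assert_allclose(out[0], np.concatenate([h_f, h_b]), atol=1e-12)

    def test_reversal_symmetry(self):
        # with identical weights in both directions, the backward half on s
        # equals the forward half on reversed(s), reversed
        config = ModelConfig(k=1, embedding_dim=3, hidden_dim=2)
        params = toy_params(config, seed=4)
        params.bwd = params.fwd
        tokens = np.array([0, 3, 1, 2, 2])
        out = bilstm_forward(tokens, params, config)
        out_rev = bilstm_forward(tokens[::-1].copy(), params, config)
        H = config.hidden_dim
        np.testing.assert_allclose(out[:, H:], out_rev[::-1, :H], atol=1e-12)

    def test_matches_unrolled_oracle(self):
        config = ModelConfig(k=1, embedding_dim=2, hidden_dim=3)
        params = toy_params(config, seed=9)
        tokens = [1, 0, 3]
        out = bilstm_forward(np.array(tokens), params, config)
        # brute-force unroll via repeated single steps
        xs = [params.embedding[t] for t in tokens]
        h = c = np.zeros(3)
        fwd = []
        for x in xs:
            h, c = lstm_step(x, h, c, params.fwd)
            fwd.append(h)
        h = c = np.zeros(3)
        bwd_rev = []
        for x in reversed(xs):
            h, c = lstm_step(x, h, c, params.bwd)
            bwd_rev.append(h)
        expected = np.hstack([np.array(fwd), np.array(bwd_rev[::-1])])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_empty_stream_rejected(self):
        config = ModelConfig(k=1, embedding_dim=2, hidden_dim=2)
        with pytest.raises(ValueError, match="empty"):
            bilstm_forward(np.array([], dtype=int), toy_params(config), config)


class TestAttend:
    def test_identical_rows_give_uniform_weights(self):
        row = np.array([0.3, -0.7, 1.1])
        result = attend(np.tile(row, (4, 1)))
        np.testing.assert_allclose(result.weights, 0.25, atol=1e-12)
        np.testing.assert_allclose(result.context, row, atol=1e-12)

    def test_single_timestep(self):
        result = attend(np.array([[1.0, 2.0]]))
        assert result.weights.tolist() == [1.0]
        np.testing.assert_allclose(result.context, [1.0, 2.0])

    def test_softmax_arithmetic(self):
        # softmax(ln 2, 0) = (2/3, 1/3)
        np.testing.assert_allclose(
            softmax(np.array([math.log(2), 0.0])), [2 / 3, 1 / 3], atol=1e-12
        )
        np.testing.assert_allclose(
            oracle_softmax([math.log(2), 0.0]), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_weights_normalized_for_random_outputs(self, rng):
        for _ in range(50):
            T, D = int(rng.integers(1, 10)), int(rng.integers(1, 6))
            outputs = rng.normal(size=(T, D)) * 10
            result = attend(outputs)
            assert (result.weights >= 0).all()
            assert abs(result.weights.sum() - 1.0) <= 1e-6
            np.testing.assert_allclose(result.context, result.weights @ outputs, atol=1e-9)

    def test_context_is_weighted_sum(self, rng):
        outputs = rng.normal(size=(6, 4))
        result = attend(outputs)
        np.testing.assert_allclose(
            result.context, result.weights @ outputs, atol=1e-10
        )

    def test_softmax_shift_invariance(self, rng):
        scores = rng.normal(size=12) * 5
        np.testing.assert_allclose(
            softmax(scores), softmax(scores + 123.456), atol=1e-6
        )


class TestForward:
    def test_zero_head_gives_uniform_probabilities(self):
        config = ModelConfig(k=2, embedding_dim=4, hidden_dim=3)
        params = toy_params(config)
        params.w_out[:] = 0.0
        params.b_out[:] = 0.0
        probs, _ = forward(np.array([0, 5, 9]), params, config)
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)

    def test_inference_is_deterministic(self):
        config = ModelConfig(k=2, embedding_dim=4, hidden_dim=3, dropout_rate=0.5)
        params = toy_params(config, seed=2)
        tokens = np.array([1, 8, 15, 3])
        p1, _ = forward(tokens, params, config)
        p2, _ = forward(tokens, params, config)
        assert np.array_equal(p1, p2)  # bit-identical

    def test_probabilities_sum_to_one(self, rng):
        config = ModelConfig(k=1, embedding_dim=2, hidden_dim=2)
        params = toy_params(config, seed=3)
        for _ in range(10):
            tokens = rng.integers(0, 4, size=rng.integers(1, 6))
            probs, att = forward(tokens, params, config)
            assert abs(probs.sum() - 1.0) <= 1e-6
            assert abs(att.weights.sum() - 1.0) <= 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_end_to_end_oracle(self, seed):
        # toy instances (T <= 4, hidden <= 3) against the straight-line oracle
        rng = np.random.default_rng(seed)
        config = ModelConfig(
            k=1,
            embedding_dim=int(rng.integers(1, 4)),
            hidden_dim=int(rng.integers(1, 4)),
        )
        params = toy_params(config, seed=seed + 100)
        tokens = rng.integers(0, 4, size=int(rng.integers(1, 5)))
        probs, att = forward(tokens, params, config)
        probs_ref, weights_ref, context_ref = oracle_forward(
            tokens.tolist(), params, config
        )
        np.testing.assert_allclose(probs, probs_ref, atol=1e-5)
        np.testing.assert_allclose(att.weights, weights_ref, atol=1e-5)
        np.testing.assert_allclose(att.context, context_ref, atol=1e-5)

    def test_out_of_vocabulary_token_rejected(self):
        config = ModelConfig(k=1, embedding_dim=2, hidden_dim=2)
        with pytest.raises(ValueError, match="token ids"):
            forward(np.array([0, 4]), toy_params(config), config)

    def test_training_mode_requires_rng(self):
        config = ModelConfig(k=1, embedding_dim=2, hidden_dim=2, dropout_rate=0.3)
        with pytest.raises(ValueError, match="rng"):
            forward_batch(np.array([[0, 1]]), toy_params(config), config, training=True)

    def test_works_on_tokenized_windows(self, rng):
        from conftest import random_window

        vocab = build_vocabulary(3)
        config = ModelConfig(k=3, embedding_dim=8, hidden_dim=8)
        params = toy_params(config)
        stream = tokenize(random_window(rng), vocab)
        probs, att = forward(stream, params, config)
        assert probs.shape == (2,) and len(att.weights) == 39


class TestGradients:
    @pytest.mark.parametrize("bidirectional", [True, False])
    def test_backward_matches_finite_differences(self, bidirectional):
        config = ModelConfig(
            k=1, embedding_dim=3, hidden_dim=3, dropout_rate=0.0,
            bidirectional=bidirectional,
        )
        rng = np.random.default_rng(0)
        params = init_parameters(config, rng)
        tokens = rng.integers(0, 4, size=(4, 5))
        labels = rng.integers(0, 2, size=4)
        cache = forward_batch(tokens, params, config)
        grads = backward_batch(cache, labels, params, config)
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for name, arr in params.named_arrays().items():
            flat_positions = check_rng.choice(
                arr.size, size=min(arr.size, 12), replace=False
            )
            for pos in flat_positions:
                idx = np.unravel_index(pos, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = cross_entropy_loss(
                    forward_batch(tokens, params, config)["probs"], labels
                )
                arr[idx] = orig - eps
                lm = cross_entropy_loss(
                    forward_batch(tokens, params, config)["probs"], labels
                )
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(fd, abs=5e-7), name


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        config = ModelConfig(k=2, embedding_dim=5, hidden_dim=4)
        params = toy_params(config, seed=8)
        vocab = build_vocabulary(2)
        path = tmp_path / "model.npz"
        save_checkpoint(path, config, params, vocab)
        config2, params2, vocab2 = load_checkpoint(path)
        assert config2 == config and vocab2.k == 2
        tokens = rng.integers(0, 16, size=7)
        p1, _ = forward(tokens, params, config)
        p2, _ = forward(tokens, params2, config2)
        np.testing.assert_array_equal(p1, p2)

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "other.npz"
        np.savez(path, __meta__=np.frombuffer(b'{"format": "x"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="format"):
            load_checkpoint(path)
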