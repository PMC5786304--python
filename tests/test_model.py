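import math

import numpy as np
import pytest

from treeddi.model import (
    CompiledTree,
    DropoutSpec,
    NodeState,
    TrainConfig,
    TreeLSTMParams,
    classify_root,
    ensemble_logits,
    ensemble_predict,
    forward_tree,
    loss,
    loss_and_grads,
    node_forward,
    predict,
    predict_logits,
    train,
)
from treeddi.parse_trees import TreeError
from tests.conftest import naive_forward, naive_logits, random_compiled_tree


def _params(H=4, C=2, X=6, seed=0, scale=0.3):
    return TreeLSTMParams.initialize(H, C, input_size=X, seed=seed, init_scale=scale)


class TestNodeForward:
    def test_zero_params_zero_fixed_point(self):
        params = TreeLSTMParams(hidden_size=3, n_classes=2, input_size=5)
        state = node_forward(params, np.ones(5))
        assert np.allclose(state.c, 0.0)
        assert np.allclose(state.h, 0.0)

    def test_scalar_hand_computation(self):
        # H=1, all weights 1, biases 0, leaf with x=1:
        # i = o = sigmoid(1), u = tanh(1), c = i*u, h = o*tanh(c)
        params = TreeLSTMParams(hidden_size=1, n_classes=2, input_size=1)
        for name in ("W_i", "W_f", "W_o", "W_u"):
            setattr(params, name, np.ones((1, 2)))
        state = node_forward(params, np.array([1.0]))
        sig1, tanh1 = 1 / (1 + math.exp(-1)), math.tanh(1)
        c = sig1 * tanh1
        assert state.c[0] == pytest.approx(c, abs=1e-4)
        assert state.c[0] == pytest.approx(0.5567, abs=1e-3)
        assert state.h[0] == pytest.approx(sig1 * math.tanh(c), abs=1e-4)
        assert state.h[0] == pytest.approx(0.3690, abs=1e-3)

    def test_one_child_rejected(self):
        params = _params()
        child = NodeState(h=np.zeros(4), c=np.zeros(4))
        with pytest.raises(TreeError, match="0 or 2"):
            node_forward(params, np.zeros(6), [child])

    def test_nan_input_rejected(self):
        params = _params()
        x = np.zeros(6)
        x[0] = np.nan
        with pytest.raises(FloatingPointError):
            node_forward(params, x)

    def test_eval_mode_dropout_is_identity(self):
        params = _params()
        x = np.ones(6)
        spec = DropoutSpec(keep_p=0.5, mode="eval", seed=0)
        plain = node_forward(params, x)
        dropped = node_forward(params, x, dropout=spec)
        assert np.array_equal(plain.h, dropped.h)

    def test_keep_p_one_train_equals_eval(self):
        params = _params()
        x = np.ones(6)
        spec = DropoutSpec(keep_p=1.0, mode="train", seed=0)
        assert np.array_equal(
            node_forward(params, x).h, node_forward(params, x, dropout=spec).h
        )


class TestOracleEquivalence:
    def test_forward_matches_naive_reference_on_100_random_trees(self):
        rng = np.random.default_rng(42)
        max_delta = 0.0
        for _ in range(100):
            H = int(rng.integers(1, 9))
            X = int(rng.integers(2, 8))
            n_leaves = int(rng.integers(2, 33))  # depth <= 6 equivalent size
            tree = random_compiled_tree(rng, n_leaves, X)
            params = TreeLSTMParams.initialize(
                H, 2, input_size=X, seed=int(rng.integers(1 << 30)), init_scale=0.4
            )
            state, _ = forward_tree(params, tree)
            h_ref, c_ref = naive_forward(params, tree)
            max_delta = max(
                max_delta,
                float(np.max(np.abs(state.h - np.array(h_ref)))),
                float(np.max(np.abs(state.c - np.array(c_ref)))),
            )
        assert max_delta < 1e-6

    def test_logits_match_naive_matrix_product(self):
        rng = np.random.default_rng(7)
        tree = random_compiled_tree(rng, 5, 6)
        params = _params(H=4, C=3, X=6, seed=1)
        logits = predict_logits(params, tree)
        assert np.allclose(logits, naive_logits(params, tree), atol=1e-9)


class TestClassifyRoot:
    def test_zero_params_zero_logits(self):
        params = TreeLSTMParams(hidden_size=3, n_classes=4, input_size=5)
        state = NodeState(h=np.ones(3), c=np.ones(3))
        assert np.array_equal(classify_root(params, state), np.zeros(4))

    def test_bias_only_argmax(self):
        params = TreeLSTMParams(hidden_size=3, n_classes=2, input_size=5)
        params.b_fc = np.array([0.0, 1.0])
        state = NodeState(h=np.random.default_rng(0).normal(size=3), c=np.zeros(3))
        assert predict(classify_root(params, state)) == 1

    def test_only_root_hidden_state_used(self):
        params = _params(H=4, C=2)
        state = NodeState(h=np.ones(4), c=np.full(4, 99.0))
        other = NodeState(h=np.ones(4), c=np.zeros(4))
        assert np.array_equal(
            classify_root(params, state), classify_root(params, other)
        )


class TestPredict:
    def test_argmax(self):
        assert predict(np.array([0.2, 0.9])) == 1

    def test_tie_breaks_low(self):
        assert predict(np.array([0.5, 0.5])) == 0

    def test_matches_numpy_argmax_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            logits = rng.normal(size=5)
            assert predict(logits) == int(np.argmax(logits))


class TestLoss:
    def test_perfect_prediction_loss_near_zero(self):
        logits = np.array([100.0, 0.0])
        assert loss([logits], [0]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_logits_closed_form(self):
        logits = np.zeros(2)
        assert loss([logits], [0], positive_weight=3.0) == pytest.approx(
            math.log(2), abs=1e-12
        )
        assert loss([logits], [1], positive_weight=3.0) == pytest.approx(
            3 * math.log(2), abs=1e-12
        )

    def test_mixed_batch_mean(self):
        logits = np.zeros(2)
        value = loss([logits, logits], [1, 0], positive_weight=3.0)
        assert value == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_positive_negative_ratio_exactly_three(self):
        logits = np.array([0.3, -0.7])
        negative = loss([logits], [0], positive_weight=3.0)
        positive = loss([np.array([-0.7, 0.3])], [1], positive_weight=3.0)
        # identical logit margins: ratio is the class weight exactly
        assert positive / negative == pytest.approx(3.0, rel=1e-12)

    def test_uniform_weights_for_type_classifier(self):
        logits = np.zeros(4)
        assert loss([logits], [2], positive_weight=1.0) == pytest.approx(
            math.log(4)
        )

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=5)
        assert loss([logits], [3]) == pytest.approx(
            loss([logits + 123.4], [3]), rel=1e-10
        )

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="class range"):
            loss([np.zeros(2)], [5])

    def test_empty_batch(self):
        with pytest.raises(ValueError, match="empty"):
            loss([], [])


class TestGradients:
    def test_finite_difference_agreement(self):
        # H=4 toys, dropout off, 1e-4 relative tolerance
        rng = np.random.default_rng(9)
        for trial in range(3):
            X = 5
            tree = random_compiled_tree(rng, int(rng.integers(2, 7)), X)
            params = _params(H=4, C=3, X=X, seed=trial, scale=0.4)
            label = int(rng.integers(3))
            _, grads = loss_and_grads(params, tree, label, positive_weight=3.0)
            eps = 1e-6
            for name in params._TENSORS:
                tensor = getattr(params, name)
                flat = tensor.reshape(-1)
                idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
                for i in idx:
                    orig = flat[i]
                    flat[i] = orig + eps
                    up, _ = loss_and_grads(params, tree, label, positive_weight=3.0)
                    flat[i] = orig - eps
                    down, _ = loss_and_grads(params, tree, label, positive_weight=3.0)
                    flat[i] = orig
                    fd = (up - down) / (2 * eps)
                    analytic = grads[name].reshape(-1)[i]
                    denom = max(1e-8, abs(fd) + abs(analytic))
                    assert abs(fd - analytic) / denom < 1e-4, (name, trial)


def _toy_dataset(n=24, seed=0, H=6, X=8):
    rng = np.random.default_rng(seed)
    trees, labels = [], []
    for i in range(n):
        trees.append(random_compiled_tree(rng, int(rng.integers(2, 6)), X))
        labels.append(i % 2)
    return trees, labels


class TestTrain:
    def test_zero_learning_rate_leaves_params_unchanged(self):
        trees, labels = _toy_dataset()
        config = TrainConfig(
            hidden_size=6, batch_size=8, learning_rate=0.0, keep_p=1.0,
            epochs=1, n_classes=2, seed=3, input_size=8,
        )
        initial = TreeLSTMParams.initialize(6, 2, input_size=8, seed=3)
        trained, _ = train(trees, labels, config)
        assert trained == initial

    def test_fixed_seed_bitwise_identical_loss_curve(self):
        trees, labels = _toy_dataset()
        config = TrainConfig(
            hidden_size=6, batch_size=8, learning_rate=0.01, keep_p=0.7,
            epochs=3, n_classes=2, seed=11, input_size=8,
        )
        _, first = train(trees, labels, config)
        _, second = train(trees, labels, config)
        assert first == second

    def test_loss_decreases_on_learnable_toy(self):
        trees, labels = _toy_dataset(n=30, seed=5)
        config = TrainConfig(
            hidden_size=6, batch_size=10, learning_rate=0.02, keep_p=1.0,
            epochs=10, n_classes=2, seed=0, input_size=8,
        )
        _, losses = train(trees, labels, config)
        assert losses[-1] < losses[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], [], TrainConfig(n_classes=2))

    def test_paper_dropout_variant_runs(self):
        trees, labels = _toy_dataset()
        config = TrainConfig(
            hidden_size=4, batch_size=8, learning_rate=0.01, keep_p=0.5,
            epochs=1, n_classes=2, seed=0, input_size=8,
            dropout_variant="paper", mask_scope="node",
        )
        params, losses = train(trees, labels, config)
        assert np.all(np.isfinite(losses))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        params = _params(H=5, C=4, X=7, seed=2)
        path = tmp_path / "model.npz"
        params.save(path)
        loaded = TreeLSTMParams.load(path)
        assert loaded == params
        assert (loaded.hidden_size, loaded.n_classes, loaded.input_size) == (5, 4, 7)


class TestEnsemble:
    def test_single_member_equals_predict(self):
        rng = np.random.default_rng(1)
        tree = random_compiled_tree(rng, 4, 6)
        params = _params(X=6, seed=4)
        assert ensemble_predict([params], tree) == predict(
            predict_logits(params, tree)
        )

    def test_logit_summation(self):
        rng = np.random.default_rng(2)
        tree = random_compiled_tree(rng, 3, 6)
        a, b = _params(X=6, seed=1), _params(X=6, seed=2)
        total = ensemble_logits([a, b], tree)
        expected = predict_logits(a, tree) + predict_logits(b, tree)
        assert np.allclose(total, expected)

    def test_hand_logits_sum_argmax(self):
        # members with logits (1,0) and (0,2) -> sum (1,2) -> class 1
        assert int(np.argmax(np.array([1.0, 0.0]) + np.array([0.0, 2.0]))) == 1

    def test_mismatched_class_counts_rejected(self):
        rng = np.random.default_rng(3)
        tree = random_compiled_tree(rng, 3, 6)
        with pytest.raises(ValueError, match="class count"):
            ensemble_logits([_params(C=2, X=6), _params(C=3, X=6)], tree)

    def test_empty_ensemble_rejected(self):
        rng = np.random.default_rng(3)
        tree = random_compiled_tree(rng, 3, 6)
        with pytest.raises(ValueError, match="at least one"):
            ensemble_logits([], tree)


class TestDropoutSpec:
    def test_invalid_keep_p(self):
        with pytest.raises(ValueError):
            DropoutSpec(keep_p=0.0)

    def test_inverted_mask_values(self):
        spec = DropoutSpec(keep_p=0.5, mode="train", seed=0, variant="inverted")
        mask = spec.sample_mask(1000)
        assert set(np.unique(mask)) <= {0.0, 2.0}

    def test_paper_mask_values(self):
        spec = DropoutSpec(keep_p=0.5, mode="train", seed=0, variant="paper")
        mask = spec.sample_mask(1000)
        assert set(np.unique(mask)) <= {0.0, 1.0}

    def test_eval_mask_is_ones(self):
        spec = DropoutSpec(keep_p=0.5, mode="eval", seed=0)
        assert np.array_equal(spec.sample_mask(10), np.ones(10))
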