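"""Shallow network classifier: architectures, training, voting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fidgetpose as fp
from fidgetpose.nn import Adam, ShallowMLP, bce_from_logits
from fidgetpose.smnn import ARCHITECTURES, ModelSpec, majority_vote


class TestModelSpec:
    @pytest.mark.parametrize("arch,sizes", [(1, [50]), (5, [50, 100]), (9, [50, 200, 200])])
    def test_reference_architectures(self, arch, sizes):
        spec = ModelSpec.from_architecture(arch)
        assert list(spec.hidden_sizes) == sizes
        assert spec.dropout_rate == (0.0 if arch <= 3 else 0.2)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="1..9"):
            ModelSpec.from_architecture(10)

    def test_custom_spec_allowed_outside_reference_ids(self):
        spec = ModelSpec(architecture_id=99, hidden_sizes=(7,))
        assert spec.hidden_sizes == (7,)

    def test_layer_shapes_follow_table(self):
        for arch, sizes in ARCHITECTURES.items():
            net = ShallowMLP(2600, sizes, 0.2 if arch > 3 else 0.0, rng=0)
            dims = [2600] + sizes + [1]
            for l in range(len(dims) - 1):
                assert net.params[f"W{l}"].shape == (dims[l], dims[l + 1])


class TestForwardPass:
    def test_hand_computed_tiny_network(self):
        """1-hidden-unit net with hand-set weights: the output must equal the
        manually evaluated sigmoid(W1·relu(W0·x + b0) + b1)."""
        net = ShallowMLP(2, [1], rng=0)
        net.set_params({"W0": np.array([[1.0], [2.0]]), "b0": np.array([0.5]),
                        "W1": np.array([[2.0]]), "b1": np.array([-1.0])})
        p = net.predict_proba(np.array([[1.0, 1.0]]))[0]
        # z0 = 1 + 2 + 0.5 = 3.5 ; relu -> 3.5 ; logit = 2*3.5 - 1 = 6
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-6.0)))
        # negative pre-activation is clipped by the rectifier
        p2 = net.predict_proba(np.array([[-1.0, 0.0]]))[0]
        assert p2 == pytest.approx(1.0 / (1.0 + math.exp(1.0)))  # logit = -1

    def test_zero_weights_give_half(self):
        net = ShallowMLP(4, [3], rng=0)
        net.set_params({k: np.zeros_like(v) for k, v in net.params.items()})
        assert net.predict_proba(np.ones((1, 4)))[0] == pytest.approx(0.5)

    def test_output_strictly_inside_unit_interval(self):
        net = ShallowMLP(4, [3], rng=1)
        p = net.predict_proba(np.full((1, 4), 1e6))
        assert 0.0 < p[0] < 1.0

    def test_gradients_match_finite_differences(self):
        """Backward pass of the 2-hidden-layer PReLU/dropout-capable net
        against numeric differentiation (dropout off)."""
        rng = np.random.default_rng(0)
        net = ShallowMLP(5, [4, 3], dropout_rate=0.0, rng=2)
        # jitter biases away from 0 so no pre-activation sits exactly on a
        # rectifier kink (where the two-sided difference quotient is undefined)
        for key in list(net.params):
            if key.startswith("b"):
                net.params[key] = rng.normal(0.05, 0.1, net.params[key].shape)
        X = rng.normal(size=(7, 5))
        y = rng.integers(0, 2, 7).astype(float)
        logits, cache = net.forward(X, train=True, rng=rng)
        grads = net.backward(cache, logits, y)
        eps = 1e-6
        for key in ["W0", "b1", "a1", "W2"]:
            flat = net.params[key].reshape(-1)
            g_flat = np.asarray(grads[key]).reshape(-1)
            for i in range(min(flat.size, 3)):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = net.forward(X)
                up = bce_from_logits(lp, y)
                flat[i] = orig - eps
                lm, _ = net.forward(X)
                down = bce_from_logits(lm, y)
                flat[i] = orig
                assert g_flat[i] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestTraining:
    def _separable(self, n=200, d=10, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n).astype(float)
        X = rng.normal(size=(n, d)) + 3.0 * y[:, None]
        return X, y

    def test_separable_data_reaches_perfect_training_accuracy(self):
        X, y = self._separable()
        res = fp.SMNNModel(X, y, ModelSpec(99, (16,)), seed=0).fit(
            fp.TrainConfig(batch_size=64, max_epochs=200, seed=0))
        assert res.history["train_acc"].iloc[-1] == 1.0

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        X, y = self._separable(50)
        model = fp.SMNNModel(X, y, ModelSpec(99, (8,)), seed=1)
        before = {k: v.copy() for k, v in model.net.params.items()}
        model.fit(fp.TrainConfig(learning_rate=0.0, batch_size=16, max_epochs=5, seed=0))
        for k in before:
            assert np.array_equal(before[k], model.net.params[k])

    def test_training_is_deterministic_given_seed(self):
        X, y = self._separable(80, seed=3)
        runs = []
        for _ in range(2):
            model = fp.SMNNModel(X, y, 5 if X.shape[1] == 2600 else ModelSpec(99, (8, 8), 0.2),
                                 seed=4)
            res = model.fit(fp.TrainConfig(batch_size=32, max_epochs=10, seed=7))
            runs.append(res.model.net.copy_params())
        for k in runs[0]:
            assert np.array_equal(runs[0][k], runs[1][k])

    def test_same_seed_same_initial_parameters(self):
        a = fp.build_model(5, 2600, seed=11).net.copy_params()
        b = fp.build_model(5, 2600, seed=11).net.copy_params()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_single_class_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError, match="single class"):
            fp.SMNNModel(X, np.ones(10))

    def test_dimension_mismatch_rejected(self):
        X, y = self._separable(20, d=6)
        res = fp.SMNNModel(X, y, ModelSpec(99, (4,)), seed=0).fit(
            fp.TrainConfig(batch_size=8, max_epochs=2))
        with pytest.raises(ValueError, match="shape"):
            res.predict_proba(np.zeros((1, 5)))

    def test_inference_is_deterministic_despite_dropout(self):
        X, y = self._separable(60, seed=5)
        res = fp.SMNNModel(X, y, ModelSpec(99, (8, 8), dropout_rate=0.5), seed=0).fit(
            fp.TrainConfig(batch_size=32, max_epochs=5, seed=0))
        p1 = res.predict_proba(X)
        p2 = res.predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_adam_zero_gradient_no_update(self):
        params = {"w": np.array([1.0, 2.0])}
        opt = Adam(params)
        opt.step(params, {"w": np.zeros(2)})
        assert np.array_equal(params["w"], [1.0, 2.0])


def brute_force_vote(probs, threshold):
    """Independent vote counter used as oracle."""
    plus = sum(1 for p in probs if p > threshold)
    minus = len(probs) - plus
    if plus > minus:
        return fp.Label.FM_PLUS
    return fp.Label.FM_MINUS


class TestMajorityVote:
    @pytest.mark.parametrize("plus,minus,expected,tie", [
        (9, 8, fp.Label.FM_PLUS, False),
        (0, 17, fp.Label.FM_MINUS, False),
        (8, 8, fp.Label.FM_MINUS, True),
    ])
    def test_vote_rules(self, plus, minus, expected, tie):
        label, is_tie = majority_vote(plus, minus)
        assert label is expected and is_tie is tie

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=33),
           st.floats(0.05, 0.95))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_agrees_with_brute_force_counter(self, probs, threshold):
        plus = sum(1 for p in probs if p > threshold)
        label, _ = majority_vote(plus, len(probs) - plus)
        assert label is brute_force_vote(probs, threshold)

    def test_odd_window_count_cannot_tie(self):
        for plus in range(18):
            _, tie = majority_vote(plus, 17 - plus)
            assert not tie


class TestSnippetClassification:
    def test_empty_window_list_rejected(self, separable_fit):
        results, _ = separable_fit
        with pytest.raises(ValueError, match="at least one window"):
            results.classify_snippet(np.empty((0, results.input_dim)))

    def test_threshold_monotonicity(self, separable_fit):
        """Raising the vote threshold can only remove FM+ votes, so it never
        converts an FM− snippet decision into FM+."""
        results, test_snippets = separable_fit
        for snippet in test_snippets[:6]:
            windows = fp.stack_windows(fp.normalize_skeleton(snippet))
            labels = [results.classify_snippet(windows, threshold=t)
                      for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
            seen_minus = False
            for lab in labels:
                if lab is fp.Label.FM_MINUS:
                    seen_minus = True
                assert not (seen_minus and lab is fp.Label.FM_PLUS)

    def test_heldout_participants_classified_well(self, separable_fit):
        results, test_snippets = separable_fit
        predictions = results.classify_snippets(test_snippets)
        correct = sum(predictions[s.snippet_id] is s.label for s in test_snippets)
        assert correct / len(test_snippets) >= 0.9

    def test_checkpoint_round_trip(self, separable_fit, tmp_path):
        results, test_snippets = separable_fit
        results.save(tmp_path / "ckpt.npz", fp.FeatureConfig())
        loaded = fp.SMNNResults.load(tmp_path / "ckpt.npz")
        windows = fp.stack_windows(fp.normalize_skeleton(test_snippets[0]))
        X = np.asarray([w.vector for w in windows])
        assert np.allclose(results.predict_proba(X), loaded.predict_proba(X))

    def test_summary_mentions_architecture(self, separable_fit):
        results, _ = separable_fit
        text = results.summary()
        assert "2600 -> 50 -> 100 -> 1" in text
        assert "batch=3968" in text
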