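import itertools

import numpy as np
import pytest

from orascreen.dbn import (
    DBNClassifier,
    RBM,
    TrainConfig,
    cd_update,
    energy,
    exact_log_likelihood,
    hidden_conditional,
    joint_probability,
    load_dbn,
    marginal_visible,
    partition_function,
    save_dbn,
    train_dbn,
    visible_conditional,
)


def small_rbm(weights, a=None, b=None) -> RBM:
    weights = np.asarray(weights, dtype=float)
    m, n = weights.shape
    return RBM(
        weights=weights,
        visible_bias=np.zeros(m) if a is None else np.asarray(a, float),
        hidden_bias=np.zeros(n) if b is None else np.asarray(b, float),
    )


def random_rbm(rng: np.random.Generator, m: int = 3, n: int = 2) -> RBM:
    return RBM(
        weights=rng.normal(0, 1, (m, n)),
        visible_bias=rng.normal(0, 1, m),
        hidden_bias=rng.normal(0, 1, n),
    )


def all_states(k):
    return [np.array(s, float) for s in itertools.product((0, 1), repeat=k)]


class TestEnergy:
    def test_zero_parameters_zero_energy(self):
        rbm = small_rbm(np.zeros((2, 2)))
        for v in all_states(2):
            for h in all_states(2):
                assert energy(rbm, v, h) == 0.0

    def test_hand_evaluated_cases(self):
        rbm = small_rbm([[1.0], [-1.0]])
        assert energy(rbm, np.array([1.0, 1.0]), np.array([1.0])) == pytest.approx(0.0)
        rbm2 = small_rbm([[1.0], [-1.0]], a=[0.5, 0.0], b=[0.25])
        assert energy(rbm2, np.array([1.0, 0.0]), np.array([1.0])) == pytest.approx(-1.75)

    def test_shape_mismatch_rejected(self):
        rbm = small_rbm(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            energy(rbm, np.zeros(3), np.zeros(2))


class TestEnumerationOracle:
    def test_uniform_at_zero_parameters(self):
        rbm = small_rbm(np.zeros((2, 1)))
        for v in all_states(2):
            for h in all_states(1):
                assert joint_probability(rbm, v, h) == pytest.approx(1 / 8, abs=1e-12)

    def test_joint_normalises(self):
        rng = np.random.default_rng(1)
        rbm = random_rbm(rng)
        total = sum(
            joint_probability(rbm, v, h)
            for v in all_states(rbm.m)
            for h in all_states(rbm.n)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_marginal_equals_summed_joint(self):
        rng = np.random.default_rng(2)
        rbm = random_rbm(rng)
        for v in all_states(rbm.m):
            summed = sum(joint_probability(rbm, v, h) for h in all_states(rbm.n))
            assert marginal_visible(rbm, v) == pytest.approx(summed, abs=1e-12)

    def test_marginal_sums_to_one(self):
        rng = np.random.default_rng(3)
        rbm = random_rbm(rng)
        total = sum(marginal_visible(rbm, v) for v in all_states(rbm.m))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_large_model_refused(self):
        rbm = small_rbm(np.zeros((15, 10)))
        with pytest.raises(ValueError, match="enumeration"):
            partition_function(rbm)


class TestConditionals:
    def test_half_at_zero_parameters(self):
        rbm = small_rbm(np.zeros((2, 3)))
        np.testing.assert_allclose(hidden_conditional(rbm, np.array([1.0, 0.0])), 0.5)
        np.testing.assert_allclose(visible_conditional(rbm, np.array([1.0, 0.0, 1.0])), 0.5)

    def test_hand_evaluated_logistic(self):
        rbm = small_rbm([[1.0], [-1.0]])
        p = hidden_conditional(rbm, np.array([1.0, 0.0]))
        assert p[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)
        assert p[0] == pytest.approx(0.73106, abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_hidden_conditional_matches_enumeration(self, seed):
        """sigmoid conditionals equal ratios of enumerated joint probabilities."""
        rng = np.random.default_rng(seed)
        rbm = random_rbm(rng)
        for v in all_states(rbm.m):
            pv = marginal_visible(rbm, v)
            probs = hidden_conditional(rbm, v)
            for j in range(rbm.n):
                pj = sum(
                    joint_probability(rbm, v, h)
                    for h in all_states(rbm.n)
                    if h[j] == 1
                )
                assert probs[j] == pytest.approx(pj / pv, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_visible_conditional_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        rbm = random_rbm(rng)
        h = np.array([1.0, 0.0])
        ph = sum(
            joint_probability(rbm, v, h) for v in all_states(rbm.m)
        )
        probs = visible_conditional(rbm, h)
        for i in range(rbm.m):
            pi = sum(
                joint_probability(rbm, v, h)
                for v in all_states(rbm.m)
                if v[i] == 1
            )
            assert probs[i] == pytest.approx(pi / ph, abs=1e-10)

    def test_visible_probability_monotone_in_bias(self):
        h = np.array([1.0, 0.0])
        base = small_rbm(np.ones((2, 2)), a=[0.0, 0.0])
        raised = small_rbm(np.ones((2, 2)), a=[1.0, 0.0])
        assert visible_conditional(raised, h)[0] > visible_conditional(base, h)[0]

    def test_shape_mismatch_rejected(self):
        rbm = small_rbm(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            hidden_conditional(rbm, np.zeros(3))


class TestCDUpdate:
    def test_all_ones_batch_raises_visible_bias(self):
        rng = np.random.default_rng(0)
        rbm = small_rbm(np.zeros((3, 2)))
        updated = cd_update(rbm, np.ones((4, 3)), TrainConfig(), rng)
        assert np.all(updated.visible_bias > rbm.visible_bias)

    def test_zero_learning_rate_is_identity(self):
        rng = np.random.default_rng(1)
        rbm = random_rbm(rng)
        updated = cd_update(
            rbm, np.ones((2, 3)), TrainConfig(learning_rate=0.0), rng
        )
        np.testing.assert_array_equal(updated.weights, rbm.weights)
        np.testing.assert_array_equal(updated.visible_bias, rbm.visible_bias)

    def test_empty_batch_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            cd_update(small_rbm(np.zeros((2, 2))), np.empty((0, 2)), TrainConfig(), rng)

    def test_update_scale_linear_in_learning_rate(self):
        batch = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        base = random_rbm(np.random.default_rng(3))
        d1 = (
            cd_update(base, batch, TrainConfig(learning_rate=0.2), np.random.default_rng(7)).weights
            - base.weights
        )
        d2 = (
            cd_update(base, batch, TrainConfig(learning_rate=0.1), np.random.default_rng(7)).weights
            - base.weights
        )
        np.testing.assert_allclose(d1, 2 * d2, atol=1e-12)

    def test_likelihood_improves_over_training(self):
        """CD-1 behaves as approximate likelihood ascent on a tiny RBM."""
        data = np.array([[1, 1, 1], [1, 1, 0], [0, 0, 0], [0, 0, 1]], float)
        rng = np.random.default_rng(0)
        rbm = RBM.initialise(3, 2, rng)
        config = TrainConfig(learning_rate=0.1, batch_size=4)
        initial = exact_log_likelihood(rbm, data)
        for _ in range(200):
            rbm = cd_update(rbm, data, config, rng)
        assert exact_log_likelihood(rbm, data) > initial


class TestDBNClassifier:
    def test_training_accuracy_on_separable_clusters(self, cluster_data):
        X, y = cluster_data
        clf = DBNClassifier(random_state=0).fit(X, y)
        assert clf.score(X, y) >= 0.95

    def test_heldout_accuracy_on_separable_clusters(self, cluster_data):
        X, y = cluster_data
        train = np.r_[0:150, 200:350]
        test = np.r_[150:200, 350:400]
        clf = DBNClassifier(random_state=0).fit(X[train], y[train])
        assert clf.score(X[test], y[test]) >= 0.9

    def test_probabilities_normalised_and_argmax_consistent(self, cluster_data):
        X, y = cluster_data
        clf = DBNClassifier(random_state=1).fit(X, y)
        probs = clf.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(clf.predict(X), clf.classes_[probs.argmax(1)])

    def test_no_finetuning_leaves_output_layer_naive(self, cluster_data):
        X, y = cluster_data
        clf = DBNClassifier(epochs_finetune=0, random_state=0).fit(X, y)
        assert clf.score(X, y) <= 0.75  # near chance: output layer untrained

    def test_seed_determinism_bitwise(self, cluster_data):
        X, y = cluster_data
        c1 = DBNClassifier(random_state=5).fit(X, y)
        c2 = DBNClassifier(random_state=5).fit(X, y)
        for r1, r2 in zip(c1.rbms_, c2.rbms_):
            np.testing.assert_array_equal(r1.weights, r2.weights)
        np.testing.assert_array_equal(c1.output_weights_, c2.output_weights_)

    def test_row_order_stability_within_two_percent(self, cluster_data):
        X, y = cluster_data
        perm = np.random.default_rng(11).permutation(X.shape[0])
        acc1 = DBNClassifier(random_state=3).fit(X, y).score(X, y)
        acc2 = DBNClassifier(random_state=3).fit(X[perm], y[perm]).score(X, y)
        assert abs(acc1 - acc2) <= 0.02

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 4))
        with pytest.raises(ValueError):
            DBNClassifier().fit(X, np.zeros(10))

    def test_unscaled_features_rejected(self):
        X = np.random.default_rng(0).random((10, 4)) * 5
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="min-max"):
            DBNClassifier().fit(X, y)

    def test_dimension_mismatch_rejected(self, cluster_data):
        X, y = cluster_data
        clf = DBNClassifier(random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(X[:, :4])

    def test_sklearn_param_interface(self):
        clf = DBNClassifier()
        clf.set_params(hidden_layer_sizes=(8,), learning_rate=0.2)
        assert clf.get_params()["hidden_layer_sizes"] == (8,)
        with pytest.raises(ValueError):
            clf.set_params(bogus=1)

    def test_functional_wrapper_matches_estimator(self, cluster_data):
        X, y = cluster_data
        model = train_dbn(X, y, arch=(16, 8), config=TrainConfig(seed=2))
        direct = DBNClassifier(hidden_layer_sizes=(16, 8), epochs_pretrain=50,
                               epochs_finetune=50, random_state=2).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), direct.predict(X))


def test_serialization_roundtrip_bitwise(tmp_path, cluster_data):
    X, y = cluster_data
    idx = np.r_[0:50, 200:250]
    clf = DBNClassifier(hidden_layer_sizes=(8, 4), random_state=0).fit(X[idx], y[idx])
    path = tmp_path / "model.json"
    save_dbn(clf, path)
    back = load_dbn(path)
    for r1, r2 in zip(clf.rbms_, back.rbms_):
        np.testing.assert_array_equal(r1.weights, r2.weights)
        np.testing.assert_array_equal(r1.visible_bias, r2.visible_bias)
        np.testing.assert_array_equal(r1.hidden_bias, r2.hidden_bias)
    np.testing.assert_array_equal(clf.output_weights_, back.output_weights_)
    np.testing.assert_array_equal(clf.predict_proba(X), back.predict_proba(X))
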