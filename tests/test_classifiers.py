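import numpy as np
import pytest

from mammocad import J48Tree, KNNClassifier, RandomForest, RandomTree, make_classifier
from mammocad.classifiers import binary_entropy, gain_ratio
from mammocad.errors import ParameterError, SchemaError


def _knn_oracle(Xtr, ytr, Q, k):
    """Brute-force all-pairs k-NN with the documented scaling and tie rules."""
    lo = Xtr.min(axis=0)
    rng = Xtr.max(axis=0) - lo
    rng = np.where(rng > 0, rng, 1.0)
    A = (Xtr - lo) / rng
    B = (Q - lo) / rng
    preds = []
    for q in B:
        d = np.sqrt(((A - q) ** 2).sum(axis=1))
        order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
        labels = ytr[order]
        v1 = labels.mean()
        if v1 > 0.5:
            preds.append(1)
        elif v1 < 0.5:
            preds.append(0)
        else:
            d0 = min(d[i] for i in order if ytr[i] == 0)
            d1 = min(d[i] for i in order if ytr[i] == 1)
            preds.append(1 if d1 < d0 else 0)
    return np.array(preds)


class TestKNN:
    def test_single_point_k1(self):
        model = KNNClassifier(k=1).fit([[0.0, 0.0]], [1])
        assert model.predict([[5.0, 5.0]])[0] == 1

    def test_coincident_opposite_labels_tie_to_class_zero(self):
        model = KNNClassifier(k=2).fit([[0.0], [0.0]], [0, 1])
        assert model.predict([[0.0]])[0] == 0

    def test_split_vote_decided_by_nearer_neighbour(self):
        model = KNNClassifier(k=2).fit([[0.0], [2.0]], [1, 0])
        np.testing.assert_allclose(model.predict_proba([[0.5]])[0], [0.5, 0.5])
        assert model.predict([[0.5]])[0] == 1  # nearer neighbour has label 1

    def test_probability_rows_sum_to_one(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        model = KNNClassifier(k=2).fit(X, y)
        p = model.predict_proba(rng.normal(size=(10, 4)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert np.all((p >= 0) & (p <= 1))

    def test_matches_brute_force_oracle_on_random_points(self, rng):
        Xtr = rng.normal(size=(120, 5)) * [1, 10, 100, 0.1, 1]
        ytr = rng.integers(0, 2, 120)
        Q = rng.normal(size=(80, 5)) * [1, 10, 100, 0.1, 1]
        model = KNNClassifier(k=2).fit(Xtr, ytr)
        np.testing.assert_array_equal(model.predict(Q), _knn_oracle(Xtr, ytr, Q, 2))

    def test_parameter_and_shape_errors(self):
        with pytest.raises(ParameterError):
            KNNClassifier(k=5).fit([[1.0], [2.0]], [0, 1])
        model = KNNClassifier(k=1).fit([[1.0, 2.0]], [0])
        with pytest.raises(SchemaError):
            model.predict([[1.0]])


class TestTrees:
    def test_pure_dataset_single_leaf(self):
        tree = J48Tree(prune=False).fit([[0.0], [1.0], [2.0]], [1, 1, 1])
        assert tree.n_leaves() == 1
        assert np.all(tree.predict([[0.5], [9.0]]) == 1)

    def test_threshold_separable_one_split(self):
        x = np.concatenate([np.linspace(-1, -0.1, 10), np.linspace(0.1, 1, 10)])
        y = (x >= 0).astype(int)
        tree = J48Tree(prune=False).fit(x[:, None], y)
        assert np.all(tree.predict(x[:, None]) == y)
        assert tree.depth() == 1
        assert -0.1 < tree._root.threshold < 0.1

    def test_gain_ratio_matches_entropy_oracle(self):
        y = np.array([0, 0, 1, 1])
        mask = np.array([True, True, True, False])  # 2x0+1x1 left, 1x1 right
        gain, ratio = gain_ratio(y, mask)

        def h(ps):
            ps = [p for p in ps if p > 0]
            return -sum(p * np.log2(p) for p in ps)

        expected_gain = h([0.5, 0.5]) - (3 / 4) * h([2 / 3, 1 / 3]) - (1 / 4) * h([1.0])
        expected_ratio = expected_gain / h([3 / 4, 1 / 4])
        assert gain == pytest.approx(expected_gain, abs=1e-12)
        assert ratio == pytest.approx(expected_ratio, abs=1e-12)

    def test_training_accuracy_nondecreasing_in_depth_cap(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        accs = []
        for cap in (1, 2, 4, 8):
            tree = J48Tree(prune=False, max_depth=cap).fit(X, y)
            accs.append((tree.predict(X) == y).mean())
        assert accs == sorted(accs)

    def test_random_tree_deterministic_under_seed(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        p1 = RandomTree(seed=3).fit(X, y).predict_proba(X)
        p2 = RandomTree(seed=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)


class TestForest:
    def test_single_tree_no_bootstrap_equals_random_tree(self, rng):
        X = rng.normal(size=(50, 4))
        y = (X[:, 1] > 0).astype(int)
        forest = RandomForest(n_trees=1, bootstrap=False, seed=9).fit(X, y)
        tree = RandomTree(seed=9).fit(X, y)
        np.testing.assert_array_equal(forest.predict_proba(X), tree.predict_proba(X))

    def test_default_member_count_is_ten(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 2, 20)
        assert len(RandomForest().fit(X, y).members_) == 10

    def test_predict_is_argmax_of_proba(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        for kind in ("knn", "j48", "random_tree", "random_forest"):
            clf = make_classifier(kind).fit(X, y)
            p = clf.predict_proba(X)
            expected = np.argmax(p, axis=1)
            ties = p[:, 0] == p[:, 1]
            pred = clf.predict(X)
            np.testing.assert_array_equal(pred[~ties], expected[~ties])
            assert np.all(pred[ties] == 0) or kind == "knn"  # knn ties use distance


def test_binary_entropy_bounds():
    assert binary_entropy([5, 5]) == pytest.approx(1.0)
    assert binary_entropy([10, 0]) == 0.0
    assert binary_entropy([0, 0]) == 0.0
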