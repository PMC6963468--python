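import numpy as np
import pytest

from mammocad import (
    AdaBoostEnsemble,
    AveragingEnsemble,
    BaggingEnsemble,
    J48Tree,
    LabeledDataset,
    averaging_mcs,
    cross_validate,
)
from mammocad.errors import ParameterError


class _FixedProba:
    """Stub member returning a constant probability matrix."""

    def __init__(self, rows):
        self.rows = np.asarray(rows, dtype=float)

    def predict_proba(self, Q):
        return np.tile(self.rows, (len(Q), 1)) if self.rows.ndim == 1 else self.rows

    def predict(self, Q):
        return np.argmax(self.predict_proba(Q), axis=1)


def _separable(rng, n=60):
    X = rng.normal(size=(n, 3))
    y = (X[:, 0] > 0).astype(int)
    return X, y


class TestBagging:
    def test_size_one_without_resampling_equals_base(self, rng):
        X, y = _separable(rng)
        bag = BaggingEnsemble(lambda: J48Tree(prune=False), size=1, resample=False).fit(X, y)
        single = J48Tree(prune=False).fit(X, y)
        np.testing.assert_array_equal(bag.predict_proba(X), single.predict_proba(X))

    def test_default_member_count_is_ten(self, rng):
        X, y = _separable(rng)
        assert len(BaggingEnsemble(lambda: J48Tree(prune=False)).fit(X, y).members_) == 10

    def test_average_within_member_envelope(self, rng):
        X, y = _separable(rng)
        bag = BaggingEnsemble(lambda: J48Tree(prune=False), size=5, seed=1).fit(X, y)
        probs = np.array([m.predict_proba(X)[:, 1] for m in bag.members_])
        avg = bag.predict_proba(X)[:, 1]
        assert np.all(avg >= probs.min(axis=0) - 1e-12)
        assert np.all(avg <= probs.max(axis=0) + 1e-12)


class TestAdaBoost:
    def test_zero_error_round_one_stops_early(self, rng):
        # wide class margin: any resampled tree separates the full set
        X = np.concatenate([rng.uniform(-2, -1, 30), rng.uniform(1, 2, 30)])[:, None]
        y = (X[:, 0] > 0).astype(int)
        boost = AdaBoostEnsemble(lambda: J48Tree(prune=False), size=10, seed=0).fit(X, y)
        assert len(boost.members_) == 1
        assert np.all(boost.predict(X) == y)

    def test_weights_renormalized_each_round(self, rng):
        X = rng.normal(size=(80, 2))
        y = (X[:, 0] + 0.8 * rng.normal(size=80) > 0).astype(int)
        boost = AdaBoostEnsemble(lambda: J48Tree(prune=False, max_depth=1), size=10, seed=0)
        boost.fit(X, y)
        for w in boost.weight_history_:
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_boosting_beats_single_stump_on_xor_like_data(self):
        # four unequal clusters in an XOR-like layout: a single axis-aligned
        # stump tops out near the largest-cluster split, boosting does better
        rng = np.random.default_rng(0)
        centers = [((0, 0), 0, 25), ((1, 1), 0, 15), ((0, 1), 1, 15), ((1, 0), 1, 25)]
        X, y = [], []
        for (cx, cy), label, count in centers:
            X.append(np.column_stack([
                rng.normal(cx, 0.15, count), rng.normal(cy, 0.15, count)
            ]))
            y.extend([label] * count)
        data = LabeledDataset(X=np.vstack(X), y=np.array(y))
        stump = lambda: J48Tree(prune=False, max_depth=1)
        acc_single = cross_validate(data, stump, folds=5, rng_seed=0).accuracy
        acc_boost = cross_validate(
            data, lambda: AdaBoostEnsemble(stump, size=10, seed=0), folds=5, rng_seed=0
        ).accuracy
        assert acc_boost > acc_single

    def test_probability_rows_sum_to_one(self, rng):
        X, y = _separable(rng)
        boost = AdaBoostEnsemble(lambda: J48Tree(prune=False, max_depth=1), size=5, seed=2)
        p = boost.fit(X, y).predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(50, 2))
        y = (X.sum(axis=1) + 0.5 * rng.normal(size=50) > 0).astype(int)
        make = lambda: AdaBoostEnsemble(lambda: J48Tree(prune=False, max_depth=2), size=8, seed=7)
        np.testing.assert_array_equal(
            make().fit(X, y).predict_proba(X), make().fit(X, y).predict_proba(X)
        )


class TestAveraging:
    def test_identical_members_equal_single_member(self):
        member = _FixedProba([0.3, 0.7])
        fused = averaging_mcs([member, member, member])
        np.testing.assert_allclose(fused.predict_proba(np.zeros((4, 1))), [[0.3, 0.7]] * 4)

    def test_opposite_certainty_ties_to_class_zero(self):
        fused = averaging_mcs([_FixedProba([1.0, 0.0]), _FixedProba([0.0, 1.0])])
        p = fused.predict_proba(np.zeros((2, 1)))
        np.testing.assert_allclose(p, 0.5)
        assert np.all(fused.predict(np.zeros((2, 1))) == 0)

    def test_mean_matches_elementwise_oracle(self, rng):
        mats = [rng.dirichlet([1, 1], size=9) for _ in range(4)]
        fused = AveragingEnsemble([_FixedProba(m) for m in mats])
        np.testing.assert_allclose(
            fused.predict_proba(np.zeros((9, 1))), sum(mats) / 4, atol=1e-12
        )

    def test_requires_two_members(self):
        with pytest.raises(ParameterError):
            averaging_mcs([_FixedProba([1, 0])])

    def test_permutation_invariant(self, rng):
        mats = [rng.dirichlet([1, 1], size=5) for _ in range(3)]
        a = AveragingEnsemble([_FixedProba(m) for m in mats]).predict_proba(np.zeros((5, 1)))
        b = AveragingEnsemble([_FixedProba(m) for m in mats[::-1]]).predict_proba(np.zeros((5, 1)))
        np.testing.assert_allclose(a, b)
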