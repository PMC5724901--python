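import numpy as np
import pytest

from retinaseg import adaboost as ab
from retinaseg.adaboost import (
    DegenerateLearnerError,
    EnsembleModel,
    TreeNodes,
    adaboost_train,
    ensemble_score,
    staged_scores,
    train_weak,
    validate_length,
)


def _leaf(vote: int) -> TreeNodes:
    """Single-leaf tree voting a constant class."""
    return TreeNodes(
        feature=np.array([-2]),
        threshold=np.array([-2.0]),
        left=np.array([-1]),
        right=np.array([-1]),
        leaf_value=np.array([vote]),
    )


def _stump(feature: int, threshold: float, left_vote: int, right_vote: int) -> TreeNodes:
    return TreeNodes(
        feature=np.array([feature, -2, -2]),
        threshold=np.array([threshold, -2.0, -2.0]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        leaf_value=np.array([0, left_vote, right_vote]),
    )


class TestTrainWeak:
    def test_separable_1d_stump_perfect(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.where(X.ravel() < 5, -1, 1)
        tree = train_weak(X, y, np.full(10, 0.1), max_depth=1)
        assert (tree.predict(X) == y).all()

    def test_inseparable_point_stump_error_quarter(self):
        # one point breaks separability; exhaustive threshold search shows
        # no stump does better than 1/4 under uniform weights
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, -1, 1, 1])
        best = min(
            min(
                (np.where(X.ravel() <= t, s, -s) != y).mean()
                for s in (-1, 1)
            )
            for t in (-0.5, 0.5, 1.5, 2.5, 3.5)
        )
        assert best == pytest.approx(0.25)
        tree = train_weak(X, y, np.full(4, 0.25), max_depth=1)
        eps = 0.25 * (tree.predict(X) != y).sum()
        assert eps == pytest.approx(0.25)

    def test_heavy_weight_point_respected(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, -1, -1, -1])
        weights = np.array([0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3])
        tree = train_weak(X, y, weights, max_depth=1)
        assert tree.predict(np.array([[0.0]]))[0] == 1

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLearnerError):
            train_weak(np.zeros((3, 1)), np.ones(3), np.full(3, 1 / 3))

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            train_weak(np.zeros((3, 1)), np.array([0, 1, 2]), np.full(3, 1 / 3))


def _mirror_algorithm(X, y, n_rounds, max_depth, seed):
    """Step the boosting recursion independently, tracking the distribution.

    Returns (alphas, epsilons, distribution sums, misclassified-mass values)
    so the implementation's trajectory can be compared step by step.
    """
    m = len(y)
    D = np.full(m, 1.0 / m)
    alphas, epss, sums, miss_mass = [], [], [], []
    for _ in range(n_rounds):
        tree = train_weak(X, y, D, max_depth=max_depth, random_state=seed)
        pred = tree.predict(X)
        miss = pred != y
        eps = D[miss].sum()
        if eps >= 0.5:
            break
        eps_eff = max(eps, 1e-10)
        alpha = 0.5 * np.log((1 - eps_eff) / eps_eff)
        z = 2 * np.sqrt(eps_eff * (1 - eps_eff))
        alphas.append(alpha)
        epss.append(eps)
        if eps == 0:
            break
        D = D / z * np.exp(np.where(miss, alpha, -alpha))
        sums.append(D.sum())
        miss_mass.append(D[miss].sum())
        D = D / D.sum()
    return alphas, epss, sums, miss_mass


def _noisy_blobs(rng, n=60):
    X = rng.standard_normal((n, 2))
    y = np.where(X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(n) > 0, 1, -1)
    return X, y


class TestAdaboostTrain:
    def test_alpha_formula_eps_point_one(self):
        # best stump errs on exactly one of ten uniformly-weighted samples
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.where(X.ravel() < 5, -1, 1)
        y[0] = 1  # inseparable point
        model = adaboost_train(X, y, n_rounds=1, max_depth=1)
        assert model.errors[0] == pytest.approx(0.1)
        assert model.alphas[0] == pytest.approx(0.5 * np.log(9.0))

    def test_distribution_stays_normalized_and_half_mass_on_misses(self, rng):
        X, y = _noisy_blobs(rng)
        model = adaboost_train(X, y, n_rounds=8, max_depth=1, seed=0)
        alphas, epss, sums, miss_mass = _mirror_algorithm(X, y, 8, 1, 0)
        assert np.allclose(model.alphas, alphas)
        assert np.allclose(model.errors, epss)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.allclose(miss_mass, 0.5, atol=1e-9)

    def test_training_error_bounded_by_product_of_z(self, rng):
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            X, y = _noisy_blobs(r)
            model = adaboost_train(X, y, n_rounds=20, max_depth=1, seed=seed)
            margins = np.zeros(len(y))
            bound = 1.0
            for alpha, z, tree in zip(model.alphas, model.zs, model.learners):
                margins += alpha * tree.predict(X)
                bound *= z
                err = (np.where(margins >= 0, 1, -1) != y).mean()
                assert err <= bound + 1e-12

    def test_separable_data_reaches_zero_error(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array([-1] * 20 + [1] * 20)
        model = adaboost_train(X, y, n_rounds=20, max_depth=1)
        pred = np.where(ensemble_score(model, X) >= 0, 1, -1)
        assert (pred == y).all()

    def test_early_stop_at_chance_error(self):
        # constant feature, balanced labels: any tree has eps = 0.5
        X = np.zeros((10, 1))
        y = np.array([1, -1] * 5)
        model = adaboost_train(X, y, n_rounds=10, max_depth=2)
        assert model.n_rounds == 0

    def test_perfect_round_caps_alpha_and_stops(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([-1, -1, 1, 1])
        model = adaboost_train(X, y, n_rounds=10, max_depth=1)
        assert model.n_rounds == 1
        assert model.errors[0] == 0.0
        assert model.alphas[0] == pytest.approx(0.5 * np.log((1 - 1e-10) / 1e-10))

    def test_deterministic_given_seed(self, rng):
        X, y = _noisy_blobs(rng)
        a = adaboost_train(X, y, 10, max_depth=2, seed=5)
        b = adaboost_train(X, y, 10, max_depth=2, seed=5)
        assert a.to_dict() == b.to_dict()


class TestEnsembleScore:
    def test_empty_model_zero_margin(self):
        assert ensemble_score(EnsembleModel(), np.array([[1.0, 2.0]]))[0] == 0.0

    def test_single_round_unit_margin(self):
        model = EnsembleModel(learners=[_leaf(1)], alphas=[1.0])
        assert ensemble_score(model, np.array([[0.0]]))[0] == 1.0

    def test_two_round_arithmetic(self):
        model = EnsembleModel(learners=[_leaf(1), _leaf(-1)], alphas=[1.0, 0.5])
        assert ensemble_score(model, np.array([[0.0]]))[0] == pytest.approx(0.5)


class TestValidateLength:
    def test_strictly_decreasing_curve_picks_last(self):
        # first learner wrong on one of two samples, later learners fix it
        model = EnsembleModel(
            learners=[_stump(0, 0.5, -1, 1), _leaf(1), _leaf(1)],
            alphas=[1.0, 1.0, 1.0],
        )
        X = np.array([[0.0], [1.0]])
        y = np.array([1, 1])
        errors = [
            (np.where(m >= 0, 1, -1) != y).mean() for m in staged_scores(model, X)
        ]
        assert errors == [0.5, 0.0, 0.0]
        assert validate_length(model, X, y) == 2

    def test_dip_then_rise_picks_dip(self):
        model = EnsembleModel(
            learners=[_leaf(-1), _leaf(1), _leaf(1), _leaf(-1), _leaf(-1), _leaf(-1)],
            alphas=[1.0] * 6,
        )
        X = np.array([[0.0]])
        y = np.array([1])
        errors = [
            (np.where(m >= 0, 1, -1) != y).mean() for m in staged_scores(model, X)
        ]
        assert errors == [1.0, 0.0, 0.0, 0.0, 1.0, 1.0]
        assert validate_length(model, X, y) == 2

    def test_empty_holdout_rejected(self):
        model = EnsembleModel(learners=[_leaf(1)], alphas=[1.0])
        with pytest.raises(ValueError):
            validate_length(model, np.empty((0, 1)), np.empty(0))


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, rng, tmp_path):
        X, y = _noisy_blobs(rng)
        model = adaboost_train(X, y, 5, max_depth=2)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = EnsembleModel.load(path)
        assert np.allclose(ensemble_score(model, X), ensemble_score(loaded, X))
        assert loaded.alphas == model.alphas
        assert loaded.format_version == 1

    def test_truncated_prefix(self, rng):
        X, y = _noisy_blobs(rng)
        model = adaboost_train(X, y, 6, max_depth=1)
        short = model.truncated(2)
        assert short.n_rounds == 2
        assert short.alphas == model.alphas[:2]
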