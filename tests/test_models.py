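import numpy as np
import pytest

from tcrdiag.features import FeatureMatrix
from tcrdiag.models import (
    DEFAULT_GRIDS,
    FAMILIES,
    ModelSpec,
    TrainedModel,
    auc_score,
    benchmark_all,
    derive_seed,
    evaluate,
    fit_final,
    grid_search_cv,
    roc_points,
    stratified_kfold,
    _fit_one,
)
from tcrdiag.nets import CNNNet, MLPNet, TransformerNet, _bce_grad


def _fm(X, y, prefix="f"):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X=X,
        y=np.asarray(y, dtype=int),
        sample_ids=[f"s{i}" for i in range(len(X))],
        feature_names=[f"{prefix}{j}" for j in range(X.shape[1])],
    )


def _separable_fm(n=60, m=8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, m))
    X[:, 0] += 6.0 * y
    return _fm(X, y)


class TestStratifiedKFold:
    def test_partition_covers_each_sample_once(self):
        fm = _separable_fm(40)
        folds = stratified_kfold(fm, k=5, seed=0)
        seen = np.concatenate([v for _, v in folds])
        assert sorted(seen) == list(range(40))

    def test_balanced_cohort_exact_fold_composition(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 50 + [0] * 50)
        fm = _fm(rng.normal(size=(100, 3)), y)
        for _, val in stratified_kfold(fm, k=5, seed=1):
            assert int(fm.y[val].sum()) == 10
            assert len(val) == 20

    def test_unbalanced_fold_counts_within_apportionment(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 37 + [0] * 56)
        fm = _fm(rng.normal(size=(93, 2)), y)
        for _, val in stratified_kfold(fm, k=5, seed=1):
            assert int(fm.y[val].sum()) in (7, 8)

    def test_class_smaller_than_k_rejected(self):
        fm = _fm(np.zeros((6, 1)), [1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError):
            stratified_kfold(fm, k=5)


class TestAucAndRoc:
    def test_three_of_four_pairs_concordant(self):
        assert auc_score([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]) == 0.75

    def test_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_score([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([1, 1], [0.1, 0.2])

    def test_roc_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        pts = roc_points(rng.integers(0, 2, 50), rng.random(50))
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_pair_counting_equals_trapezoidal_area(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.choice(np.round(rng.random(10), 2), size=n)  # forces ties
            pts = roc_points(y, s)
            area = np.trapezoid(pts[:, 1], pts[:, 0])
            assert auc_score(y, s) == pytest.approx(area, abs=1e-10)


class TestGridSearch:
    def test_one_point_grid_is_the_winner(self):
        spec = ModelSpec("logistic_regression", grid={"C": [1.0]}, seed=0)
        cv = grid_search_cv(spec, _separable_fm())
        assert cv.best_params == {"C": 1.0}

    def test_winner_maximizes_mean_auc(self):
        spec = ModelSpec("knn", seed=0)
        cv = grid_search_cv(spec, _separable_fm(seed=3))
        assert cv.best_mean_auc == max(cv.mean_aucs)
        assert cv.best_index == int(np.argmax(cv.mean_aucs))

    def test_separable_data_logistic_regression(self):
        cv = grid_search_cv(ModelSpec("logistic_regression", seed=1), _separable_fm())
        assert cv.best_mean_auc >= 0.99

    def test_naive_bayes_empty_grid_evaluates_defaults(self):
        cv = grid_search_cv(ModelSpec("naive_bayes", seed=0), _separable_fm())
        assert cv.grid_points == [{}]
        assert cv.best_mean_auc > 0.9

    def test_failing_grid_point_flagged_not_dropped(self):
        # receptive field larger than the feature vector fails at build time
        spec = ModelSpec(
            "cnn", grid={"kernel_size": [3, 101], "filters": [2]}, seed=0
        )
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 30)
        X = rng.normal(size=(60, 8)) + 2.0 * y[:, None]  # signal in every column
        cv = grid_search_cv(spec, _fm(X, y))
        failing = [i for i, p in enumerate(cv.grid_points) if p["kernel_size"] == 101]
        assert cv.failures == failing
        assert cv.mean_aucs[failing[0]] == 0.5
        assert cv.best_params["kernel_size"] == 3

    def test_invalid_hyperparameter_rejected_up_front(self):
        with pytest.raises(ValueError):
            ModelSpec("logistic_regression", grid={"bogus": [1]})


class TestFitAndEvaluate:
    def test_scores_are_probabilities_for_all_families(self):
        fm = _separable_fm(n=40)
        small = {
            "mlp": {"hidden_sizes": (8,), "epochs": 5},
            "cnn": {"filters": 2, "kernel_size": 3, "epochs": 5},
            "transformer": {"d_model": 8, "nhead": 2, "epochs": 3},
            "random_forest": {"n_estimators": 20},
            "gradient_boosting": {"n_estimators": 20},
            "adaboost": {"n_estimators": 20},
        }
        for family in FAMILIES:
            model = _fit_one(family, small.get(family, {}), fm.X, fm.y, seed=0)
            s = model.score_samples(fm.X)
            assert np.isfinite(s).all()
            assert ((0 <= s) & (s <= 1)).all()

    def test_deterministic_families_refit_identically(self):
        fm = _separable_fm()
        for family in ("decision_tree", "logistic_regression", "naive_bayes", "knn"):
            a = _fit_one(family, {}, fm.X, fm.y, seed=7).score_samples(fm.X)
            b = _fit_one(family, {}, fm.X, fm.y, seed=7).score_samples(fm.X)
            assert np.array_equal(a, b)

    def test_perfect_separation_metrics(self):
        fm = _fm(np.zeros((4, 1)), [1, 0, 1, 0])

        class Stub:
            family = "stub"

            def score_samples(self, X):
                return np.array([0.9, 0.1, 0.8, 0.2])

        rep = evaluate(Stub(), fm)
        assert (rep.accuracy, rep.auc, rep.recall, rep.f1) == (1.0, 1.0, 1.0, 1.0)


class TestNeuralNets:
    def _grad_check(self, net, n=5, m=10, tol=1e-5):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n, m))
        y = rng.integers(0, 2, n).astype(float)
        net._build(m, np.random.default_rng(1))
        net._built = True
        logits, cache = net._forward(X, train=True, rng=np.random.default_rng(2))
        _, dlog = _bce_grad(logits, y)
        grads = net._backward(dlog, cache)
        for k, g in grads.items():
            p = net.params[k]
            it = np.nditer(p, flags=["multi_index"])
            num = np.zeros_like(p)
            for _ in it:
                idx = it.multi_index
                eps, orig = 1e-6, p[idx]
                p[idx] = orig + eps
                l1, _ = _bce_grad(net._forward(X, True, np.random.default_rng(2))[0], y)
                p[idx] = orig - eps
                l2, _ = _bce_grad(net._forward(X, True, np.random.default_rng(2))[0], y)
                p[idx] = orig
                num[idx] = (l1 - l2) / (2 * eps)
            rel = np.max(np.abs(g - num)) / max(np.max(np.abs(num)), 1e-8)
            assert rel < tol, f"{type(net).__name__} {k}: rel err {rel:.2e}"

    def test_mlp_gradients_match_finite_differences(self):
        self._grad_check(MLPNet(hidden_sizes=(4,), dropout=0.0))

    @pytest.mark.parametrize("pooling", ["max", "avg"])
    def test_cnn_gradients_match_finite_differences(self, pooling):
        self._grad_check(CNNNet(filters=2, kernel_size=3, pooling=pooling, dropout=0.0))

    def test_transformer_gradients_match_finite_differences(self):
        self._grad_check(
            TransformerNet(d_model=8, nhead=2, num_layers=1, dim_feedforward=6,
                           dropout=0.0),
            m=6,
        )

    def test_transformer_d_model_head_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            TransformerNet(d_model=10, nhead=3)

    def test_transformer_batch_pointwise_invariance(self):
        net = TransformerNet(d_model=8, nhead=2, epochs=2, dropout=0.0, seed=0)
        rng = np.random.default_rng(0)
        X = rng.random((4, 6))
        net.fit(X, np.array([0, 1, 0, 1.0]))
        single = net.decision_function(X[:1])
        dup = net.decision_function(np.vstack([X[0], X[0], X[2]]))
        assert dup[0] == pytest.approx(dup[1], abs=1e-12)
        assert single[0] == pytest.approx(dup[0], abs=1e-12)

    def test_transformer_zero_input_finite_baseline(self):
        net = TransformerNet(d_model=8, nhead=2, epochs=2, seed=0)
        rng = np.random.default_rng(1)
        net.fit(rng.random((6, 5)), np.array([0, 1, 0, 1, 0, 1.0]))
        z = net.decision_function(np.zeros((3, 5)))
        assert np.isfinite(z).all()
        assert z[0] == z[1] == z[2]

    def test_eval_mode_forward_is_deterministic(self):
        net = TransformerNet(d_model=8, nhead=2, epochs=2, dropout=0.5, seed=0)
        rng = np.random.default_rng(2)
        X = rng.random((6, 5))
        net.fit(X, np.array([0, 1, 0, 1, 0, 1.0]))
        assert np.array_equal(net.decision_function(X), net.decision_function(X))

    def test_nan_input_rejected(self):
        net = MLPNet(epochs=1)
        X = np.zeros((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="nan"):
            net.fit(X, np.zeros(4))

    def test_same_seed_training_is_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        y = rng.integers(0, 2, 20).astype(float)
        a = MLPNet(hidden_sizes=(8,), epochs=10, seed=5).fit(X, y)
        b = MLPNet(hidden_sizes=(8,), epochs=10, seed=5).fit(X, y)
        assert np.array_equal(a.decision_function(X), b.decision_function(X))


def test_benchmark_table_complete_and_ranked():
    fm_train = _separable_fm(n=60, seed=4)
    fm_test = _separable_fm(n=30, seed=5)
    specs = [
        ModelSpec("logistic_regression", grid={"C": [1.0]}, seed=derive_seed(0, "lr")),
        ModelSpec("naive_bayes", seed=derive_seed(0, "nb")),
        ModelSpec("decision_tree", grid={"max_depth": [3]}, seed=derive_seed(0, "dt")),
    ]
    table, models, reports = benchmark_all(specs, fm_train, fm_test)
    assert len(table) == 3
    assert set(models) == {s.family for s in specs}
    assert (table["test_auc"].to_numpy()[:-1] >= table["test_auc"].to_numpy()[1:]).all()
    for col in ("test_auc", "test_accuracy", "test_recall", "test_f1"):
        assert table[col].notna().all()
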