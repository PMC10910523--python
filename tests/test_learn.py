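"""Penalized logistic regression: weights, objective, grid search, prediction."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from lupusnlp.features import FeatureMatrix
from lupusnlp.learn import (DEFAULT_C_GRID, PenalizedLogisticModel,
                            TrainingConfig, balanced_class_weights, classify,
                            fit_l2_logreg, grid_search_c, logreg_objective,
                            predict_proba)


def fm_from(X, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return FeatureMatrix([f"p{i}" for i in range(X.shape[0])], names,
                         ["cui_count"] * X.shape[1], X)


def simulated(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    logits = 2.0 * X[:, 0] - 1.0 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    return fm_from(X), y


class TestBalancedWeights:
    def test_one_quarter_positives(self):
        w = balanced_class_weights([1] * 25 + [0] * 75)
        assert w[1] == pytest.approx(2.0)
        assert w[0] == pytest.approx(2 / 3)

    def test_balanced_labels_give_unit_weights(self):
        w = balanced_class_weights([0, 1] * 10)
        assert w == {0: 1.0, 1: 1.0}

    def test_178_294_cohort_split(self):
        w = balanced_class_weights([1] * 178 + [0] * 294)
        assert w[1] == pytest.approx(472 / (2 * 178))
        assert w[0] == pytest.approx(472 / (2 * 294))
        assert w[1] == pytest.approx(1.3258, abs=1e-4)
        assert w[0] == pytest.approx(0.8027, abs=1e-4)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            balanced_class_weights([1, 1, 1])


class TestFit:
    def test_separable_data_has_finite_growing_coefficient(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = [0, 0, 1, 1]
        small = fit_l2_logreg(fm_from(X), y, C=0.1)
        large = fit_l2_logreg(fm_from(X), y, C=100.0)
        assert np.isfinite(small.coef).all() and np.isfinite(large.coef).all()
        assert abs(large.coef[0]) > abs(small.coef[0])

    def test_all_zero_column_gets_exactly_zero_coefficient(self):
        fm, y = simulated()
        X = np.column_stack([fm.values, np.zeros(len(y))])
        model = fit_l2_logreg(fm_from(X), y, C=1.0)
        assert model.coef[-1] == 0.0

    def test_agrees_with_independent_optimizer(self):
        """Coefficients and objective match an independently implemented
        solver (scikit-learn's lbfgs path) on a small fixture."""
        X = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0], [0.0, 0.0],
                      [2.0, 1.0], [1.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 0])
        C = 0.7
        model = fit_l2_logreg(fm_from(X), y, C=C)
        sk = LogisticRegression(C=C, class_weight="balanced", solver="lbfgs",
                                tol=1e-12, max_iter=50_000).fit(X, y)
        w = np.where(y == 1, balanced_class_weights(y)[1],
                     balanced_class_weights(y)[0])
        ours = logreg_objective(np.concatenate(([model.intercept], model.coef)),
                                X, y.astype(float), w, C)[0]
        theirs = logreg_objective(np.concatenate((sk.intercept_, sk.coef_[0])),
                                  X, y.astype(float), w, C)[0]
        assert ours <= theirs + 1e-6
        assert np.allclose(model.coef, sk.coef_[0], atol=1e-5)

    def test_non_finite_features_error(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="finite"):
            fit_l2_logreg(fm_from(X), [0, 1], C=1.0)

    def test_regularization_path_norm_non_decreasing(self):
        fm, y = simulated(seed=4)
        norms = [np.linalg.norm(fit_l2_logreg(fm, y, C=C).coef)
                 for C in (1e-3, 1e-2, 1e-1, 1, 10, 100)]
        assert all(b >= a - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_balanced_weights_equal_minority_replication(self):
        """Balanced class weights act like replicating the minority class.

        With 25 positives / 75 negatives the balanced weights are
        (2, 2/3) = 2/3 * (3, 1), i.e. the weighted likelihood is 2/3 of the
        likelihood of the dataset with positives replicated 3x; fitting the
        replicated data at C' = (2/3) C makes the two objectives exactly
        proportional, so the minimizers coincide.
        """
        rng = np.random.default_rng(2)
        Xp, Xn = rng.normal(1.0, 1.0, (25, 2)), rng.normal(0.0, 1.0, (75, 2))
        X = np.vstack([Xp, Xn])
        y = np.array([1] * 25 + [0] * 75)
        balanced = fit_l2_logreg(fm_from(X), y, C=1.0,
                                 config=TrainingConfig(class_weight="balanced"))
        Xr = np.vstack([Xp, Xp, Xp, Xn])
        yr = np.array([1] * 75 + [0] * 75)
        replicated = fit_l2_logreg(fm_from(Xr), yr, C=2 / 3,
                                   config=TrainingConfig(class_weight="none"))
        assert np.allclose(balanced.coef, replicated.coef, atol=1e-6)
        assert balanced.intercept == pytest.approx(replicated.intercept, abs=1e-6)


class TestPlantedSignalRecovery:
    def test_lupus_nephritis_cui_ranks_among_top_positive_coefficients(
            self, lexicon, negation_rules, patterns, rule_config):
        """On a planted-signal corpus the mixed model recovers the lupus
        nephritis concept (C0024143) as a top-5 positive coefficient."""
        from lupusnlp.evaluate import top_coefficients
        from lupusnlp.features import MixedFeatureSpec, build_mixed_matrix
        from lupusnlp.synth import SynthConfig, generate_corpus

        corpus = generate_corpus(SynthConfig(n_patients=300, notes_mean=25,
                                             notes_sd=12, seed=19))
        fm = build_mixed_matrix(corpus, MixedFeatureSpec(), lexicon,
                                negation_rules, patterns, rule_config)
        y = [int(p.gold_label) for p in corpus.patients]
        model = fit_l2_logreg(fm, y, C=1.0)
        top5 = [name for name, coef in top_coefficients(model, 5)]
        assert "C0024143" in top5
        assert model.coef[fm.feature_names.index("C0024143")] > 0


class TestGridSearch:
    def test_single_value_grid_returns_it(self):
        fm, y = simulated()
        config = TrainingConfig(c_grid=(0.5,), cv_folds=3)
        best, table = grid_search_c(fm, y, config)
        assert best == 0.5 and len(table) == 1

    def test_default_grid_has_11_log_spaced_values(self):
        fm, y = simulated()
        _, table = grid_search_c(fm, y, TrainingConfig(cv_folds=3))
        assert len(table) == 11
        assert [c for c, _ in table] == [10.0 ** k for k in range(-5, 6)]

    def test_best_c_beats_grid_extremes_on_strong_signal(self):
        fm, y = simulated(n=200, seed=8)
        best, table = grid_search_c(fm, y, TrainingConfig(cv_folds=5))
        scores = dict(table)
        assert scores[best] >= scores[DEFAULT_C_GRID[0]]
        assert scores[best] >= scores[DEFAULT_C_GRID[-1]]

    def test_tiny_minority_class_errors(self):
        fm, _ = simulated(n=10)
        with pytest.raises(ValueError):
            grid_search_c(fm, [1] + [0] * 9, TrainingConfig(cv_folds=5))


class TestPrediction:
    def test_zero_model_gives_half_probability_and_negative_class(self):
        fm, y = simulated(n=10)
        model = PenalizedLogisticModel(
            feature_names=list(fm.feature_names), coef=np.zeros(3),
            intercept=0.0, C=1.0, class_weights={0: 1.0, 1: 1.0})
        proba = predict_proba(model, fm)
        assert np.allclose(proba, 0.5)
        assert not classify(model, fm, threshold=0.5).any()  # strict >

    def test_threshold_behavior_near_half(self):
        # A 0.49 score is called negative and 0.53 positive at the 0.5 cut.
        model = PenalizedLogisticModel(
            feature_names=["x"], coef=np.array([1.0]), intercept=0.0,
            C=1.0, class_weights={0: 1.0, 1: 1.0})
        logit = lambda p: np.log(p / (1 - p))
        fm = fm_from(np.array([[logit(0.49)], [logit(0.53)]]), names=["x"])
        assert classify(model, fm).tolist() == [False, True]

    def test_probability_monotone_in_positive_coefficient_feature(self):
        model = PenalizedLogisticModel(
            feature_names=["x"], coef=np.array([2.0]), intercept=-1.0,
            C=1.0, class_weights={0: 1.0, 1: 1.0})
        grid = fm_from(np.linspace(-3, 3, 20)[:, None], names=["x"])
        proba = predict_proba(model, grid)
        assert (np.diff(proba) >= 0).all()

    def test_feature_name_mismatch_lists_names(self):
        model = PenalizedLogisticModel(
            feature_names=["a", "b"], coef=np.zeros(2), intercept=0.0,
            C=1.0, class_weights={0: 1.0, 1: 1.0})
        with pytest.raises(ValueError, match="missing=\\['b'\\]"):
            predict_proba(model, fm_from(np.zeros((2, 2)), names=["a", "c"]))

    def test_reordered_features_align_to_model(self):
        model = PenalizedLogisticModel(
            feature_names=["a", "b"], coef=np.array([1.0, -1.0]), intercept=0.0,
            C=1.0, class_weights={0: 1.0, 1: 1.0})
        X = np.array([[1.0, 0.0]])
        direct = predict_proba(model, fm_from(X, names=["a", "b"]))
        swapped = predict_proba(model, fm_from(X[:, ::-1], names=["b", "a"]))
        assert direct == pytest.approx(swapped)


class TestModelPersistence:
    def test_json_round_trip(self, tmp_path):
        fm, y = simulated()
        model = fit_l2_logreg(fm, y, C=2.0)
        model.to_json(tmp_path / "m.json")
        back = PenalizedLogisticModel.from_json(tmp_path / "m.json")
        assert back.feature_names == model.feature_names
        assert np.allclose(back.coef, model.coef)
        assert back.C == model.C and back.class_weights == model.class_weights
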