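"""Regression metrics, model competition and dose prediction."""

import warnings

import numpy as np
import pytest

from placebomatch.cluster import kmeans_fit
from placebomatch.colors import RGBColor
from placebomatch.dataio import PIGMENT_COLUMNS, Standardizer
from placebomatch.regress import (
    MODEL_ORDER,
    CompetitionConfig,
    CVScore,
    compete,
    fit_final,
    predict_formula,
    r2,
    rmse,
    select_winner,
)

from conftest import FAST_GRIDS


def _score(name, mean_rmse, mean_r2=0.0):
    return CVScore(name, mean_rmse, mean_r2, {}, {}, {})


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2, 3])
        assert rmse(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_hand_arithmetic(self):
        # SS_res = 2, SS_tot = 2
        assert rmse([0, 2], [1, 1]) == pytest.approx(1.0)
        assert r2([0, 2], [1, 1]) == pytest.approx(0.0)

    def test_mean_predictor_scores_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        assert r2(y, np.full(30, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracles(self):
        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        assert rmse(y, yhat) == pytest.approx(np.sqrt(np.mean((y - yhat) ** 2)), abs=1e-12)
        exp_r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2(y, yhat) == pytest.approx(exp_r2, abs=1e-12)

    def test_constant_target_rejected_for_r2(self):
        with pytest.raises(ValueError, match="constant"):
            r2([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])


class TestSelectWinner:
    def test_minimal_rmse_wins(self):
        # a realistic cluster table: the forest's 20.6 is minimal
        table = [
            _score("linear", 56.5449, 0.4618),
            _score("random_forest", 20.6466, 0.9305),
            _score("gradient_boosting", 30.7755, 0.8382),
            _score("svr", 78.7574, 0.2451),
            _score("ridge", 56.5589, 0.4614),
        ]
        assert select_winner(table) == "random_forest"

    def test_all_equal_falls_back_to_fixed_order(self):
        table = [_score(n, 5.0, 0.5) for n in reversed(MODEL_ORDER)]
        assert select_winner(table) == "linear"

    def test_rmse_tie_broken_by_r2(self):
        table = [_score("linear", 5.0, 0.4), _score("ridge", 5.0, 0.9)]
        assert select_winner(table) == "ridge"

    def test_single_entry(self):
        assert select_winner([_score("svr", 9.9)]) == "svr"


class TestCompete:
    def test_realizable_linear_hypothesis(self):
        # noise-free linear dose -> color map, inverted: linear family is exact
        rng = np.random.default_rng(2)
        Y = rng.uniform(0, 100, (40, 4))
        A = rng.uniform(-1, 1, (3, 4))
        Z = Y @ A.T  # colors linear in doses (already centered-ish)
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        # invert: doses are an exact linear function of these features only
        # if A is invertible on the dose span; use 3 pigments to stay exact
        Y3 = Z @ rng.uniform(-5, 5, (3, 4)) + 50.0
        table = compete(Z, Y3, CompetitionConfig(folds=5, repeats=1, seed=0, grids={}, families=("linear",)))
        assert table[0].mean_r2 == pytest.approx(1.0, abs=1e-9)
        assert table[0].mean_rmse == pytest.approx(0.0, abs=1e-6)

    def test_shuffled_targets_have_no_skill(self):
        rng = np.random.default_rng(3)
        Y = rng.uniform(0, 100, (60, 4))
        Z = rng.standard_normal((60, 3))  # features independent of targets
        cfg = CompetitionConfig(folds=5, repeats=1, seed=1, grids=FAST_GRIDS)
        table = compete(Z, Y, cfg)
        for s in table:
            assert s.mean_r2 <= 0.1

    def test_nonsmooth_target_favors_forest(self):
        # sharp axis-aligned plateaus with no linear trend: tree
        # ensembles model them, linear/ridge cannot — the competition
        # surfaces the right winner
        rng = np.random.default_rng(4)
        Z = rng.uniform(-2, 2, (150, 3))
        y = 100.0 * (np.abs(Z[:, 0]) < 1) + 50.0 * (Z[:, 1] > 0.5) + rng.normal(0, 1, 150)
        Y = np.column_stack([y, y, y, y])
        cfg = CompetitionConfig(folds=5, repeats=1, seed=2, grids=FAST_GRIDS,
                                families=("linear", "ridge", "random_forest"))
        assert select_winner(compete(Z, Y, cfg)) == "random_forest"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((40, 3))
        Y = rng.uniform(0, 50, (40, 4))
        cfg = CompetitionConfig(folds=4, repeats=2, seed=9, grids={}, families=("linear", "ridge"))
        t1 = compete(Z, Y, cfg)
        t2 = compete(Z, Y, cfg)
        for a, b in zip(t1, t2):
            assert a.mean_rmse == b.mean_rmse and a.mean_r2 == b.mean_r2

    def test_small_cluster_reduces_folds_with_warning(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((6, 3))
        Y = rng.uniform(0, 10, (6, 4))
        with pytest.warns(UserWarning, match="reducing folds"):
            compete(Z, Y, CompetitionConfig(folds=5, repeats=1, grids={}, families=("linear",)))

    def test_too_small_cluster_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            compete(np.ones((3, 3)), np.ones((3, 4)), CompetitionConfig())


@pytest.fixture(scope="module")
def tiny_fit():
    # noise-free forward map memorized by a random forest
    rng = np.random.default_rng(7)
    Y = rng.uniform(0, 100, (30, 4))
    X = 250.0 - Y @ np.array([[0.2, 0.05, 0.1, 0.01], [0.1, 0.15, 0.05, 0.02], [0.05, 0.2, 0.15, 0.01]]).T
    std = Standardizer().fit(X)
    Z = std.transform(X)
    cmodel = kmeans_fit(Z, 2, seed=0)
    cfg = CompetitionConfig(folds=5, repeats=1, seed=0,
                            grids={"random_forest": {"n_estimators": [150]}},
                            families=("random_forest",))
    Z_by, Y_by, tables = {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in range(2):
            idx = cmodel.labels == c
            Z_by[c], Y_by[c] = Z[idx], Y[idx]
            tables[c] = compete(Z[idx], Y[idx], cfg)
    bundle = fit_final(Z_by, Y_by, tables, cfg)
    return bundle, cmodel, std, X, Y


class TestFitFinalAndPredict:
    def test_bundle_structure(self, tiny_fit):
        bundle, *_ = tiny_fit
        for c, reg in bundle.clusters.items():
            assert set(reg.estimators) == set(PIGMENT_COLUMNS)
            assert reg.winner == "random_forest"

    def test_training_color_memorized_within_tolerance(self, tiny_fit):
        bundle, cmodel, std, X, Y = tiny_fit
        i = 3
        f = predict_formula(bundle, cmodel, std, RGBColor(*X[i]))
        # in-sample forest prediction stays in the neighborhood of truth
        assert f.doses() == pytest.approx(Y[i], abs=25.0)

    def test_refit_beats_cv_in_sample(self, tiny_fit):
        bundle, cmodel, std, X, Y = tiny_fit
        for c, reg in bundle.clusters.items():
            idx = cmodel.labels == c
            Z = std.transform(X)[idx]
            in_sample = np.mean(
                [rmse(Y[idx][:, j], reg.estimators[p].predict(Z)) for j, p in enumerate(PIGMENT_COLUMNS)]
            )
            cv = next(s for s in reg.scores if s.model_name == reg.winner).mean_rmse
            assert in_sample <= cv + 1e-9

    def test_negative_prediction_clamps_to_zero(self, tiny_fit):
        import copy

        orig, cmodel, std, *_ = tiny_fit
        bundle = copy.deepcopy(orig)

        class Negative:
            def predict(self, Z):
                return np.full(len(Z), -3.7)

        bundle.clusters[0].estimators = {p: Negative() for p in PIGMENT_COLUMNS}
        bundle.clusters[1].estimators = {p: Negative() for p in PIGMENT_COLUMNS}
        f = predict_formula(bundle, cmodel, std, RGBColor(100, 100, 100))
        assert all(getattr(f, p) == 0.0 for p in PIGMENT_COLUMNS)
        assert f.excipient_g == 20.00

    def test_output_rounded_to_weighing_precision(self, tiny_fit):
        bundle, cmodel, std, X, _ = tiny_fit
        f = predict_formula(bundle, cmodel, std, RGBColor(*X[0]))
        for p in PIGMENT_COLUMNS:
            v = getattr(f, p)
            assert v == round(v, 2) or abs(v - round(v, 2)) < 1e-12
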