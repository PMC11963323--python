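"""Per-cluster regression competition and inverse dose prediction.

Within each color cluster, five regressor families — linear, ridge, SVR
(RBF), random forest and gradient boosting — compete to predict the four
pigment doses from standardized RGB. Hyperparameters are grid-searched
by inner cross-validated RMSE, then each tuned family is scored with
repeated 5-fold cross-validation; the family with the smallest mean RMSE
wins the cluster and is refitted on the full cluster, one estimator per
pigment. Prediction standardizes the query color, routes it to its
cluster, applies that cluster's winner, clamps negative doses to zero
and rounds to the 0.01 mg formulation precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold
from sklearn.svm import SVR

from .cluster import ClusterModel, assign
from .colors import RGBColor
from .dataio import PIGMENT_COLUMNS, PigmentFormula, Standardizer

__all__ = [
    "MODEL_ORDER",
    "CompetitionConfig",
    "CVScore",
    "ClusterRegressors",
    "RegressionBundle",
    "rmse",
    "r2",
    "compete",
    "select_winner",
    "fit_final",
    "predict_formula",
]

#: Fixed family order; also the final tie-break in winner selection.
MODEL_ORDER = ("linear", "ridge", "svr", "random_forest", "gradient_boosting")


def default_grids() -> dict[str, dict[str, list]]:
    return {
        "linear": {},
        "ridge": {"alpha": [0.1, 1.0, 10.0]},
        "svr": {"C": [1.0, 10.0, 100.0], "epsilon": [0.1, 1.0]},
        "random_forest": {
            "n_estimators": [100, 300],
            "max_depth": [None, 5, 10],
            "min_samples_leaf": [1, 3],
        },
        "gradient_boosting": {
            "n_estimators": [100, 300],
            "learning_rate": [0.05, 0.1],
            "max_depth": [2, 3],
        },
    }


def _make_estimator(name: str, seed: int) -> BaseEstimator:
    if name == "linear":
        return LinearRegression()
    if name == "ridge":
        return Ridge()
    if name == "svr":
        return SVR(kernel="rbf")
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed)
    raise ValueError(f"unknown model family {name!r}")


@dataclass
class CompetitionConfig:
    """Cross-validation and grid-search settings for the model
    competition.

    ``folds``/``repeats`` drive the scoring loop (repeated k-fold);
    grid search uses a single seeded ``folds``-fold split internally.
    """

    folds: int = 5
    repeats: int = 3
    seed: int = 42
    grids: Mapping[str, Mapping[str, list]] = field(default_factory=default_grids)
    families: Sequence[str] = MODEL_ORDER


@dataclass
class CVScore:
    """Cross-validated performance of one family in one cluster,
    macro-averaged over folds, repeats and the four pigments."""

    model_name: str
    mean_rmse: float
    mean_r2: float
    per_pigment_rmse: dict[str, float]
    per_pigment_r2: dict[str, float]
    best_params: dict[str, dict]


@dataclass
class ClusterRegressors:
    """Winner of one cluster's competition: one fitted estimator per
    pigment plus the full score table."""

    winner: str
    estimators: dict[str, BaseEstimator]
    scores: list[CVScore]


@dataclass
class RegressionBundle:
    """Per-cluster winning regressors with training metadata."""

    clusters: dict[int, ClusterRegressors]
    folds: int
    repeats: int
    seed: int

    def predict_doses(self, cluster: int, Z: np.ndarray) -> np.ndarray:
        """Raw (unclamped, unrounded) dose predictions, shape (n, 4)."""
        reg = self.clusters[cluster]
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return np.column_stack([reg.estimators[p].predict(Z) for p in PIGMENT_COLUMNS])


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; the mean
    predictor scores exactly 0. Undefined (raises) for constant y."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 is undefined for a constant target")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _effective_folds(n: int, folds: int) -> int:
    if n < 4:
        raise ValueError(f"cluster too small for cross-validation (n={n})")
    eff = min(folds, n // 2)
    if eff < folds:
        warnings.warn(f"cluster of {n} samples: reducing folds {folds} -> {eff}", stacklevel=3)
    return eff


def compete(Z: np.ndarray, Y: np.ndarray, config: CompetitionConfig | None = None) -> list[CVScore]:
    """Run the model competition on one cluster.

    ``Z``: standardized colors (n, 3); ``Y``: pigment doses (n, 4) in
    the canonical pigment order. Deterministic given ``config.seed``.
    """
    config = config or CompetitionConfig()
    Z = np.asarray(Z, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Z.shape[0]
    folds = _effective_folds(n, config.folds)
    inner_cv = KFold(n_splits=folds, shuffle=True, random_state=config.seed)
    outer_cv = RepeatedKFold(n_splits=folds, n_repeats=config.repeats, random_state=config.seed)
    splits = list(outer_cv.split(Z))

    scores: list[CVScore] = []
    for name in config.families:
        grid = dict(config.grids.get(name, {}))
        best_params: dict[str, dict] = {}
        pig_rmse: dict[str, list[float]] = {p: [] for p in PIGMENT_COLUMNS}
        pig_r2: dict[str, list[float]] = {p: [] for p in PIGMENT_COLUMNS}
        for j, pigment in enumerate(PIGMENT_COLUMNS):
            y = Y[:, j]
            est = _make_estimator(name, config.seed)
            if grid:
                search = GridSearchCV(est, grid, scoring="neg_root_mean_squared_error", cv=inner_cv)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    search.fit(Z, y)
                params = search.best_params_
            else:
                params = {}
            best_params[pigment] = params
            tuned = clone(est).set_params(**params)
            for tr, te in splits:
                m = clone(tuned)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(Z[tr], y[tr])
                pred = m.predict(Z[te])
                pig_rmse[pigment].append(rmse(y[te], pred))
                # a fold whose target is constant has no defined r2; skip it
                if np.ptp(y[te]) > 0:
                    pig_r2[pigment].append(r2(y[te], pred))
        per_rmse = {p: float(np.mean(v)) for p, v in pig_rmse.items()}
        per_r2 = {p: float(np.mean(v)) if v else float("nan") for p, v in pig_r2.items()}
        scores.append(
            CVScore(
                model_name=name,
                mean_rmse=float(np.mean(list(per_rmse.values()))),
                mean_r2=float(np.nanmean(list(per_r2.values()))),
                per_pigment_rmse=per_rmse,
                per_pigment_r2=per_r2,
                best_params=best_params,
            )
        )
    return scores


def select_winner(table: Sequence[CVScore]) -> str:
    """Smallest mean RMSE wins; ties go to the higher mean R^2, then to
    the fixed family order."""
    if not table:
        raise ValueError("empty score table")

    def order_key(s: CVScore):
        rank = MODEL_ORDER.index(s.model_name) if s.model_name in MODEL_ORDER else len(MODEL_ORDER)
        return (s.mean_rmse, -s.mean_r2, rank)

    return min(table, key=order_key).model_name


def fit_final(
    Z_by_cluster: Mapping[int, np.ndarray],
    Y_by_cluster: Mapping[int, np.ndarray],
    tables: Mapping[int, Sequence[CVScore]],
    config: CompetitionConfig | None = None,
) -> RegressionBundle:
    """Refit each cluster's winner on the full cluster with its best
    hyperparameters, one estimator per pigment."""
    config = config or CompetitionConfig()
    clusters: dict[int, ClusterRegressors] = {}
    for c, table in tables.items():
        winner = select_winner(table)
        score = next(s for s in table if s.model_name == winner)
        ests: dict[str, BaseEstimator] = {}
        Y = np.atleast_2d(np.asarray(Y_by_cluster[c], dtype=float))
        for j, pigment in enumerate(PIGMENT_COLUMNS):
            est = _make_estimator(winner, config.seed).set_params(**score.best_params[pigment])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(np.asarray(Z_by_cluster[c], dtype=float), Y[:, j])
            ests[pigment] = est
        clusters[c] = ClusterRegressors(winner=winner, estimators=ests, scores=list(table))
    return RegressionBundle(clusters=clusters, folds=config.folds, repeats=config.repeats, seed=config.seed)


def predict_formula(
    bundle: RegressionBundle,
    cluster_model: ClusterModel,
    standardizer: Standardizer,
    query: RGBColor,
    excipient_g: float = 20.00,
) -> PigmentFormula:
    """Predict the pigment formula reproducing a query color.

    Negative predictions are clamped to 0 and doses are rounded to two
    decimals, the precision at which formulations are weighed.
    """
    z = standardizer.transform([query])
    c = int(assign(cluster_model, z)[0])
    doses = bundle.predict_doses(c, z)[0]
    doses = np.clip(doses, 0.0, None)
    rounded = [math.floor(float(d) * 100 + 0.5) / 100 for d in doses]
    return PigmentFormula(*rounded, excipient_g=excipient_g)
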