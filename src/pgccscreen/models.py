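"""Repeated k-fold benchmarking of regressors over feature sets.

Seven regressor families — Ridge, SVM (epsilon-SVR), random forest (RF),
histogram gradient boosting (HGB), decision tree (DT), SGD linear
regression, and a multilayer perceptron (MLP) — are evaluated on each of the
nine feature representations under 10-round, 10-fold cross-validation: in
each round the compounds are randomly re-partitioned into 10 folds, each
fold is predicted by a model trained on the other 9, and the round score is
the mean of the 10 fold-level Pearson correlations between predicted and
actual responses.  A configuration's headline score is the median of its
round scores.  One shared :class:`CVPlan` is reused for every configuration
so that model comparisons are paired by round.

Continuous (embedding) features are standardized inside each training fold;
binary fingerprints are left unscaled.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge, SGDRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .features import FeatureSet

__all__ = [
    "MODEL_FAMILIES",
    "CVPlan",
    "ModelConfig",
    "CVResult",
    "build_cv_plan",
    "make_estimator",
    "pearson",
    "run_cv",
    "benchmark_grid",
    "select_best",
]

MODEL_FAMILIES: tuple[str, ...] = ("Ridge", "SVM", "RF", "HGB", "DT", "SGD", "MLP")


@dataclass(frozen=True)
class CVPlan:
    """Round-by-round fold assignment shared by every benchmarked model.

    ``assignment[r, i]`` is the fold id of item ``i`` in round ``r``.  Within
    a round the folds are disjoint, cover all items, and differ in size by at
    most one.
    """

    n_items: int
    rounds: int
    folds: int
    seed: int
    assignment: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.assignment.shape != (self.rounds, self.n_items):
            raise ValueError("assignment shape mismatch")

    def fold_indices(self, round_idx: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment[round_idx] == fold)

    @property
    def plan_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.assignment).tobytes())
        h.update(str((self.n_items, self.rounds, self.folds, self.seed)).encode())
        return h.hexdigest()[:16]


def build_cv_plan(n_items: int, rounds: int = 10, folds: int = 10, seed: int = 0) -> CVPlan:
    """Random balanced partition of the items, repeated per round."""
    if n_items < folds:
        raise ValueError(f"n_items={n_items} < folds={folds}")
    rng = np.random.default_rng(seed)
    assignment = np.empty((rounds, n_items), dtype=np.int32)
    base, extra = divmod(n_items, folds)
    sizes = [base + (1 if f < extra else 0) for f in range(folds)]
    fold_of_position = np.repeat(np.arange(folds, dtype=np.int32), sizes)
    for r in range(rounds):
        perm = rng.permutation(n_items)
        assignment[r, perm] = fold_of_position
    return CVPlan(n_items=n_items, rounds=rounds, folds=folds, seed=seed, assignment=assignment)


@dataclass(frozen=True)
class ModelConfig:
    family: str
    feature_set: FeatureSet

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def config_id(self) -> str:
        return f"{self.family}|{self.feature_set.id}"


def make_estimator(family: str, binary_features: bool, seed: int = 0):
    """Instantiate one family, parameterized for repeated CV on one CPU.

    Hyperparameters follow library defaults except where a setting is either
    lossless or standard practice for wide feature matrices:

    * RF uses ``max_features="sqrt"`` — scanning all of up to 3072 features
      at every split is prohibitive and sub-sampling is the usual choice for
      high-dimensional fingerprints;
    * HGB uses ``max_bins=2`` on binary fingerprints (two bins represent
      0/1 features exactly; 255 bins are pure overhead) and ``max_bins=64``
      on continuous embeddings;
    * MLP uses one 64-unit hidden layer with early stopping, sized to the
      few-hundred-compound training sets it sees here.

    Stochastic families get a fixed ``random_state`` derived from ``seed``.
    Continuous feature matrices are standardized in-pipeline (fit on the
    training fold only); binary fingerprints are passed through unscaled.
    """
    if family == "Ridge":
        est = Ridge()
    elif family == "SVM":
        est = SVR()
    elif family == "RF":
        est = RandomForestRegressor(
            max_features="sqrt", random_state=seed, n_jobs=1
        )
    elif family == "HGB":
        est = HistGradientBoostingRegressor(
            max_bins=2 if binary_features else 64, random_state=seed
        )
    elif family == "DT":
        est = DecisionTreeRegressor(random_state=seed)
    elif family == "SGD":
        est = SGDRegressor(random_state=seed)
    elif family == "MLP":
        est = MLPRegressor(
            hidden_layer_sizes=(64,),
            early_stopping=True,
            n_iter_no_change=10,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model family {family!r}")
    if not binary_features:
        return make_pipeline(StandardScaler(), est)
    return est


def pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between actual and predicted responses.

    Returns NaN (with a warning) when either vector is constant, where the
    coefficient is undefined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant vector: Pearson correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(y_true, y_pred).statistic)


@dataclass
class CVResult:
    """Benchmark slice for one (family, feature set) configuration."""

    config: ModelConfig
    round_scores: np.ndarray  # mean fold rho per round
    fold_scores: np.ndarray  # (rounds, folds)
    oof_predictions: np.ndarray  # (rounds, n_items) out-of-fold predictions
    plan_hash: str
    failed: bool = False

    @property
    def median_score(self) -> float:
        return float(np.median(self.round_scores))


def run_cv(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    seed: int = 0,
) -> CVResult:
    """Cross-validate one configuration under the shared plan.

    For every round and fold the model is fit on the training folds only and
    scored on the held-out fold.  Folds where the model predicts a constant
    (undefined correlation) contribute 0 to the round mean, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != plan.n_items or y.shape[0] != plan.n_items:
        raise ValueError("X/y rows must align with the CV plan items")
    fold_scores = np.full((plan.rounds, plan.folds), np.nan)
    oof = np.full((plan.rounds, plan.n_items), np.nan)
    try:
        for r in range(plan.rounds):
            for f in range(plan.folds):
                test_idx = plan.fold_indices(r, f)
                train_idx = np.flatnonzero(plan.assignment[r] != f)
                est = make_estimator(
                    config.family, config.feature_set.is_binary, seed=seed
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[train_idx], y[train_idx])
                    pred = est.predict(X[test_idx])
                oof[r, test_idx] = pred
                if np.ptp(pred) == 0 or np.ptp(y[test_idx]) == 0:
                    warnings.warn(
                        f"{config.config_id} round {r} fold {f}: constant "
                        "predictions; scoring fold as 0",
                        stacklevel=2,
                    )
                    fold_scores[r, f] = 0.0
                else:
                    fold_scores[r, f] = pearson(y[test_idx], pred)
    except Exception as err:  # model fit failure: mark config failed
        warnings.warn(f"{config.config_id} failed: {err}", stacklevel=2)
        return CVResult(
            config=config,
            round_scores=np.full(plan.rounds, np.nan),
            fold_scores=fold_scores,
            oof_predictions=oof,
            plan_hash=plan.plan_hash,
            failed=True,
        )
    round_scores = fold_scores.mean(axis=1)
    return CVResult(
        config=config,
        round_scores=round_scores,
        fold_scores=fold_scores,
        oof_predictions=oof,
        plan_hash=plan.plan_hash,
    )


def benchmark_grid(
    feature_matrices: dict[str, np.ndarray],
    feature_sets: list[FeatureSet],
    y: np.ndarray,
    plan: CVPlan,
    families: tuple[str, ...] = MODEL_FAMILIES,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Run every family on every feature set under one shared plan.

    ``feature_matrices`` maps feature-set id to its (n_items, n_features)
    matrix, rows aligned with ``y`` and the plan.  Returns results keyed by
    config id; failed configs are retained but flagged.
    """
    results: dict[str, CVResult] = {}
    for fs in feature_sets:
        X = feature_matrices[fs.id]
        for family in families:
            config = ModelConfig(family=family, feature_set=fs)
            results[config.config_id] = run_cv(config, X, y, plan, seed=seed)
    return results


def select_best(results: dict[str, CVResult], kind: str) -> CVResult:
    """Best non-failed configuration of a kind by median round score."""
    candidates = [
        r
        for r in results.values()
        if r.config.feature_set.kind == kind and not r.failed
    ]
    if not candidates:
        raise ValueError(f"no successful configuration of kind {kind!r}")
    return max(candidates, key=lambda r: r.median_score)


def results_frame(results: dict[str, CVResult]) -> pd.DataFrame:
    """Long-form table (one row per config x round) for export and plotting."""
    rows = []
    for res in results.values():
        for r, score in enumerate(res.round_scores):
            rows.append(
                {
                    "config_id": res.config.config_id,
                    "family": res.config.family,
                    "feature_set": res.config.feature_set.id,
                    "kind": res.config.feature_set.kind,
                    "round": r,
                    "mean_rho": score,
                    "median_rho": res.median_score,
                    "failed": res.failed,
                    "plan_hash": res.plan_hash,
                }
            )
    return pd.DataFrame(rows)
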