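"""Stacking ensemble of one structure-based and one description-based model.

The out-of-fold predictions of the two base models — generated under the
same cross-validation plan as the individual benchmarks — are the inputs of
an ordinary-least-squares meta-regression

    y = intercept + beta_structure * p_structure + beta_description * p_description

whose coefficients (with standard errors and two-sided p-values) quantify
how much each channel contributes.  Stacked performance is scored with the
same nested, leakage-free protocol: within each round the meta-learner for
fold k is trained only on out-of-fold meta-features of the other folds.
Model comparison across rounds uses a one-tailed paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .models import CVPlan, CVResult, make_estimator, pearson

__all__ = [
    "StackModel",
    "fit_stack",
    "predict_stack",
    "run_stacked_cv",
    "compare_paired",
    "fit_deployment_stack",
    "DeployedEnsemble",
]


@dataclass(frozen=True)
class StackConfig:
    """Identity of a stacked configuration (for result bookkeeping)."""

    base_structure_id: str
    base_description_id: str
    family: str = "STACK"

    @property
    def config_id(self) -> str:
        return f"STACK({self.base_structure_id} + {self.base_description_id})"


@dataclass
class StackModel:
    """Linear meta-learner over two base-model prediction channels."""

    base_structure_id: str
    base_description_id: str
    intercept: float
    beta_structure: float
    beta_description: float
    se: tuple[float, float, float]
    p_values: tuple[float, float, float]  # intercept, structure, description
    n_obs: int
    collinear: bool = False

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.intercept, self.beta_structure, self.beta_description])


def fit_stack(
    p_structure: np.ndarray,
    p_description: np.ndarray,
    y: np.ndarray,
    base_structure_id: str = "structure",
    base_description_id: str = "description",
) -> StackModel:
    """OLS meta-fit of y on the two base prediction vectors.

    The prediction vectors must be out-of-fold with respect to each item;
    passing in-sample predictions would leak the base models' training
    labels into the meta-learner.  Collinear base predictions still fit (via
    pinv) but are flagged.  Requires residual degrees of freedom, i.e. more
    than 3 observations.
    """
    p1 = np.asarray(p_structure, dtype=float)
    p2 = np.asarray(p_description, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (p1.shape == p2.shape == y.shape) or y.ndim != 1:
        raise ValueError("prediction vectors and y must be aligned 1-D arrays")
    if y.size <= 3:
        raise ValueError("insufficient residual degrees of freedom for the meta-fit")
    X = sm.add_constant(np.column_stack([p1, p2]), has_constant="add")
    collinear = False
    if np.ptp(p1) > 0 and np.ptp(p2) > 0:
        r = abs(stats.pearsonr(p1, p2).statistic)
        if r > 0.999:
            collinear = True
            warnings.warn(
                f"base predictions nearly collinear (|r|={r:.4f}); "
                "coefficients are unstable",
                stacklevel=2,
            )
    res = sm.OLS(y, X).fit()
    return StackModel(
        base_structure_id=base_structure_id,
        base_description_id=base_description_id,
        intercept=float(res.params[0]),
        beta_structure=float(res.params[1]),
        beta_description=float(res.params[2]),
        se=tuple(float(s) for s in res.bse),
        p_values=tuple(float(p) for p in res.pvalues),
        n_obs=int(res.nobs),
        collinear=collinear,
    )


def predict_stack(
    model: StackModel, p_structure: np.ndarray, p_description: np.ndarray
) -> np.ndarray:
    """intercept + beta_s * p_structure + beta_d * p_description, vectorized.

    Items with a missing (NaN) base prediction propagate NaN so callers can
    flag rather than silently drop them.
    """
    p1 = np.asarray(p_structure, dtype=float)
    p2 = np.asarray(p_description, dtype=float)
    return model.intercept + model.beta_structure * p1 + model.beta_description * p2


def run_stacked_cv(
    base_structure: CVResult,
    base_description: CVResult,
    y: np.ndarray,
    plan: CVPlan,
) -> tuple[CVResult, StackModel]:
    """Score the stacking ensemble under the shared plan, leakage-free.

    Within each round, both base models' out-of-fold predictions (already
    computed under the same plan) form the meta-feature matrix; the
    meta-learner scoring fold k is an OLS fit on the meta-features of the
    other folds.  Round score = mean fold Pearson rho; headline = median
    across rounds.  Also returns the deployment meta-model fit on the full
    out-of-fold meta-features of the final round.
    """
    if base_structure.plan_hash != base_description.plan_hash:
        raise ValueError("base models were not scored under the same CV plan")
    y = np.asarray(y, dtype=float)
    fold_scores = np.full((plan.rounds, plan.folds), np.nan)
    oof = np.full((plan.rounds, plan.n_items), np.nan)
    for r in range(plan.rounds):
        p1 = base_structure.oof_predictions[r]
        p2 = base_description.oof_predictions[r]
        for f in range(plan.folds):
            test_idx = plan.fold_indices(r, f)
            train_idx = np.flatnonzero(plan.assignment[r] != f)
            meta = fit_stack(p1[train_idx], p2[train_idx], y[train_idx])
            pred = predict_stack(meta, p1[test_idx], p2[test_idx])
            oof[r, test_idx] = pred
            if np.ptp(pred) == 0:
                fold_scores[r, f] = 0.0
            else:
                fold_scores[r, f] = pearson(y[test_idx], pred)
    # deployment meta-model: fit on all out-of-fold meta-features, averaged
    # across rounds for stability
    p1_bar = base_structure.oof_predictions.mean(axis=0)
    p2_bar = base_description.oof_predictions.mean(axis=0)
    final_meta = fit_stack(
        p1_bar,
        p2_bar,
        y,
        base_structure_id=base_structure.config.config_id,
        base_description_id=base_description.config.config_id,
    )
    result = CVResult(
        config=StackConfig(
            base_structure_id=base_structure.config.config_id,
            base_description_id=base_description.config.config_id,
        ),
        round_scores=fold_scores.mean(axis=1),
        fold_scores=fold_scores,
        oof_predictions=oof,
        plan_hash=plan.plan_hash,
    )
    return result, final_meta


def compare_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """One-tailed paired t-test on per-round scores (a greater than b).

    The pairing is by round under the identical CV plan.  Zero variance of
    the differences makes the statistic degenerate: t is reported as +/-inf
    (or NaN for identical scores) with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired score vectors of length >= 2")
    diff = a - b
    if np.ptp(diff) == 0:
        warnings.warn("zero variance of paired differences; p-value degenerate", stacklevel=2)
        if np.all(diff == 0):
            return float("nan"), 0.5
        return float(np.sign(diff[0]) * np.inf), 0.0 if diff[0] > 0 else 1.0
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DeployedEnsemble:
    """Base models refit on all training data + the meta-learner, ready to score."""

    structure_model: object
    description_model: object
    meta: StackModel
    structure_feature_set_id: str
    description_feature_set_id: str
    plan_hash: str

    def predict(self, X_structure: np.ndarray, X_description: np.ndarray) -> np.ndarray:
        p1 = self.structure_model.predict(np.asarray(X_structure, dtype=float))
        p2 = self.description_model.predict(np.asarray(X_description, dtype=float))
        return predict_stack(self.meta, p1, p2)


def fit_deployment_stack(
    base_structure: CVResult,
    base_description: CVResult,
    X_structure: np.ndarray,
    X_description: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    seed: int = 0,
) -> DeployedEnsemble:
    """Final model: bases refit on the full training set, meta from OOF features."""
    _, meta = run_stacked_cv_meta_only(base_structure, base_description, y)
    s_est = make_estimator(
        base_structure.config.family,
        base_structure.config.feature_set.is_binary,
        seed=seed,
    )
    d_est = make_estimator(
        base_description.config.family,
        base_description.config.feature_set.is_binary,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s_est.fit(np.asarray(X_structure, dtype=float), y)
        d_est.fit(np.asarray(X_description, dtype=float), y)
    return DeployedEnsemble(
        structure_model=s_est,
        description_model=d_est,
        meta=meta,
        structure_feature_set_id=base_structure.config.feature_set.id,
        description_feature_set_id=base_description.config.feature_set.id,
        plan_hash=plan.plan_hash,
    )


def run_stacked_cv_meta_only(
    base_structure: CVResult, base_description: CVResult, y: np.ndarray
) -> tuple[None, StackModel]:
    """Fit only the deployment meta-learner from round-averaged OOF features."""
    p1_bar = base_structure.oof_predictions.mean(axis=0)
    p2_bar = base_description.oof_predictions.mean(axis=0)
    meta = fit_stack(
        p1_bar,
        p2_bar,
        np.asarray(y, dtype=float),
        base_structure_id=base_structure.config.config_id,
        base_description_id=base_description.config.config_id,
    )
    return None, meta
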