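"""Stacking meta-learner: coefficient recovery, paired comparison, gains."""

import numpy as np
import pytest
from scipy import stats

from pgccscreen import ensemble as ens
from pgccscreen import features as feat
from pgccscreen import fixtures as fx
from pgccscreen import models


class TestFitStack:
    def test_identity_recovery(self, rng):
        """y equal to base-1 exactly: beta1 ~ 1, beta2 ~ 0."""
        p1 = rng.normal(size=200)
        p2 = rng.normal(size=200)  # independent noise channel
        model = ens.fit_stack(p1, p2, y=p1)
        assert model.beta_structure == pytest.approx(1.0, abs=1e-8)
        assert model.beta_description == pytest.approx(0.0, abs=1e-8)

    def test_uninformative_base_not_significant(self, rng):
        """A pure-noise channel gets a coefficient indistinguishable from 0."""
        p1 = rng.normal(size=200)
        p2 = rng.normal(size=200)
        y = p1 + rng.normal(0, 0.1, size=200)  # only channel 1 informative
        model = ens.fit_stack(p1, p2, y)
        assert model.p_values[1] < 1e-6
        assert model.p_values[2] > 0.01

    def test_linear_ground_truth_recovered_within_ci(self, rng):
        p1 = rng.normal(size=300)
        p2 = rng.normal(size=300)
        y = 0.7 * p1 + 0.3 * p2 + rng.normal(0, 0.05, size=300)
        model = ens.fit_stack(p1, p2, y)
        for est, se, true in [
            (model.beta_structure, model.se[1], 0.7),
            (model.beta_description, model.se[2], 0.3),
        ]:
            assert abs(est - true) < 3 * se
            assert est == pytest.approx(true, abs=0.05)
        # both channels carry signal: both significant
        assert model.p_values[1] < 1e-3 and model.p_values[2] < 1e-3

    def test_degenerate_n_refused(self):
        with pytest.raises(ValueError):
            ens.fit_stack(np.array([1.0, 2.0]), np.array([0.0, 1.0]), np.array([1.0, 2.0]))

    def test_collinear_bases_warn_but_fit(self, rng):
        p1 = rng.normal(size=100)
        with pytest.warns(UserWarning, match="collinear"):
            model = ens.fit_stack(p1, p1.copy(), y=2 * p1)
        assert model.collinear

    def test_stack_se_matches_textbook_ols(self, rng):
        """Standard errors agree with the closed-form (X'X)^-1 sigma^2 formula."""
        p1, p2 = rng.normal(size=50), rng.normal(size=50)
        y = 1.0 + 0.5 * p1 - 0.2 * p2 + rng.normal(0, 0.3, size=50)
        model = ens.fit_stack(p1, p2, y)
        X = np.column_stack([np.ones(50), p1, p2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (50 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(model.coef, beta, atol=1e-10)
        np.testing.assert_allclose(model.se, se, atol=1e-10)


class TestPredictStack:
    @staticmethod
    def _model(intercept, b1, b2):
        return ens.StackModel(
            base_structure_id="s",
            base_description_id="d",
            intercept=intercept,
            beta_structure=b1,
            beta_description=b2,
            se=(0, 0, 0),
            p_values=(1, 1, 1),
            n_obs=10,
        )

    def test_hand_arithmetic(self):
        model = self._model(0.1, 1.2, 0.6)
        out = ens.predict_stack(model, np.array([-1.0]), np.array([-2.0]))
        assert out[0] == pytest.approx(-2.3)
        ident = self._model(0.0, 1.0, 0.0)
        assert ens.predict_stack(ident, np.array([-3.0]), np.array([7.0]))[0] == -3.0

    def test_vectorized_equals_per_item(self, rng):
        model = self._model(0.2, 0.9, 0.4)
        p1, p2 = rng.normal(size=20), rng.normal(size=20)
        vec = ens.predict_stack(model, p1, p2)
        single = [ens.predict_stack(model, p1[i : i + 1], p2[i : i + 1])[0] for i in range(20)]
        np.testing.assert_allclose(vec, single)

    def test_missing_base_prediction_propagates_nan(self):
        model = self._model(0.0, 1.0, 1.0)
        out = ens.predict_stack(model, np.array([1.0, np.nan]), np.array([1.0, 1.0]))
        assert np.isnan(out[1]) and out[0] == 2.0


class TestComparePaired:
    def test_constructed_separation(self, rng):
        b = rng.normal(0.2, 0.02, size=10)
        a = b + 1 + rng.normal(0, 0.01, size=10)
        t, p = ens.compare_paired(a, b)
        assert t > 0 and p < 0.05

    def test_null_case(self):
        a = np.linspace(0, 1, 10)
        with pytest.warns(UserWarning):
            t, p = ens.compare_paired(a, a.copy())
        assert np.isnan(t) and p == 0.5

    def test_matches_textbook_computation(self):
        a = np.array([0.31, 0.29, 0.35, 0.30, 0.33])
        b = np.array([0.27, 0.28, 0.30, 0.29, 0.30])
        t, p = ens.compare_paired(a, b)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = stats.t.sf(t_ref, df=len(d) - 1)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


def _stacked_setup(n, seed, noise_sd=0.3, signal_strength=2.0, rounds=2):
    """Structure and description channels with partially independent signal."""
    sar = fx.PlantedSAR.random(seed=seed, noise_sd=noise_sd)
    lib = fx.generate_compound_library(n, sar, seed=seed + 100)
    y = lib["y_true"].to_numpy()
    sets = feat.enumerate_feature_sets()
    fs_s = sets[0]  # MACCS: carries the SAR
    fs_d = [s for s in sets if s.id == "embedding-small"][0]
    # embedding signal: noisy view of y, so the description channel is
    # informative but not redundant with the structure channel
    rng = np.random.default_rng(seed + 7)
    noisy_y = y + rng.normal(0, 0.5 * max(y.std(), 0.1), size=len(y))
    provider = fx.MockEmbeddingProvider(
        seed=seed,
        signal_map=dict(zip(lib["description"], noisy_y)),
        signal_strength=signal_strength,
    )
    X_s, _ = feat.assemble_feature_matrix(lib, fs_s)
    X_d, _ = feat.assemble_feature_matrix(lib, fs_d, provider=provider)
    plan = models.build_cv_plan(n, rounds=rounds, folds=10, seed=seed)
    res_s = models.run_cv(models.ModelConfig("Ridge", fs_s), X_s, y, plan)
    res_d = models.run_cv(models.ModelConfig("Ridge", fs_d), X_d, y, plan)
    return res_s, res_d, y, plan, (X_s, X_d)


class TestStackedCV:
    def test_plan_mismatch_rejected(self):
        res_s, res_d, y, plan, _ = _stacked_setup(60, seed=0)
        other_plan = models.build_cv_plan(60, rounds=2, folds=10, seed=999)
        res_other = models.run_cv(
            models.ModelConfig("Ridge", res_d.config.feature_set),
            np.random.default_rng(0).normal(size=(60, 10)),
            y,
            other_plan,
        )
        with pytest.raises(ValueError):
            ens.run_stacked_cv(res_s, res_other, y, plan)

    def test_stacking_improves_on_single_replicate(self):
        res_s, res_d, y, plan, _ = _stacked_setup(120, seed=3)
        stack, meta = ens.run_stacked_cv(res_s, res_d, y, plan)
        assert stack.median_score >= max(res_s.median_score, res_d.median_score) - 0.01
        assert meta.beta_structure > 0  # structure channel carries signal

    def test_deployment_model_scores_new_items(self):
        res_s, res_d, y, plan, (X_s, X_d) = _stacked_setup(60, seed=5)
        deployed = ens.fit_deployment_stack(res_s, res_d, X_s, X_d, y, plan)
        pred = deployed.predict(X_s[:10], X_d[:10])
        assert pred.shape == (10,)
        assert np.isfinite(pred).all()
        # refit on the training data: in-sample predictions track y
        rho = models.pearson(y, deployed.predict(X_s, X_d))
        assert rho > 0.5
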