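"""Model hierarchy: spec invariants, design-matrix construction, fitting,
prediction/pooling, serialization round-trip, recalibration."""

import numpy as np
import pandas as pd
import pytest

from gestage import (
    GAEstimateSet,
    GAEstimator,
    ImputationSet,
    ModelSpec,
    build_design_matrix,
    fit_model,
    make_model_spec,
    predict_ga,
    recalibrate,
)
from conftest import make_linear_cohort


class TestModelSpec:
    def test_model1_columns(self):
        spec = make_model_spec(1)
        assert spec.columns == ["sex", "multiple_birth", "birthweight_g"]

    def test_model2_excludes_birthweight(self):
        spec = make_model_spec(2)
        assert "birthweight_g" not in spec.columns
        with pytest.raises(ValueError, match="birthweight"):
            ModelSpec(2, ("sex", "multiple_birth", "birthweight_g"), ("ALA",))

    def test_model1_rejects_analytes(self):
        with pytest.raises(ValueError, match="no analyte"):
            ModelSpec(1, ("sex", "multiple_birth", "birthweight_g"), ("ALA",))

    def test_interaction_pairs_must_be_declared(self):
        with pytest.raises(ValueError, match="undeclared"):
            ModelSpec(3, ("sex", "multiple_birth", "birthweight_g"),
                      ("ALA",), (("ALA", "TSH"),))

    def test_all_pairs_count(self):
        analytes = ("A1", "A2", "A3", "A4")
        spec = make_model_spec(2, analytes=analytes, interactions="all")
        p = len(analytes)
        assert len(spec.columns) == 2 + p + p * (p - 1) // 2


class TestDesignMatrix:
    def test_model1_has_three_columns(self, small_cohort):
        design, _ = build_design_matrix(small_cohort.records, make_model_spec(1))
        assert list(design.columns) == ["sex", "multiple_birth", "birthweight_g"]

    def test_standardized_columns(self, small_cohort):
        spec = make_model_spec(3)
        design, scaler = build_design_matrix(small_cohort.records, spec)
        continuous = [c for c in design.columns if c not in ("sex", "multiple_birth")]
        means = design[continuous].mean().abs()
        sds = (design[continuous].std(ddof=0) - 1).abs()
        assert (means < 1e-9).all()
        assert (sds < 1e-9).all()

    def test_scaler_reproduces_training_design(self, small_cohort):
        spec = make_model_spec(3)
        d1, scaler = build_design_matrix(small_cohort.records, spec)
        d2, _ = build_design_matrix(small_cohort.records, spec, scaler=scaler)
        pd.testing.assert_frame_equal(d1, d2)

    def test_missing_value_named_in_error(self, small_cohort):
        records = small_cohort.records.copy()
        records.loc[records.index[3], "TSH"] = np.nan
        sid = records.loc[records.index[3], "sample_id"]
        with pytest.raises(ValueError, match=f"TSH.*{sid}"):
            build_design_matrix(records, make_model_spec(3))

    def test_column_order_deterministic(self, small_cohort):
        spec = make_model_spec(3)
        cols = spec.columns
        assert cols[:3] == ["sex", "multiple_birth", "birthweight_g"]
        mains = cols[3 : 3 + len(spec.analyte_terms)]
        assert mains == sorted(mains)
        pairs = cols[3 + len(spec.analyte_terms):]
        assert pairs == sorted(pairs)
        assert all("*" in p for p in pairs)


class TestFit:
    def test_noiseless_recovery(self):
        records, active = make_linear_cohort(800, seed=2)
        train, test = records.iloc[:600], records.iloc[600:]
        est = fit_model(train, train["ga_obs_weeks"], model_id=2, seed=0)
        pred = est.predict(test)
        err = np.sqrt(np.mean((pred - test["ga_obs_weeks"]) ** 2))
        assert err < 0.05
        # active coefficients recover generating signs (standardized scale
        # preserves sign)
        for name, coef in active.items():
            assert np.sign(est.coef_[name]) == np.sign(coef)

    def test_null_outcome_predicts_training_mean(self):
        rng = np.random.default_rng(8)
        records, _ = make_linear_cohort(400, seed=4)
        y = rng.normal(39.0, 1.0, len(records))  # independent of predictors
        est = fit_model(records, y, model_id=3, seed=1)
        pred = est.predict(records)
        assert np.abs(pred - y.mean()).max() < 0.1 + 3 * y.std() / np.sqrt(len(y))

    def test_same_seed_identical_coefficients(self, small_cohort):
        r = small_cohort.records
        e1 = fit_model(r, r["ga_obs_weeks"], model_id=3, seed=42)
        e2 = fit_model(r, r["ga_obs_weeks"], model_id=3, seed=42)
        assert e1.coef_ == e2.coef_
        assert e1.intercept_ == e2.intercept_
        assert e1.lambda_ == e2.lambda_

    def test_constant_outcome_rejected(self, small_cohort):
        r = small_cohort.records
        with pytest.raises(ValueError, match="constant"):
            fit_model(r, np.full(len(r), 39.0), model_id=1)

    def test_zero_variance_column_dropped_with_warning(self, small_cohort):
        r = small_cohort.records.copy()
        r["multiple_birth"] = 0
        with pytest.warns(UserWarning, match="zero-variance"):
            est = fit_model(r, r["ga_obs_weeks"], model_id=1, seed=0)
        assert "multiple_birth" in est.dropped_columns_
        est.predict(r)  # still scorable


class TestPredict:
    def test_pooling_identity_for_identical_copies(self, small_cohort):
        r = small_cohort.records
        est = fit_model(r, r["ga_obs_weeks"], model_id=1, seed=0)
        single = predict_ga(est, r)
        imp = ImputationSet([r.copy() for _ in range(4)], seed=0)
        pooled = predict_ga(est, imp)
        assert pooled.m == 4
        np.testing.assert_array_equal(pooled.pooled.to_numpy(), single.pooled.to_numpy())

    def test_residuals_recomputable(self, small_cohort):
        r = small_cohort.records
        est = fit_model(r, r["ga_obs_weeks"], model_id=1, seed=0)
        ests = predict_ga(est, r)
        np.testing.assert_allclose(
            ests.residual.to_numpy(),
            ests.pooled.to_numpy() - r["ga_obs_weeks"].to_numpy(),
        )

    def test_missing_term_column_is_schema_error(self, small_cohort):
        r = small_cohort.records
        est = fit_model(r, r["ga_obs_weeks"], model_id=3, seed=0)
        with pytest.raises(KeyError):
            est.predict(r.drop(columns=["TSH"]))

    def test_serialization_round_trip(self, small_cohort, tmp_path):
        r = small_cohort.records
        est = fit_model(r, r["ga_obs_weeks"], model_id=3, seed=0)
        path = tmp_path / "model.json"
        est.to_json(path)
        reloaded = GAEstimator.from_json(path)
        np.testing.assert_allclose(
            reloaded.predict(r), est.predict(r), rtol=0, atol=1e-12
        )

    def test_clipping_optional(self, small_cohort):
        r = small_cohort.records
        est = fit_model(r, r["ga_obs_weeks"], model_id=1, seed=0)
        est.clip_range = (38.9, 39.1)
        clipped = est.predict(r)
        assert clipped.min() >= 38.9 and clipped.max() <= 39.1


class TestRecalibrate:
    def _estimates(self, pred, obs):
        n = len(pred)
        return GAEstimateSet(
            pd.Series([f"S{i}" for i in range(n)]),
            pd.DataFrame({"imp_1": pred}),
            pd.Series(obs),
        )

    def test_identity_when_perfect(self):
        obs = np.linspace(34, 42, 50)
        cal = recalibrate(self._estimates(obs.copy(), obs))
        assert cal.slope == pytest.approx(1.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(cal.adjusted.pooled, cal.raw.pooled)

    def test_pure_shift_removed(self):
        obs = np.linspace(34, 42, 50)
        cal = recalibrate(self._estimates(obs + 1.0, obs))
        np.testing.assert_allclose(cal.adjusted.pooled.to_numpy(), obs, atol=1e-9)

    def test_shrinkage_recovered_and_rmse_reduced(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(39, 1.5, 400)
        pred = 39 + 0.8 * (obs - 39) + rng.normal(0, 0.2, 400)
        cal = recalibrate(self._estimates(pred, obs))
        assert cal.slope == pytest.approx(1 / 0.8, rel=0.1)
        raw_rmse = np.sqrt(np.mean((pred - obs) ** 2))
        adj_rmse = np.sqrt(np.mean((cal.adjusted.pooled.to_numpy() - obs) ** 2))
        assert adj_rmse < raw_rmse

    def test_zero_variance_predictions_rejected(self):
        obs = np.linspace(34, 42, 10)
        with pytest.raises(ValueError, match="zero-variance"):
            recalibrate(self._estimates(np.full(10, 39.0), obs))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            recalibrate(self._estimates(np.array([39.0, 40.0]), np.array([39.0, 40.0])))
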