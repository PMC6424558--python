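"""Validation metrics: RMSE, within-k accuracy, residual diagnostics,
ROC/AUC against the pairwise Mann-Whitney oracle, stratified reporting,
and cohort summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestage import (
    GAEstimateSet,
    default_reference_chart,
    residual_table,
    rmse,
    roc_auc,
    stratified_report,
    summarize_cohort,
    within_k,
)
from gestage.metrics import pooled_roc_auc


def brute_force_auc(scores, labels):
    """Exhaustive pairwise comparison oracle: mean over all (pos, neg)
    pairs of 1{s_pos > s_neg} + 0.5 * 1{tie}."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def estimates_from(pred, obs, m_copies=None, sample_ids=None):
    n = len(pred)
    per = pd.DataFrame({"imp_1": np.asarray(pred, dtype=float)})
    if m_copies:
        per = pd.concat([per] * m_copies, axis=1)
        per.columns = [f"imp_{i+1}" for i in range(m_copies)]
    sids = pd.Series(sample_ids) if sample_ids is not None else pd.Series(
        [f"S{i}" for i in range(n)]
    )
    return GAEstimateSet(sids.reset_index(drop=True), per,
                         pd.Series(np.asarray(obs, dtype=float)))


class TestRmse:
    def test_zero_when_exact(self):
        assert rmse([39.0, 40.0], [39.0, 40.0]) == 0.0

    @pytest.mark.parametrize(
        "residuals,expected",
        [([1, -1, 1, -1], 1.0), ([2, 0, 0, 0], 1.0), ([0.5, -0.5], 0.5)],
    )
    def test_hand_arithmetic(self, residuals, expected):
        obs = np.full(len(residuals), 39.0)
        assert rmse(obs + np.array(residuals, float), obs) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rmse_dominates_mean_absolute(self, residuals):
        res = np.array(residuals)
        obs = np.full(len(res), 39.0)
        assert rmse(obs + res, obs) >= np.mean(np.abs(res)) - 1e-12


class TestWithinK:
    @pytest.mark.parametrize(
        "count,n,expected_pct",
        [(311, 487, 63.9), (937, 1036, 90.4), (459, 487, 94.3), (615, 1036, 59.4)],
    )
    def test_percent_to_one_decimal(self, count, n, expected_pct):
        obs = np.full(n, 39.0)
        pred = obs.copy()
        pred[count:] += 5.0  # beyond any k of interest
        c, pct = within_k(pred, obs, 2.0)
        assert c == count
        assert pct == expected_pct

    def test_boundary_inclusive(self):
        c, _ = within_k([40.0], [39.0], 1.0)
        assert c == 1

    @given(
        st.lists(st.floats(-4, 4), min_size=1, max_size=80).map(np.array)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_k(self, residuals):
        obs = np.full(len(residuals), 39.0)
        c1, _ = within_k(obs + residuals, obs, 1.0)
        c2, _ = within_k(obs + residuals, obs, 2.0)
        assert c1 <= c2

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            within_k([39.0], [39.0], 0.0)


class TestResidualTable:
    def test_category_means_on_constructed_fixture(self):
        obs = np.array([34.0, 35.0, 39.0, 40.0, 43.0])
        pred = obs + np.array([1.0, 1.0, 0.0, 0.0, -1.0])  # regression to the mean
        rows, cats = residual_table(estimates_from(pred, obs))
        assert len(rows) == 5
        assert cats["<37"] == pytest.approx(1.0)
        assert cats["37-42"] == pytest.approx(0.0)
        assert cats[">42"] == pytest.approx(-1.0)

    def test_single_sample(self):
        rows, cats = residual_table(estimates_from([39.5], [39.0]))
        assert len(rows) == 1
        assert cats["37-42"] == pytest.approx(0.5)
        assert np.isnan(cats["<37"])


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1.0, 2.0, 10.0, 11.0], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        r = roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert r.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            roc_auc([1.0, 2.0], [1, 1])

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        s = rng.normal(size=100) + y
        for method in ("delong", "bootstrap"):
            r = roc_auc(s, y, ci_method=method, n_boot=200, seed=0)
            assert 0 <= r.ci_lower <= r.auc <= r.ci_upper <= 1

    def test_curve_monotone(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 80)
        s = rng.normal(size=80) + 0.8 * y
        r = roc_auc(s, y)
        assert (np.diff(r.fpr) >= 0).all()
        assert (np.diff(r.tpr) >= 0).all()

    @given(st.data())
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_matches_pairwise_oracle_with_ties(self, data):
        n = data.draw(st.integers(4, 60))
        # coarse grid forces ties
        scores = np.array(data.draw(
            st.lists(st.integers(0, 6), min_size=n, max_size=n))) / 2.0
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_pooled_auc_is_mean_over_imputations(self):
        rng = np.random.default_rng(3)
        obs = np.concatenate([rng.normal(34, 1, 30), rng.normal(39.5, 1, 120)])
        pred1 = obs + rng.normal(0, 1.0, 150)
        pred2 = obs + rng.normal(0, 1.0, 150)
        per = pd.DataFrame({"imp_1": pred1, "imp_2": pred2})
        ests = GAEstimateSet(pd.Series([f"S{i}" for i in range(150)]), per, pd.Series(obs))
        pooled = pooled_roc_auc(ests)
        y = (obs < 37).astype(int)
        expected = (roc_auc(-pred1, y).auc + roc_auc(-pred2, y).auc) / 2
        assert pooled.auc == pytest.approx(expected)


class TestStratifiedReport:
    def _cohort(self, obs, bw, sex="male"):
        n = len(obs)
        return pd.DataFrame({
            "infant_id": [f"I{i}" for i in range(n)],
            "sample_id": [f"S{i}" for i in range(n)],
            "sample_type": "heel",
            "sex": sex,
            "multiple_birth": 0,
            "birthweight_g": bw,
            "ga_obs_weeks": obs,
            "age_at_collection_h": 15.0,
        })

    def test_hand_computed_strata(self):
        obs = np.array([39.0, 39.0, 39.0, 34.0])
        bw = np.array([3000.0, 3100.0, 2300.0, 2400.0])
        pred = obs + np.array([1.0, -1.0, 2.0, 0.0])
        rep = stratified_report(estimates_from(pred, obs), self._cohort(obs, bw), chart=None)
        overall = rep[rep.stratum == "overall"].iloc[0]
        assert overall["n"] == 4
        assert overall["rmse_weeks"] == pytest.approx(np.sqrt(6 / 4))
        assert overall["within_1wk_count"] == 3
        assert overall["within_2wk_count"] == 4
        low = rep[rep.stratum == "<2500g"].iloc[0]
        assert low["n"] == 2
        assert low["rmse_weeks"] == pytest.approx(np.sqrt(4 / 2))

    def test_empty_stratum_flagged_not_fabricated(self):
        obs = np.full(5, 39.0)
        rep = stratified_report(
            estimates_from(obs.copy(), obs), self._cohort(obs, np.full(5, 3200.0)), chart=None
        )
        pre = rep[rep.stratum == "preterm(<37wk)"].iloc[0]
        assert pre["n"] == 0
        assert np.isnan(pre["rmse_weeks"])

    def test_sga_nesting_in_report(self, big_cohort):
        r = big_cohort.records.head(400).reset_index(drop=True)
        obs = r["ga_obs_weeks"].to_numpy()
        rep = stratified_report(
            estimates_from(obs + 0.5, obs, m_copies=2, sample_ids=r["sample_id"]),
            r,
            chart=default_reference_chart(),
        )
        n10 = rep[rep.stratum == "SGA10"].iloc[0]["n"]
        n3 = rep[rep.stratum == "SGA3"].iloc[0]["n"]
        assert n3 <= n10


class TestSummarizeCohort:
    def test_single_male_term_singleton(self):
        df = pd.DataFrame({
            "infant_id": ["I0"], "sample_id": ["S0"], "sample_type": ["heel"],
            "sex": ["male"], "multiple_birth": [0], "birthweight_g": [3200.0],
            "ga_obs_weeks": [39.5], "age_at_collection_h": [20.0],
        })
        s = summarize_cohort(df)["heel"]
        assert s["sex"]["male"] == (1, 100.0)
        assert s["ga_category"][">=37wk"] == (1, 100.0)
        assert s["multiple_birth"] == (0, 0.0)

    def test_term_percent_to_one_decimal(self):
        n, term = 487, 454
        ga = np.concatenate([np.full(term, 39.0), np.full(n - term, 35.0)])
        df = pd.DataFrame({
            "infant_id": [f"I{i}" for i in range(n)],
            "sample_id": [f"S{i}" for i in range(n)],
            "sample_type": "heel", "sex": "male", "multiple_birth": 0,
            "birthweight_g": 3000.0, "ga_obs_weeks": ga, "age_at_collection_h": 15.0,
        })
        s = summarize_cohort(df)["heel"]
        assert s["ga_category"][">=37wk"] == (454, 93.2)

    def test_birthweight_categories_partition(self, big_cohort):
        s = summarize_cohort(big_cohort.records)
        for stype, sub in s.items():
            total = sum(c for c, _ in sub["birthweight_category"].values())
            assert total == sub["n"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame(columns=["sample_type"]))
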