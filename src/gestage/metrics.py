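"""External-validation surfaces for gestational-age models.

RMSE, within-±k-week accuracy (closed interval: a residual of exactly k
weeks counts as within), stratified performance (overall, SGA10, SGA3,
<2500 g, GA categories), residual diagnostics by observed GA, and
preterm-birth discrimination (ROC/AUC at the dichotomous <37-week
threshold, preterm as the positive class, scored by the negated predicted
GA so lower predictions rank as more preterm-like).

The AUC is the midrank Mann–Whitney statistic — exactly the probability a
random preterm sample receives a more preterm-like score than a random
term sample, with ties counting one half.  Its default 95% CI uses the
DeLong variance estimator; a stratified bootstrap is available.  Under
multiple imputation every metric is computed per completed copy and pooled
across copies: scalars by averaging, counts by averaging then rounding to
the closest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .impute import pool_count, pool_scalar
from .models import GAEstimateSet
from .reference import ReferenceChart, classify_sga

PRETERM_CUT_WEEKS = 37.0
GA_CATEGORIES = (("<37", -np.inf, 37.0), ("37-42", 37.0, 42.0), (">42", 42.0, np.inf))


def _round_half_up(x: float, digits: int = 1) -> float:
    f = 10.0**digits
    return math.floor(x * f + 0.5) / f if x >= 0 else math.ceil(x * f - 0.5) / f


def rmse(predicted, observed) -> float:
    """Root mean square error of predicted minus observed GA, in weeks."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size == 0:
        raise ValueError("rmse of an empty set is undefined")
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValueError("rmse requires finite inputs")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def within_k(predicted, observed, k_weeks: float) -> tuple[int, float]:
    """Count and percent of samples with |predicted - observed| <= k weeks.

    The boundary is inclusive; percent is reported to one decimal.
    """
    if k_weeks <= 0:
        raise ValueError("k_weeks must be > 0")
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size == 0:
        raise ValueError("within_k of an empty set is undefined")
    count = int((np.abs(p - o) <= k_weeks).sum())
    return count, _round_half_up(100.0 * count / p.size, 1)


def residual_table(estimates: GAEstimateSet) -> tuple[pd.DataFrame, dict[str, float]]:
    """Rows of (observed GA, residual) plus mean residual per GA category
    (<37 wk, 37-42 wk, >42 wk).  Residual = predicted - observed."""
    if estimates.observed is None:
        raise ValueError("residuals require observed gestational ages")
    rows = pd.DataFrame(
        {
            "sample_id": estimates.sample_id.to_numpy(),
            "ga_obs_weeks": estimates.observed.to_numpy(dtype=float),
            "residual_weeks": estimates.residual.to_numpy(dtype=float),
        }
    )
    cat_means = {}
    ga = rows["ga_obs_weeks"].to_numpy()
    for label, lo, hi in GA_CATEGORIES:
        sel = (ga >= lo) & (ga < hi) if label != "37-42" else (ga >= lo) & (ga <= hi)
        cat_means[label] = float(rows.loc[sel, "residual_weeks"].mean()) if sel.any() else float("nan")
    return rows, cat_means


# -- ROC / AUC --------------------------------------------------------------


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_lower: float
    ci_upper: float
    positive_class: str = "preterm (<37 wk)"
    ci_method: str = "delong"


def _midrank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via midranks: equals the Mann–Whitney U statistic / (n1*n0)."""
    ranks = stats.rankdata(scores)  # average (mid) ranks under ties
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float, level: float) -> tuple[float, float]:
    """DeLong (1988) variance of the AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.empty(m)
    for i, s in enumerate(pos):
        v10[i] = ((s > neg).sum() + 0.5 * (s == neg).sum()) / n
    v01 = np.empty(n)
    for j, s in enumerate(neg):
        v01[j] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def roc_auc(
    scores,
    preterm_labels,
    ci_method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve and AUC for preterm discrimination.

    ``scores`` must already be oriented so larger means more preterm-like
    (use the negated predicted GA); ``preterm_labels`` is 1 for preterm.
    AUC is the midrank Mann–Whitney probability; the curve comes from the
    empirical operating points.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(preterm_labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("AUC undefined: both preterm and term samples are required")
    auc = _midrank_auc(s, y)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    if ci_method == "delong":
        lo, hi = _delong_ci(s, y, auc, level)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
            )
            reps[b] = _midrank_auc(s[idx], y[idx])
        alpha = 1.0 - level
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2]).tolist()
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(fpr, tpr, auc, float(lo), float(hi), ci_method=ci_method)


def pooled_roc_auc(estimates: GAEstimateSet, ci_method: str = "delong", **kwargs) -> RocResult:
    """Per-imputation ROC/AUC pooled by averaging AUC and CI bounds; the
    curve reported is from the pooled predictions."""
    if estimates.observed is None:
        raise ValueError("preterm labels require observed gestational ages")
    y = (estimates.observed.to_numpy(dtype=float) < PRETERM_CUT_WEEKS).astype(int)
    per = [
        roc_auc(-estimates.per_imputation[c].to_numpy(), y, ci_method=ci_method, **kwargs)
        for c in estimates.per_imputation.columns
    ]
    pooled_curve = roc_auc(-estimates.pooled.to_numpy(), y, ci_method=ci_method, **kwargs)
    return RocResult(
        pooled_curve.fpr,
        pooled_curve.tpr,
        pool_scalar([r.auc for r in per]),
        pool_scalar([r.ci_lower for r in per]),
        pool_scalar([r.ci_upper for r in per]),
        ci_method=ci_method,
    )


# -- stratified reporting ---------------------------------------------------


def _strata_masks(
    estimates: GAEstimateSet, cohort: pd.DataFrame, chart: ReferenceChart | None
) -> dict[str, np.ndarray]:
    cohort = cohort.set_index("sample_id").loc[estimates.sample_id.to_numpy()]
    ga = cohort["ga_obs_weeks"].to_numpy(dtype=float)
    bw = cohort["birthweight_g"].to_numpy(dtype=float)
    masks: dict[str, np.ndarray] = {"overall": np.ones(len(cohort), dtype=bool)}
    if chart is not None:
        sex = cohort["sex"].to_numpy()
        masks["SGA10"] = classify_sga(bw, ga, sex, chart, "P10")
        masks["SGA3"] = classify_sga(bw, ga, sex, chart, "P3")
    masks["<2500g"] = bw < 2500.0
    masks["preterm(<37wk)"] = ga < 37.0
    masks["32-36wk"] = (ga >= 32.0) & (ga < 37.0)
    masks["<32wk"] = ga < 32.0
    masks["term(>=37wk)"] = ga >= 37.0
    return masks


def stratified_report(
    estimates: GAEstimateSet,
    cohort: pd.DataFrame,
    chart: ReferenceChart | None = None,
    ks=(1.0, 2.0),
) -> pd.DataFrame:
    """Per-stratum performance: n, pooled RMSE, pooled within-±k counts
    and percents.  Metrics are computed per imputation then pooled; empty
    strata report n=0 with NaN metrics rather than fabricated values."""
    if estimates.observed is None:
        raise ValueError("stratified reporting requires observed gestational ages")
    obs = estimates.observed.to_numpy(dtype=float)
    rows = []
    for label, mask in _strata_masks(estimates, cohort, chart).items():
        n = int(mask.sum())
        row: dict = {"stratum": label, "model": estimates.model_id, "n": n}
        if n == 0:
            row["rmse_weeks"] = float("nan")
            for k in ks:
                row[f"within_{k:g}wk_count"] = 0
                row[f"within_{k:g}wk_pct"] = float("nan")
            rows.append(row)
            continue
        per_rmse, per_counts = [], {k: [] for k in ks}
        for c in estimates.per_imputation.columns:
            pred = estimates.per_imputation[c].to_numpy()[mask]
            per_rmse.append(rmse(pred, obs[mask]))
            for k in ks:
                per_counts[k].append(within_k(pred, obs[mask], k)[0])
        row["rmse_weeks"] = pool_scalar(per_rmse)
        for k in ks:
            cnt = pool_count(per_counts[k])
            row[f"within_{k:g}wk_count"] = cnt
            row[f"within_{k:g}wk_pct"] = _round_half_up(100.0 * cnt / n, 1)
        rows.append(row)
    return pd.DataFrame(rows)


# -- cohort summarization ---------------------------------------------------

BW_CATEGORIES = (
    (">=4000g", 4000.0, np.inf),
    ("2500-3999g", 2500.0, 4000.0),
    ("1500-2499g", 1500.0, 2500.0),
    ("1000-1499g", 1000.0, 1500.0),
    ("<1000g", -np.inf, 1000.0),
)


def _pct(count: int, n: int) -> float:
    return _round_half_up(100.0 * count / n, 1) if n else float("nan")


def summarize_cohort(cohort: pd.DataFrame) -> dict:
    """Cohort characteristics by sample type: counts/percents for sex, GA
    category (cuts at 32 and 37 completed weeks), birthweight category
    (cuts at 1000/1500/2500/4000 g) and multiples; mean ± SD of GA,
    birthweight (overall / term / preterm) and collection age."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    out: dict = {}
    for stype, grp in cohort.groupby("sample_type"):
        n = len(grp)
        ga = grp["ga_obs_weeks"].to_numpy(dtype=float)
        bw = grp["birthweight_g"].to_numpy(dtype=float)
        age = grp["age_at_collection_h"].to_numpy(dtype=float)
        term = ga >= 37.0
        s: dict = {"n": n}
        male = int((grp["sex"] == "male").sum())
        s["sex"] = {
            "male": (male, _pct(male, n)),
            "female": (n - male, _pct(n - male, n)),
        }
        s["ga_category"] = {
            ">=37wk": (int(term.sum()), _pct(int(term.sum()), n)),
            "32-36wk": (
                int(((ga >= 32) & (ga < 37)).sum()),
                _pct(int(((ga >= 32) & (ga < 37)).sum()), n),
            ),
            "<32wk": (int((ga < 32).sum()), _pct(int((ga < 32).sum()), n)),
        }
        s["ga_weeks_mean_sd"] = (float(ga.mean()), float(ga.std(ddof=1)) if n > 1 else 0.0)
        s["birthweight_g_mean_sd"] = {
            "overall": (float(bw.mean()), float(bw.std(ddof=1)) if n > 1 else 0.0),
            "term": _mean_sd(bw[term]),
            "preterm": _mean_sd(bw[~term]),
        }
        s["birthweight_category"] = {
            label: (int(((bw >= lo) & (bw < hi)).sum()), _pct(int(((bw >= lo) & (bw < hi)).sum()), n))
            for label, lo, hi in BW_CATEGORIES
        }
        mult = int((grp["multiple_birth"].astype(int) == 1).sum())
        s["multiple_birth"] = (mult, _pct(mult, n))
        s["collection_age_h_mean_sd"] = {
            "overall": _mean_sd(age),
            "term": _mean_sd(age[term]),
            "preterm": _mean_sd(age[~term]),
        }
        out[stype] = s
    return out


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 0:
        return (float("nan"), float("nan"))
    return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0
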