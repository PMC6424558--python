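"""Sample screening, multiple imputation, and pooling of results.

Samples missing their entire analyte panel carry no information and are
excluded at screening (the default exclusion threshold of 1.0 drops only
fully-missing samples).  Remaining missing analyte values are multiply
imputed (default m = 10) by chained-equations regression with posterior
noise draws, conditioning on all observed analytes plus sex, birthweight
and sample type.  Gestational age is deliberately never used as a
conditioning variable: it is the downstream prediction target.

Downstream results are pooled across imputations as plain averages;
pooled counts are the average count rounded to the closest integer
(ties rounded away from zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .panel import AnalytePanel, default_panel
from .simulate import CohortTable

DEFAULT_M = 10


@dataclass
class ScreeningResult:
    kept: list[str]
    excluded: dict[str, str]  # sample_id -> reason code
    missing_counts: pd.Series  # per-sample missing analyte count
    flagged_for_imputation: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.excluded)


def screen_samples(
    cohort: CohortTable | pd.DataFrame,
    exclusion_threshold: float = 1.0,
    panel: AnalytePanel | None = None,
) -> ScreeningResult:
    """Partition samples into kept and excluded by missing-analyte fraction.

    A sample is excluded when its missing fraction is >= the threshold
    (default 1.0: only samples with 100% of analyte values missing are
    dropped).  Kept samples with any missing analyte are flagged for
    imputation.
    """
    records = cohort.records if isinstance(cohort, CohortTable) else cohort
    panel = panel or default_panel()
    names = [n for n in panel.names if n in records.columns]
    if not names:
        raise ValueError("cohort has no analyte columns from the panel")
    if len(records) == 0:
        logging.getLogger("gestage").warning("screening an empty cohort")
        return ScreeningResult([], {}, pd.Series(dtype=int))
    counts = records[names].isna().sum(axis=1)
    counts.index = records["sample_id"]
    frac = counts / len(names)
    kept, excluded, flagged = [], {}, []
    for sid, f in frac.items():
        if f >= exclusion_threshold:
            excluded[sid] = "all_missing" if f >= 1.0 else "above_threshold"
        else:
            kept.append(sid)
            if f > 0:
                flagged.append(sid)
    return ScreeningResult(kept, excluded, counts, flagged)


@dataclass
class ImputationSet:
    """m completed copies of a cohort (observed cells identical across
    copies; only originally-missing cells vary)."""

    copies: list[pd.DataFrame]
    seed: int
    method: str = "mice-bayesian-ridge"

    @property
    def m(self) -> int:
        return len(self.copies)

    def __iter__(self):
        return iter(self.copies)


def _conditioning_frame(records: pd.DataFrame, analyte_names: list[str]) -> pd.DataFrame:
    X = records[analyte_names].copy()
    X["__sex"] = (records["sex"] == "male").astype(float)
    X["__multiple"] = records["multiple_birth"].astype(float)
    X["__bw"] = records["birthweight_g"].astype(float)
    X["__cord"] = (records["sample_type"] == "cord").astype(float)
    return X


def impute_missing(
    cohort: CohortTable | pd.DataFrame,
    m: int = DEFAULT_M,
    seed: int = 0,
    panel: AnalytePanel | None = None,
    max_iter: int = 8,
) -> ImputationSet:
    """Multiply impute missing analytes by chained equations.

    Produces ``m`` completed copies; each copy's imputations are posterior
    draws (Bayesian ridge per analyte) with a distinct stream derived from
    ``seed``, so copies are stochastically distinct but fully reproducible.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    records = cohort.records if isinstance(cohort, CohortTable) else cohort
    panel = panel or default_panel()
    names = [n for n in panel.names if n in records.columns]
    values = records[names]
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"cannot impute analytes missing in every sample: {list(all_missing)}; "
            "exclude them from the panel or supply data"
        )
    if not values.isna().any().any():
        return ImputationSet([records.copy() for _ in range(m)], seed)

    X = _conditioning_frame(records, names)
    copies = []
    child_seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    for k in range(m):
        imp = IterativeImputer(
            estimator=BayesianRidge(),
            sample_posterior=True,
            max_iter=max_iter,
            random_state=int(child_seeds[k]),
            keep_empty_features=True,
        )
        filled = pd.DataFrame(imp.fit_transform(X), columns=X.columns, index=X.index)
        copy = records.copy()
        copy[names] = np.maximum(filled[names].to_numpy(), 0.0)  # concentrations >= 0
        # observed cells are restored exactly (imputer round-trips them,
        # but we never rely on that)
        observed = ~values.isna()
        for col in names:
            copy.loc[observed[col].to_numpy(), col] = values.loc[observed[col], col]
        copies.append(copy)
    return ImputationSet(copies, seed)


def pool_scalar(values, m: int | None = None) -> float:
    """Pooled scalar across imputations: the arithmetic mean."""
    vals = np.asarray(list(values), dtype=float)
    if m is not None and len(vals) != m:
        raise ValueError(f"expected {m} values, got {len(vals)}")
    if len(vals) == 0:
        raise ValueError("cannot pool an empty collection")
    return float(vals.mean())

def pool_count(counts, m: int | None = None) -> int:
    """Pooled count: the mean count rounded to the closest integer, ties
    rounded half away from zero."""
    mean = pool_scalar(counts, m)
    return int(math.floor(mean + 0.5)) if mean >= 0 else int(math.ceil(mean - 0.5))
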