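"""Gestational-age prediction models.

Three nested multivariable models estimate continuous gestational age
(weeks) from a dried-blood-spot sample:

* Model 1 (baseline): infant sex, multiple birth, birthweight.
* Model 2 (analyte): sex, multiple birth, the analyte panel, and pairwise
  analyte interactions (no birthweight).
* Model 3 (full): all clinical covariates plus analytes and interactions.

Fitting is elastic-net penalized least squares (mixing parameter alpha,
default 0.5) with k-fold cross-validation selecting the penalty weight at
minimum CV error; continuous predictors are standardized and interactions
are formed on the standardized main effects.  By default interactions are
restricted to all pairs among the analytes with the strongest independent
gestational-age contribution (fetal/adult hemoglobin ratio, TSH, 17-OHP,
ALA, C5, C4DC, TYR); an all-pairs option exists.

The estimator is scikit-learn compatible (``get_params``/``set_params``,
fitted attributes with trailing underscores) so it composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .impute import ImputationSet
from .panel import STRONG_PREDICTORS, default_panel

CLINICAL_ORDER = ["sex", "multiple_birth", "birthweight_g"]
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Term list for one model of the hierarchy."""

    model_id: int
    clinical_terms: tuple[str, ...]
    analyte_terms: tuple[str, ...] = ()
    interaction_pairs: tuple[tuple[str, str], ...] = ()
    standardize: bool = True
    l1_ratio: float = 0.5
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        unknown = set(self.clinical_terms) - set(CLINICAL_ORDER)
        if unknown:
            raise ValueError(f"unknown clinical terms: {sorted(unknown)}")
        if self.model_id == 1:
            if self.analyte_terms:
                raise ValueError("Model 1 takes no analyte terms")
            if "birthweight_g" not in self.clinical_terms:
                raise ValueError("Model 1 must include birthweight")
        if self.model_id == 2 and "birthweight_g" in self.clinical_terms:
            raise ValueError("Model 2 excludes birthweight")
        if self.model_id in (2, 3):
            for t in ("sex", "multiple_birth"):
                if t not in self.clinical_terms:
                    raise ValueError(f"Model {self.model_id} must include {t}")
        declared = set(self.analyte_terms)
        for a, b in self.interaction_pairs:
            if a not in declared or b not in declared:
                raise ValueError(f"interaction pair ({a}, {b}) references undeclared analytes")

    @property
    def columns(self) -> list[str]:
        """Deterministic design-column order: clinical, analytes
        (alphabetical), interaction pairs (lexicographic)."""
        clin = [c for c in CLINICAL_ORDER if c in self.clinical_terms]
        mains = sorted(self.analyte_terms)
        pairs = sorted(tuple(sorted(p)) for p in self.interaction_pairs)
        return clin + mains + [f"{a}*{b}" for a, b in pairs]


def make_model_spec(
    model_id: int,
    analytes=None,
    interactions: str | tuple = "strong",
    **kwargs,
) -> ModelSpec:
    """Build the spec for Model 1, 2 or 3.

    ``interactions``: ``"strong"`` (all pairs among the strong-predictor
    subset present on the panel), ``"all"`` (all pairs among the analyte
    terms), ``"none"``, or an explicit pair collection.
    """
    if model_id == 1:
        return ModelSpec(1, tuple(CLINICAL_ORDER), **kwargs)
    analytes = tuple(analytes) if analytes is not None else tuple(default_panel().names)
    if interactions == "strong":
        base = [a for a in STRONG_PREDICTORS if a in analytes]
        pairs = tuple(itertools.combinations(sorted(base), 2))
    elif interactions == "all":
        pairs = tuple(itertools.combinations(sorted(analytes), 2))
    elif interactions == "none":
        pairs = ()
    else:
        pairs = tuple(tuple(sorted(p)) for p in interactions)
    clinical = ("sex", "multiple_birth") if model_id == 2 else tuple(CLINICAL_ORDER)
    return ModelSpec(model_id, clinical, analytes, pairs, **kwargs)


# ---------------------------------------------------------------------------


def _raw_features(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Encode raw main-effect columns (before standardization)."""
    cols = {}
    for term in [c for c in CLINICAL_ORDER if c in spec.clinical_terms]:
        if term == "sex":
            cols["sex"] = (records["sex"] == "male").astype(float)
        elif term == "multiple_birth":
            cols["multiple_birth"] = records["multiple_birth"].astype(float)
        else:
            cols["birthweight_g"] = records["birthweight_g"].astype(float)
    for name in sorted(spec.analyte_terms):
        if name not in records.columns:
            raise KeyError(f"required analyte column {name!r} absent from records")
        vals = records[name].astype(float)
        if vals.isna().any():
            bad = records.loc[vals.isna(), "sample_id"].iloc[0] if "sample_id" in records else "?"
            raise ValueError(
                f"missing value for term {name!r} (e.g. sample {bad}); impute upstream"
            )
        cols[name] = np.log1p(vals) if spec.log_transform else vals
    return pd.DataFrame(cols, index=records.index)


def build_design_matrix(
    records: pd.DataFrame,
    spec: ModelSpec,
    scaler: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Assemble the design matrix for ``spec``.

    Continuous columns (birthweight, analytes, and the formed interaction
    products) are standardized to zero mean and unit SD when
    ``spec.standardize``; binary indicators (sex, multiple_birth) are left
    as 0/1.  ``scaler`` maps column -> (center, scale); pass a stored
    scaler to reproduce a training design on new data, or ``None`` to fit
    one.  Returns ``(design, scaler)``.
    """
    X = _raw_features(records, spec)
    fit_scaler = scaler is None
    scaler = {} if fit_scaler else dict(scaler)
    binary = {"sex", "multiple_birth"}

    def _standardize(col: str, vals: pd.Series) -> pd.Series:
        if not spec.standardize or col in binary:
            return vals
        if fit_scaler:
            center, scale = float(vals.mean()), float(vals.std(ddof=0))
            if scale == 0.0:
                scale = 1.0
            scaler[col] = (center, scale)
        center, scale = scaler[col]
        return (vals - center) / scale

    out = {col: _standardize(col, X[col]) for col in X.columns}
    pairs = sorted(tuple(sorted(p)) for p in spec.interaction_pairs)
    for a, b in pairs:
        out[f"{a}*{b}"] = _standardize(f"{a}*{b}", out[a] * out[b])
    design = pd.DataFrame(out, index=records.index)[spec.columns]
    return design, scaler


class GAEstimator(BaseEstimator, RegressorMixin):
    """Elastic-net gestational-age regressor over one model spec.

    Parameters
    ----------
    model : int
        1 (baseline clinical), 2 (analyte), or 3 (full).
    analytes : sequence of str, optional
        Analyte terms for Models 2/3 (default: the 47-analyte panel).
    interactions : {"strong", "all", "none"} or pair collection
        Pairwise analyte interaction scope.
    l1_ratio : float
        Elastic-net mixing (1 = lasso, 0 = ridge).
    n_lambdas, lambda_min_ratio : penalty grid (geometric, from the
        data-derived maximum down to ``lambda_min_ratio`` times it).
    cv : int
        Number of cross-validation folds.
    log_transform : bool
        Apply log1p to analyte main effects before standardization.
    clip_range : (float, float) or None
        Optional prediction clipping in weeks; off by default.
    random_state : int
        Seeds the CV fold shuffle; fits are deterministic given it.
    """

    def __init__(
        self,
        model: int = 3,
        analytes=None,
        interactions="strong",
        l1_ratio: float = 0.5,
        n_lambdas: int = 80,
        lambda_min_ratio: float = 1e-5,
        cv: int = 10,
        log_transform: bool = False,
        clip_range=None,
        random_state: int = 0,
    ):
        self.model = model
        self.analytes = analytes
        self.interactions = interactions
        self.l1_ratio = l1_ratio
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.log_transform = log_transform
        self.clip_range = clip_range
        self.random_state = random_state

    # -- core API ------------------------------------------------------

    def fit(self, records: pd.DataFrame, y) -> "GAEstimator":
        y = np.asarray(y, dtype=float)
        if len(records) != len(y):
            raise ValueError("records and y length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("observed gestational ages must be finite")
        if np.ptp(y) == 0.0:
            raise ValueError("constant outcome: gestational age has zero variance")
        if len(records) <= self.cv:
            raise ValueError(f"need more than cv={self.cv} samples to fit")
        spec = make_model_spec(
            self.model,
            self.analytes,
            self.interactions,
            l1_ratio=self.l1_ratio,
            log_transform=self.log_transform,
        )
        design, scaler = build_design_matrix(records, spec)
        keep = design.columns[design.std(ddof=0) > 0].tolist()
        dropped = [c for c in design.columns if c not in keep]
        if dropped:
            warnings.warn(f"dropping zero-variance design columns: {dropped}", stacklevel=2)
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        enet = ElasticNetCV(
            l1_ratio=self.l1_ratio,
            alphas=self.n_lambdas,
            eps=self.lambda_min_ratio,
            cv=folds,
            max_iter=50_000,
            tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter at tiny lambdas
            enet.fit(design[keep].to_numpy(), y)
        self.spec_ = spec
        self.scaler_ = scaler
        self.columns_ = keep
        self.dropped_columns_ = dropped
        self.coef_ = dict(zip(keep, enet.coef_.tolist()))
        self.intercept_ = float(enet.intercept_)
        self.lambda_ = float(enet.alpha_)
        self.n_features_in_ = design.shape[1]
        self.training_meta_ = {
            "n": int(len(y)),
            "seed": self.random_state,
            "selected_lambda": self.lambda_,
            "cv_folds": self.cv,
        }
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        design, _ = build_design_matrix(records, self.spec_, scaler=self.scaler_)
        missing = [c for c in self.columns_ if c not in design.columns]
        if missing:
            raise KeyError(f"records lack required model terms: {missing}")
        beta = np.array([self.coef_[c] for c in self.columns_])
        pred = design[self.columns_].to_numpy() @ beta + self.intercept_
        if self.clip_range is not None:
            pred = np.clip(pred, *self.clip_range)
        return pred

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "schema_version": SCHEMA_VERSION,
            "params": self.get_params(deep=False)
            | {"analytes": list(self.analytes) if self.analytes is not None else None,
               "interactions": (self.interactions if isinstance(self.interactions, str)
                                else [list(p) for p in self.interactions])},
            "spec": {
                "model_id": self.spec_.model_id,
                "clinical_terms": list(self.spec_.clinical_terms),
                "analyte_terms": list(self.spec_.analyte_terms),
                "interaction_pairs": [list(p) for p in self.spec_.interaction_pairs],
                "standardize": self.spec_.standardize,
                "l1_ratio": self.spec_.l1_ratio,
                "log_transform": self.spec_.log_transform,
            },
            "standardization": {k: list(v) for k, v in self.scaler_.items()},
            "columns": self.columns_,
            "dropped_columns": self.dropped_columns_,
            "intercept_weeks": self.intercept_,
            "coefficients": self.coef_,
            "lambda": self.lambda_,
            "training_meta": self.training_meta_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GAEstimator":
        params = dict(d["params"])
        if not isinstance(params.get("interactions"), str) and params.get("interactions") is not None:
            params["interactions"] = tuple(tuple(p) for p in params["interactions"])
        if params.get("clip_range") is not None:
            params["clip_range"] = tuple(params["clip_range"])
        est = cls(**params)
        s = d["spec"]
        est.spec_ = ModelSpec(
            s["model_id"],
            tuple(s["clinical_terms"]),
            tuple(s["analyte_terms"]),
            tuple(tuple(p) for p in s["interaction_pairs"]),
            s["standardize"],
            s["l1_ratio"],
            s["log_transform"],
        )
        est.scaler_ = {k: tuple(v) for k, v in d["standardization"].items()}
        est.columns_ = list(d["columns"])
        est.dropped_columns_ = list(d["dropped_columns"])
        est.intercept_ = float(d["intercept_weeks"])
        est.coef_ = {k: float(v) for k, v in d["coefficients"].items()}
        est.lambda_ = float(d["lambda"])
        est.training_meta_ = dict(d["training_meta"])
        est.n_features_in_ = len(d["columns"]) + len(d["dropped_columns"])
        return est

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GAEstimator":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------


@dataclass
class GAEstimateSet:
    """Per-sample predictions: one column per imputation, pooled mean,
    observed GA, and residual (pooled - observed)."""

    sample_id: pd.Series
    per_imputation: pd.DataFrame  # columns imp_1..imp_m
    observed: pd.Series | None = None
    model_id: int | None = None

    def __post_init__(self) -> None:
        self.pooled = self.per_imputation.mean(axis=1)
        self.residual = None if self.observed is None else self.pooled - self.observed

    @property
    def m(self) -> int:
        return self.per_imputation.shape[1]

    def __len__(self) -> int:
        return len(self.pooled)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.sample_id.to_numpy()})
        for c in self.per_imputation.columns:
            out[c] = self.per_imputation[c].to_numpy()
        out["pooled_ga_weeks"] = self.pooled.to_numpy()
        if self.observed is not None:
            out["ga_obs_weeks"] = self.observed.to_numpy()
            out["residual_weeks"] = self.residual.to_numpy()
        if self.model_id is not None:
            out["model"] = self.model_id
        return out


def fit_model(records: pd.DataFrame, ga_obs, model_id: int = 3, seed: int = 0, **kwargs) -> GAEstimator:
    """Fit one model of the hierarchy (thin wrapper over GAEstimator)."""
    return GAEstimator(model=model_id, random_state=seed, **kwargs).fit(records, ga_obs)


def predict_ga(model: GAEstimator, data, observed: str | None = "ga_obs_weeks") -> GAEstimateSet:
    """Score records (a DataFrame) or an ImputationSet.

    For an ImputationSet each completed copy is scored and the pooled
    prediction is the per-sample mean; observed GA and residuals are
    attached when the records carry an observed-GA column.
    """
    if isinstance(data, ImputationSet):
        copies = data.copies
    else:
        copies = [data]
    first = copies[0]
    preds = {f"imp_{k + 1}": model.predict(copy) for k, copy in enumerate(copies)}
    per_imp = pd.DataFrame(preds, index=first.index)
    obs = first[observed] if observed is not None and observed in first.columns else None
    sid = first["sample_id"] if "sample_id" in first.columns else pd.Series(
        [str(i) for i in range(len(first))], index=first.index
    )
    return GAEstimateSet(sid, per_imp, obs, getattr(model, "model", None))


@dataclass
class CalibrationResult:
    intercept: float
    slope: float
    raw: GAEstimateSet
    adjusted: GAEstimateSet


def recalibrate(estimates: GAEstimateSet) -> CalibrationResult:
    """Calibration-in-the-large: OLS of observed on predicted GA.

    Predictions shrunken toward the cohort mean yield a slope above 1,
    over-dispersed predictions a slope below 1.  The adjusted prediction
    is ``intercept + slope * prediction``; both raw and adjusted estimate
    sets are returned.
    """
    if estimates.observed is None:
        raise ValueError("recalibration requires observed gestational ages")
    if len(estimates) < 3:
        raise ValueError("recalibration requires at least 3 samples")
    x = estimates.pooled.to_numpy()
    y = estimates.observed.to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("zero-variance predictions cannot be recalibrated")
    slope, intercept = np.polyfit(x, y, 1)
    adjusted = GAEstimateSet(
        estimates.sample_id,
        intercept + slope * estimates.per_imputation,
        estimates.observed,
        estimates.model_id,
    )
    return CalibrationResult(float(intercept), float(slope), estimates, adjusted)
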