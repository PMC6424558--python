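"""Seeded simulation of newborn-screening cohorts.

One row per dried-blood-spot sample: clinical covariates (sex, multiple
birth, birthweight, ultrasound gestational age, postnatal age at
collection) plus the analyte panel.  Infants may contribute a heel-prick
sample, a cord sample, or both (paired rows share all clinical fields).

Gestational age is drawn from a two-component mixture: a dominant term
component (truncated normal on [37, 43] wk) and a preterm tail (truncated
normal on [24, 37) wk, mean 34.8, SD 1.9).  The term component's location
and spread are solved numerically so the mixture reproduces the configured
overall mean/SD at the configured preterm fraction, matching the heavy
right-shifted, left-skewed shape of facility-birth GA distributions.

Analyte values follow linear mean models in GA and postnatal age with a
cord-sample shift, plus noise that is partially shared within analyte
groups (single latent factor, strength ``correlation_strength``), truncated
at zero because concentrations are nonnegative.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import SimulationConfig
from .panel import AnalytePanel

__generator_version__ = "1.0"

CLINICAL_COLUMNS = [
    "infant_id", "sample_id", "sample_type", "sex", "multiple_birth",
    "birthweight_g", "ga_obs_weeks", "age_at_collection_h",
]

GA_LO, GA_HI = 20.0, 45.0
TERM_LO, TERM_HI = 37.0, 43.0
PRETERM_LO = 24.0
PRETERM_MEAN, PRETERM_SD = 34.8, 1.9
BW_SEX_OFFSET_G = 60.0  # male minus female, g
CORD_AGE_MAX_H = 2.0167  # 2 h 1 min


@dataclass
class CohortTable:
    """A simulated cohort: one row per sample, plus provenance."""

    records: pd.DataFrame
    provenance: dict

    def __len__(self) -> int:
        return len(self.records)


def _config_digest(config: SimulationConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _trunc_norm_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    d = stats.truncnorm(a, b, loc=mu, scale=sigma)
    return d.mean(), d.std()


def solve_term_component(config: SimulationConfig) -> tuple[float, float]:
    """Solve (mu, sigma) of the term truncated normal so the GA mixture
    hits the configured overall mean and SD."""
    p = config.preterm_target_fraction
    m_pre, s_pre = _trunc_norm_moments(PRETERM_MEAN, PRETERM_SD, PRETERM_LO, TERM_LO)
    target_mean, target_var = config.ga_mean_weeks, config.ga_sd_weeks**2
    if p >= 1.0:
        raise ValueError("preterm_target_fraction must be < 1 for a term component to exist")

    # component mean/var the term part must contribute
    m_term = (target_mean - p * m_pre) / (1.0 - p)
    v_term = (
        target_var
        - p * (s_pre**2 + (m_pre - target_mean) ** 2)
        - (1.0 - p) * (m_term - target_mean) ** 2
    ) / (1.0 - p)
    if v_term <= 0:
        raise ValueError(
            "configured GA mean/SD and preterm fraction are jointly infeasible "
            "(term component would need non-positive variance)"
        )

    def residuals(x):
        mu, log_sigma = x
        m, s = _trunc_norm_moments(mu, np.exp(log_sigma), TERM_LO, TERM_HI)
        return [m - m_term, s - np.sqrt(v_term)]

    sol = optimize.fsolve(residuals, x0=[m_term, np.log(np.sqrt(v_term))], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


def _draw_ga(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    mu_t, sd_t = solve_term_component(config)
    is_pre = rng.random(n) < config.preterm_target_fraction
    a_t, b_t = (TERM_LO - mu_t) / sd_t, (TERM_HI - mu_t) / sd_t
    a_p = (PRETERM_LO - PRETERM_MEAN) / PRETERM_SD
    b_p = (TERM_LO - PRETERM_MEAN) / PRETERM_SD
    ga = stats.truncnorm.rvs(a_t, b_t, loc=mu_t, scale=sd_t, size=n, random_state=rng)
    n_pre = int(is_pre.sum())
    if n_pre:
        ga[is_pre] = stats.truncnorm.rvs(
            a_p, b_p, loc=PRETERM_MEAN, scale=PRETERM_SD, size=n_pre, random_state=rng
        )
    return np.clip(ga, GA_LO, GA_HI)


def _draw_birthweight(
    ga: np.ndarray, male: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Birthweight conditional on GA and sex.

    The GA slope is derived from the configured term/preterm means and the
    mixture component locations, so the marginal term/preterm birthweight
    summaries land near their configured values.
    """
    mu_t, sd_t = solve_term_component(config)
    m_term, _ = _trunc_norm_moments(mu_t, sd_t, TERM_LO, TERM_HI)
    m_pre, _ = _trunc_norm_moments(PRETERM_MEAN, PRETERM_SD, PRETERM_LO, TERM_LO)
    slope = (config.birthweight_term_mean_g - config.birthweight_preterm_mean_g) / (
        m_term - m_pre
    )
    # within-term GA spread explains part of the term SD; the rest is noise
    _, s_term_ga = _trunc_norm_moments(mu_t, sd_t, TERM_LO, TERM_HI)
    resid_var = config.birthweight_term_sd_g**2 - (slope * s_term_ga) ** 2
    resid_sd = np.sqrt(max(resid_var, 100.0**2))
    mean = (
        config.birthweight_term_mean_g
        + slope * (ga - m_term)
        + BW_SEX_OFFSET_G * (male - 0.5)
    )
    bw = mean + rng.normal(0.0, resid_sd, size=ga.shape)
    return np.clip(bw, 300.0, 6000.0)


def birthweight_model_params(config: SimulationConfig) -> dict:
    """Anchor points of the conditional birthweight model (used to build a
    matched reference chart)."""
    mu_t, sd_t = solve_term_component(config)
    m_term, s_term_ga = _trunc_norm_moments(mu_t, sd_t, TERM_LO, TERM_HI)
    m_pre, _ = _trunc_norm_moments(PRETERM_MEAN, PRETERM_SD, PRETERM_LO, TERM_LO)
    slope = (config.birthweight_term_mean_g - config.birthweight_preterm_mean_g) / (
        m_term - m_pre
    )
    resid_sd = np.sqrt(
        max(config.birthweight_term_sd_g**2 - (slope * s_term_ga) ** 2, 100.0**2)
    )
    return {
        "ga_anchor_weeks": m_term,
        "mean_at_anchor_g": config.birthweight_term_mean_g,
        "slope_g_per_week": slope,
        "sex_offset_g": BW_SEX_OFFSET_G,
        "resid_sd_g": resid_sd,
    }


def _draw_collection_age(
    sample_type: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    age = np.zeros(len(sample_type))
    heel = sample_type == "heel"
    cord = ~heel
    if heel.any():
        a = (0.4 - config.heel_collection_mean_h) / config.heel_collection_sd_h
        b = (72.0 - config.heel_collection_mean_h) / config.heel_collection_sd_h
        age[heel] = stats.truncnorm.rvs(
            a, b, loc=config.heel_collection_mean_h, scale=config.heel_collection_sd_h,
            size=int(heel.sum()), random_state=rng,
        )
    if cord.any():
        a = (0.0 - config.cord_collection_mean_h) / config.cord_collection_sd_h
        b = (CORD_AGE_MAX_H - config.cord_collection_mean_h) / config.cord_collection_sd_h
        age[cord] = stats.truncnorm.rvs(
            a, b, loc=config.cord_collection_mean_h, scale=config.cord_collection_sd_h,
            size=int(cord.sum()), random_state=rng,
        )
    return age


def simulate_analytes(
    ga_obs_weeks,
    age_at_collection_h,
    sample_type,
    sex,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw analyte values for samples with the given covariates.

    Vectorized: scalar inputs are broadcast to length-1 arrays.  Each
    analyte follows ``intercept + ga_slope*(ga-40) + age_slope*age +
    cord_shift*1{cord} + noise`` truncated at zero, where the noise of
    analytes in the same group shares a latent factor of configurable
    strength (the marginal noise SD is preserved).  ``sex`` is accepted
    for mechanism extensions but does not enter the default mean model.
    """
    ga = np.atleast_1d(np.asarray(ga_obs_weeks, dtype=float))
    age = np.atleast_1d(np.asarray(age_at_collection_h, dtype=float))
    stype = np.atleast_1d(np.asarray(sample_type, dtype=object))
    n = len(ga)
    panel = config.panel
    unknown = set(config.analyte_effects) - set(panel.names)
    if unknown:
        raise ValueError(f"effects refer to unknown analytes: {sorted(unknown)}")
    is_cord = (stype == "cord").astype(float)

    c = config.correlation_strength
    group_factors = {g: rng.standard_normal(n) for g in sorted({panel.group(a) for a in panel})}
    out = {}
    for name in panel.names:
        e = config.analyte_effects[name]
        mean = (
            e.intercept
            + e.ga_slope * (ga - 40.0)
            + e.age_slope * age
            + e.cord_shift * is_cord
        )
        noise = e.noise_sd * (
            np.sqrt(1.0 - c**2) * rng.standard_normal(n)
            + c * group_factors[panel.group(name)]
        )
        out[name] = np.maximum(mean + noise, 0.0)
    return pd.DataFrame(out, columns=list(panel.names))


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Simulate a full cohort (deterministic given ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_infants
    provenance = {
        "seed": config.seed,
        "config_digest": _config_digest(config),
        "generator_version": __generator_version__,
    }
    panel = config.panel
    columns = CLINICAL_COLUMNS + list(panel.names)
    if n == 0:
        return CohortTable(pd.DataFrame(columns=columns), provenance)

    ga = _draw_ga(n, config, rng)
    male = (rng.random(n) < config.sex_male_fraction).astype(int)
    multiple = (rng.random(n) < config.multiple_birth_fraction).astype(int)
    bw = _draw_birthweight(ga, male, config, rng)

    u = rng.random(n)
    paired = u < config.paired_fraction
    heel_only = (~paired) & (u < config.paired_fraction + config.heel_only_fraction)
    cord_only = ~(paired | heel_only)

    rows = []
    infant_ids = np.array([f"I{i:06d}" for i in range(n)])
    for stype, mask in (("heel", paired | heel_only), ("cord", paired | cord_only)):
        idx = np.flatnonzero(mask)
        df = pd.DataFrame(
            {
                "infant_id": infant_ids[idx],
                "sample_id": [f"{infant_ids[i]}-{stype[0].upper()}" for i in idx],
                "sample_type": stype,
                "sex": np.where(male[idx] == 1, "male", "female"),
                "multiple_birth": multiple[idx],
                "birthweight_g": bw[idx],
                "ga_obs_weeks": ga[idx],
            }
        )
        rows.append(df)
    samples = pd.concat(rows, ignore_index=True)
    samples["age_at_collection_h"] = _draw_collection_age(
        samples["sample_type"].to_numpy(), config, rng
    )
    analytes = simulate_analytes(
        samples["ga_obs_weeks"].to_numpy(),
        samples["age_at_collection_h"].to_numpy(),
        samples["sample_type"].to_numpy(),
        samples["sex"].to_numpy(),
        config,
        rng,
    )
    records = pd.concat([samples, analytes], axis=1)
    records = records.sort_values("sample_id", kind="stable").reset_index(drop=True)
    return CohortTable(records, provenance)


def apply_missingness(
    cohort: CohortTable,
    config: SimulationConfig,
    inject_fully_missing: int = 0,
) -> CohortTable:
    """Blank analyte cells at random (MCAR by default; MAR doubles the rate
    for cord samples), capped per sample at ``max_missing_per_sample``.

    ``inject_fully_missing`` samples (taken from the end of the table) have
    every analyte blanked, to exercise the screening step.
    """
    panel = config.panel
    if config.max_missing_per_sample > len(panel):
        raise ValueError("max_missing_per_sample exceeds panel size")
    records = cohort.records.copy()
    if config.missing_rate == 0 and inject_fully_missing == 0:
        return CohortTable(records, dict(cohort.provenance))
    rng = np.random.default_rng([config.seed, 77])  # decoupled from cohort draw stream
    n, p = len(records), len(panel)
    rate = np.full(n, config.missing_rate)
    if config.missing_mechanism == "mar":
        rate[records["sample_type"].to_numpy() == "cord"] *= 2.0
    mask = rng.random((n, p)) < rate[:, None]
    # cap: keep at most max_missing_per_sample blanked cells per row,
    # chosen by random priority so the kept subset is unbiased
    priority = rng.random((n, p))
    priority[~mask] = np.inf
    order = np.argsort(priority, axis=1)
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(p)[None, :].repeat(n, axis=0), axis=1)
    mask &= rank < config.max_missing_per_sample
    if inject_fully_missing:
        mask[-inject_fully_missing:, :] = True
    values = records[list(panel.names)].to_numpy(dtype=float)
    values[mask] = np.nan
    records[list(panel.names)] = values
    prov = dict(cohort.provenance)
    prov["missingness"] = {
        "rate": config.missing_rate,
        "mechanism": config.missing_mechanism,
        "cap": config.max_missing_per_sample,
        "injected_fully_missing": inject_fully_missing,
    }
    return CohortTable(records, prov)
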