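"""Simulation configuration: cohort composition and analyte effect models.

Defaults reproduce the composition of a South-Asian facility-birth cohort
sampled for newborn screening: term-dominated gestational ages
(mean ~39.1 wk, SD ~1.5 wk, ~7% preterm), ~50/50 sex split, rare multiple
births, heel-prick collection ~15 h after birth versus cord collection at
birth, and sparse missingness (at most 5 of 47 analytes per sample).

Analyte effect defaults are calibration constants, not literature assay
values: they are fixed so that a refit full model (clinical + analytes +
interactions) attains a heel-prick RMSE of about one week at n = 5000,
with the fetal/adult hemoglobin ratio, TSH, 17-OHP, ALA, C5, C4DC and TYR
carrying the gestational-age signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .panel import AnalytePanel, default_panel


@dataclass(frozen=True)
class AnalyteEffect:
    """Linear mean model for one analyte.

    mean = intercept + ga_slope * (ga - 40) + age_slope * age_h
           + cord_shift * 1{cord sample};  value = max(mean + noise, 0).
    """

    intercept: float
    ga_slope: float = 0.0
    age_slope: float = 0.0
    noise_sd: float = 1.0
    cord_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def default_analyte_effects(panel: AnalytePanel | None = None) -> dict[str, AnalyteEffect]:
    """Default per-analyte effect models for the 47-analyte panel.

    Seven analytes carry gestational-age signal; the rest are pure noise
    at plausible concentration scales (amino acids in umol/L, short/long
    acylcarnitines in umol/L, hormones in assay units).
    """
    panel = panel or default_panel()
    strong = {
        # fetal/adult hemoglobin ratio: declines with GA and postnatal age
        "HBFA_RATIO": AnalyteEffect(4.0, -0.40, -0.004, 1.0, 0.10),
        # TSH: early postnatal surge -> heel (age~15h) means exceed cord
        "TSH": AnalyteEffect(8.0, -1.0, 0.25, 4.4, -1.0),
        "OHP17": AnalyteEffect(15.0, -2.0, -0.05, 12.5, 2.0),
        "ALA": AnalyteEffect(300.0, 10.0, 1.0, 100.0, 10.0),
        "C5": AnalyteEffect(0.12, -0.005, 0.0005, 0.05, 0.0),
        "C4DC": AnalyteEffect(0.30, 0.015, 0.0, 0.15, 0.01),
        "TYR": AnalyteEffect(120.0, 8.0, 0.5, 80.0, 5.0),
    }
    scale_by_group = {
        "amino_acid": (150.0, 40.0),
        "acylcarnitine": (0.20, 0.06),
        "endocrine": (10.0, 3.0),
        "hemoglobin": (2.0, 0.5),
        "enzyme": (50.0, 15.0),
        "other": (20.0, 7.0),
    }
    special = {"C0": (13.0, 4.0), "C2": (25.0, 8.0)}
    effects: dict[str, AnalyteEffect] = {}
    for name in panel:
        if name in strong:
            effects[name] = strong[name]
        else:
            mu, sd = special.get(name, scale_by_group[panel.group(name)])
            effects[name] = AnalyteEffect(mu, 0.0, 0.0, sd, 0.0)
    return effects


@dataclass
class SimulationConfig:
    """Full parameterization of a simulated newborn-screening cohort."""

    n_infants: int = 1000
    ga_mean_weeks: float = 39.1
    ga_sd_weeks: float = 1.5
    preterm_target_fraction: float = 0.07
    sex_male_fraction: float = 0.505
    multiple_birth_fraction: float = 0.016
    birthweight_term_mean_g: float = 2880.0
    birthweight_term_sd_g: float = 393.0
    birthweight_preterm_mean_g: float = 2300.0
    birthweight_preterm_sd_g: float = 540.0
    heel_collection_mean_h: float = 15.0
    heel_collection_sd_h: float = 6.5
    cord_collection_mean_h: float = 0.06
    cord_collection_sd_h: float = 0.25
    paired_fraction: float = 0.425
    heel_only_fraction: float = 0.031
    analyte_effects: dict[str, AnalyteEffect] = field(default_factory=default_analyte_effects)
    correlation_strength: float = 0.3
    missing_rate: float = 0.0013
    max_missing_per_sample: int = 5
    missing_mechanism: str = "mcar"  # or "mar" (rate doubled for cord samples)
    seed: int = 0
    panel: AnalytePanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        props = {
            "preterm_target_fraction": self.preterm_target_fraction,
            "sex_male_fraction": self.sex_male_fraction,
            "multiple_birth_fraction": self.multiple_birth_fraction,
            "paired_fraction": self.paired_fraction,
            "heel_only_fraction": self.heel_only_fraction,
            "missing_rate": self.missing_rate,
            "correlation_strength": self.correlation_strength,
        }
        for name, p in props.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.paired_fraction + self.heel_only_fraction > 1.0:
            raise ValueError("paired_fraction + heel_only_fraction must be <= 1")
        sds = {
            "ga_sd_weeks": self.ga_sd_weeks,
            "birthweight_term_sd_g": self.birthweight_term_sd_g,
            "birthweight_preterm_sd_g": self.birthweight_preterm_sd_g,
            "heel_collection_sd_h": self.heel_collection_sd_h,
            "cord_collection_sd_h": self.cord_collection_sd_h,
        }
        for name, sd in sds.items():
            if sd <= 0:
                raise ValueError(f"{name} must be > 0, got {sd}")
        if self.n_infants < 0:
            raise ValueError("n_infants must be >= 0")
        if self.max_missing_per_sample > len(self.panel):
            raise ValueError(
                f"max_missing_per_sample ({self.max_missing_per_sample}) exceeds "
                f"panel size ({len(self.panel)})"
            )
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar'")
        unknown = set(self.analyte_effects) - set(self.panel.names)
        if unknown:
            raise ValueError(f"effects given for analytes not on the panel: {sorted(unknown)}")
        missing = set(self.panel.names) - set(self.analyte_effects)
        if missing:
            raise ValueError(f"no effect model for panel analytes: {sorted(missing)}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyte_effects"] = {
            name: [e.intercept, e.ga_slope, e.age_slope, e.noise_sd, e.cord_shift]
            for name, e in self.analyte_effects.items()
        }
        d["panel"] = {"names": list(self.panel.names), "groups": dict(self.panel.groups)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "panel" in d:
            p = d["panel"]
            d["panel"] = AnalytePanel(names=tuple(p["names"]), groups=dict(p["groups"]))
        if "analyte_effects" in d:
            d["analyte_effects"] = {
                name: AnalyteEffect(*vals) if not isinstance(vals, AnalyteEffect) else vals
                for name, vals in d["analyte_effects"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
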