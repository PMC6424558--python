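"""End-to-end orchestration: simulate -> screen -> impute -> fit -> score ->
(optionally recalibrate) -> validate -> report.

A development cohort is simulated and used to fit the three-model hierarchy
separately for heel-prick and cord samples; an independently simulated
external cohort is screened, multiply imputed, scored per imputation, and
summarized into cohort-characteristics, accuracy, and discrimination
reports.  A single master seed is fanned out to per-stage child seeds via
``numpy.random.SeedSequence([master, stage_index])``, so stages are
isolated but globally reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .config import SimulationConfig
from .impute import impute_missing, screen_samples
from .metrics import pooled_roc_auc, residual_table, stratified_report, summarize_cohort
from .models import GAEstimator, predict_ga, recalibrate
from .reference import ReferenceChart, default_reference_chart
from .simulate import CohortTable, apply_missingness, birthweight_model_params, simulate_cohort

log = logging.getLogger("gestage")

STAGES = ("simulate_train", "simulate_external", "screen", "impute", "fit", "score", "validate")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed (below 2**31)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(master), idx]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Run-level configuration: two simulation configs plus analysis knobs."""

    training: SimulationConfig
    external: SimulationConfig
    seed: int = 0
    m_imputations: int = 10
    models: tuple[int, ...] = (1, 2, 3)
    sample_types: tuple[str, ...] = ("heel", "cord")
    interactions: str = "strong"
    recalibrate: bool = False
    inject_fully_missing: int = 1
    cv_folds: int = 10

    @classmethod
    def default(cls, seed: int = 0, n_train: int = 5000, n_external: int = 1500) -> "PipelineConfig":
        train = SimulationConfig(n_infants=n_train, seed=stage_seed(seed, "simulate_train"))
        ext = SimulationConfig(n_infants=n_external, seed=stage_seed(seed, "simulate_external"))
        return cls(training=train, external=ext, seed=seed)

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "m_imputations": self.m_imputations,
            "models": list(self.models),
            "sample_types": list(self.sample_types),
            "interactions": self.interactions,
            "recalibrate": self.recalibrate,
            "inject_fully_missing": self.inject_fully_missing,
            "cv_folds": self.cv_folds,
            "training": self.training.to_dict(),
            "external": self.external.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(
            training=SimulationConfig.from_dict(d["training"]),
            external=SimulationConfig.from_dict(d["external"]),
            seed=d.get("seed", 0),
            m_imputations=d.get("m_imputations", 10),
            models=tuple(d.get("models", (1, 2, 3))),
            sample_types=tuple(d.get("sample_types", ("heel", "cord"))),
            interactions=d.get("interactions", "strong"),
            recalibrate=d.get("recalibrate", False),
            inject_fully_missing=d.get("inject_fully_missing", 1),
            cv_folds=d.get("cv_folds", 10),
        )


@dataclass
class RunManifest:
    config_digest: str
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    version: str = "1.0"

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    fitted: dict  # (sample_type, model_id) -> GAEstimator
    estimates: dict  # (sample_type, model_id) -> GAEstimateSet
    reports: dict  # name -> DataFrame / dict
    chart: ReferenceChart


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256(
        json.dumps(
            {"train": config.training.to_dict(), "ext": config.external.to_dict(),
             "seed": config.seed, "m": config.m_imputations},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_digest=digest)
    manifest.seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    manifest_path = outdir / "manifest.json"

    def _stage(name: str):
        manifest.timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")
        log.info("stage=%s starting", name)

    def _fail(name: str, exc: Exception):
        manifest.stage_status[name] = f"failed: {exc}"
        manifest.save(manifest_path)
        raise RuntimeError(f"pipeline stage {name!r} failed") from exc

    try:
        _stage("simulate_train")
        train = simulate_cohort(config.training)
        gio.write_cohort(train, outdir / "training_cohort.csv")
        manifest.outputs["training_cohort"] = str(outdir / "training_cohort.csv")
        manifest.stage_status["simulate_train"] = "ok"
    except Exception as e:  # noqa: BLE001
        _fail("simulate_train", e)

    try:
        _stage("simulate_external")
        external = simulate_cohort(config.external)
        external = apply_missingness(
            external, config.external, inject_fully_missing=config.inject_fully_missing
        )
        gio.write_cohort(external, outdir / "external_cohort.csv")
        manifest.outputs["external_cohort"] = str(outdir / "external_cohort.csv")
        manifest.stage_status["simulate_external"] = "ok"
    except Exception as e:  # noqa: BLE001
        _fail("simulate_external", e)

    try:
        _stage("screen")
        screening = screen_samples(external, panel=config.external.panel)
        kept = external.records[external.records["sample_id"].isin(screening.kept)].reset_index(
            drop=True
        )
        manifest.stage_status["screen"] = (
            f"ok: kept {len(screening.kept)}, excluded {len(screening.excluded)}"
        )
    except Exception as e:  # noqa: BLE001
        _fail("screen", e)

    try:
        _stage("impute")
        imp_set = impute_missing(
            kept, m=config.m_imputations, seed=manifest.seeds["impute"],
            panel=config.external.panel,
        )
        manifest.stage_status["impute"] = f"ok: m={imp_set.m}"
    except Exception as e:  # noqa: BLE001
        _fail("impute", e)

    chart = default_reference_chart(birthweight_model_params(config.external))
    chart.to_csv(outdir / "reference_chart.csv")
    manifest.outputs["reference_chart"] = str(outdir / "reference_chart.csv")

    fitted: dict = {}
    estimates: dict = {}
    reports: dict = {}
    try:
        _stage("fit")
        for stype in config.sample_types:
            rows = train.records[train.records["sample_type"] == stype]
            for mid in config.models:
                est = GAEstimator(
                    model=mid,
                    analytes=tuple(config.training.panel.names) if mid > 1 else None,
                    interactions=config.interactions,
                    cv=config.cv_folds,
                    random_state=manifest.seeds["fit"] + mid,
                ).fit(rows, rows["ga_obs_weeks"].to_numpy())
                fitted[(stype, mid)] = est
                path = outdir / f"model_{stype}_{mid}.json"
                est.to_json(path)
                manifest.outputs[f"model_{stype}_{mid}"] = str(path)
        manifest.stage_status["fit"] = "ok"
    except Exception as e:  # noqa: BLE001
        _fail("fit", e)

    try:
        _stage("score")
        for stype in config.sample_types:
            masks = [c["sample_type"] == stype for c in imp_set.copies]
            sub_copies = [c[m].reset_index(drop=True) for c, m in zip(imp_set.copies, masks)]
            from .impute import ImputationSet

            sub = ImputationSet(sub_copies, imp_set.seed, imp_set.method)
            for mid in config.models:
                ests = predict_ga(fitted[(stype, mid)], sub)
                if config.recalibrate:
                    ests = recalibrate(ests).adjusted
                estimates[(stype, mid)] = ests
                gio.write_estimates(ests, outdir / f"estimates_{stype}_{mid}.csv")
                manifest.outputs[f"estimates_{stype}_{mid}"] = str(
                    outdir / f"estimates_{stype}_{mid}.csv"
                )
        manifest.stage_status["score"] = "ok"
    except Exception as e:  # noqa: BLE001
        _fail("score", e)

    try:
        _stage("validate")
        summary = summarize_cohort(kept)
        with open(outdir / "cohort_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, default=float)
        reports["cohort_summary"] = summary

        acc_frames, auc_rows, resid_frames = [], [], []
        for (stype, mid), ests in estimates.items():
            rep = stratified_report(ests, kept, chart)
            rep.insert(0, "sample_type", stype)
            acc_frames.append(rep)
            roc = pooled_roc_auc(ests)
            auc_rows.append(
                {
                    "sample_type": stype,
                    "model": mid,
                    "auc": round(roc.auc, 3),
                    "ci_lower": round(roc.ci_lower, 3),
                    "ci_upper": round(roc.ci_upper, 3),
                }
            )
            rows, cat_means = residual_table(ests)
            rows.insert(0, "sample_type", stype)
            rows.insert(1, "model", mid)
            resid_frames.append(rows)
        accuracy = pd.concat(acc_frames, ignore_index=True)
        accuracy["rmse_weeks"] = accuracy["rmse_weeks"].round(2)
        auc_table = pd.DataFrame(auc_rows)
        residuals = pd.concat(resid_frames, ignore_index=True)
        accuracy.to_csv(outdir / "accuracy_report.csv", index=False)
        auc_table.to_csv(outdir / "auc_report.csv", index=False)
        residuals.to_csv(outdir / "residuals.csv", index=False, float_format="%.10g")
        for key in ("accuracy_report", "auc_report", "residuals"):
            manifest.outputs[key] = str(outdir / f"{key}.csv")
        reports["accuracy"] = accuracy
        reports["auc"] = auc_table
        reports["residuals"] = residuals
        manifest.stage_status["validate"] = "ok"
    except Exception as e:  # noqa: BLE001
        _fail("validate", e)

    manifest.save(manifest_path)
    return PipelineResult(manifest, fitted, estimates, reports, chart)
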