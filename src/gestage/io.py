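"""Delimited-text readers/writers for cohorts and estimate tables.

Cohorts are comma-separated UTF-8 with a header row, one row per sample:
``infant_id, sample_id, sample_type, sex, multiple_birth, birthweight_g,
ga_obs_weeks, age_at_collection_h`` followed by one column per panel
analyte.  Missing analyte values are encoded as empty fields.
"""

from __future__ import annotations

import json

import pandas as pd

from .panel import AnalytePanel, default_panel
from .simulate import CLINICAL_COLUMNS, CohortTable

_FLOAT_FMT = "%.10g"


def write_cohort(cohort: CohortTable | pd.DataFrame, path, provenance_path=None) -> None:
    records = cohort.records if isinstance(cohort, CohortTable) else cohort
    records.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")
    if provenance_path is not None and isinstance(cohort, CohortTable):
        with open(provenance_path, "w", encoding="utf-8") as fh:
            json.dump(cohort.provenance, fh, indent=1)


def read_cohort(path, panel: AnalytePanel | None = None) -> pd.DataFrame:
    panel = panel or default_panel()
    df = pd.read_csv(path, dtype={"infant_id": str, "sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required columns: {missing}")
    absent = [a for a in panel.names if a not in df.columns]
    if absent:
        raise ValueError(f"cohort file {path} lacks panel analyte columns: {absent}")
    return df


def write_estimates(estimates, path) -> None:
    estimates.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_imputation_set(imp_set, directory, prefix: str = "imputed") -> list[str]:
    """Persist m completed copies plus a manifest; returns written paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, copy in enumerate(imp_set.copies, start=1):
        p = directory / f"{prefix}_{k:02d}.csv"
        copy.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths.append(str(p))
    manifest = {
        "m": imp_set.m,
        "seed": imp_set.seed,
        "method": imp_set.method,
        "files": paths,
    }
    with open(directory / f"{prefix}_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return paths
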