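"""Birthweight-for-gestational-age reference charts and SGA classification.

SGA10 / SGA3 flag infants whose birthweight falls strictly below the 10th /
3rd percentile of a reference birthweight distribution within categories of
completed gestational week and infant sex.  The default chart is a
parametric Gaussian family (location linear in gestational week, constant
scale, fixed male-female offset); the delimited-text chart format lets
users substitute any population reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHART_COLUMNS = ["sex", "ga_week", "location_g", "scale_g", "p03_g", "p10_g", "p50_g", "p90_g"]
PERCENTILES = {"p03_g": 0.03, "p10_g": 0.10, "p50_g": 0.50, "p90_g": 0.90}
DEFAULT_WEEKS = range(24, 44)  # completed weeks 24..43


@dataclass
class ReferenceChart:
    """Percentile rows keyed by (sex, completed GA week)."""

    table: pd.DataFrame  # columns CHART_COLUMNS, one row per (sex, week)

    def __post_init__(self) -> None:
        t = self.table
        missing = set(CHART_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"chart missing columns: {sorted(missing)}")
        if t.duplicated(["sex", "ga_week"]).any():
            raise ValueError("duplicate (sex, ga_week) rows")
        q = t[["p03_g", "p10_g", "p50_g", "p90_g"]].to_numpy()
        if not (np.diff(q, axis=1) > 0).all():
            raise ValueError("percentile rows must be strictly increasing (P3 < P10 < P50 < P90)")
        weeks = np.sort(t["ga_week"].unique())
        if len(weeks) and not np.array_equal(weeks, np.arange(weeks[0], weeks[-1] + 1)):
            raise ValueError("covered GA weeks must be contiguous")
        for wk in weeks:
            if set(t.loc[t["ga_week"] == wk, "sex"]) != {"male", "female"}:
                raise ValueError(f"both sexes required for week {wk}")
        self._index = t.set_index(["sex", "ga_week"])

    @property
    def weeks(self) -> tuple[int, int]:
        w = self.table["ga_week"]
        return int(w.min()), int(w.max())

    def row(self, sex: str, week: int) -> pd.Series:
        try:
            return self._index.loc[(sex, week)]
        except KeyError:
            lo, hi = self.weeks
            raise KeyError(
                f"gestational week {week} outside chart coverage [{lo}, {hi}] for sex={sex!r}"
            ) from None

    def to_csv(self, path) -> None:
        self.table[CHART_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceChart":
        return cls(pd.read_csv(path))


def build_reference_chart(
    params: dict[str, dict[str, float]],
    weeks=DEFAULT_WEEKS,
) -> ReferenceChart:
    """Build a Gaussian-family chart from per-sex location/scale parameters.

    ``params[sex]`` must provide ``location_at_40_g``, ``slope_g_per_week``
    and ``scale_g``; location at completed week w is evaluated at mid-week
    (w + 0.5).
    """
    rows = []
    for sex in ("female", "male"):
        p = params[sex]
        for wk in weeks:
            loc = p["location_at_40_g"] + p["slope_g_per_week"] * (wk + 0.5 - 40.0)
            scale = p["scale_g"]
            row = {"sex": sex, "ga_week": int(wk), "location_g": loc, "scale_g": scale}
            for col, q in PERCENTILES.items():
                row[col] = stats.norm.ppf(q, loc=loc, scale=scale)
            rows.append(row)
    return ReferenceChart(pd.DataFrame(rows, columns=CHART_COLUMNS))


def default_reference_chart(bw_params: dict | None = None) -> ReferenceChart:
    """Default chart matched to the cohort simulator's birthweight model.

    ``bw_params`` is the output of :func:`gestage.simulate.birthweight_model_params`;
    omitted, the defaults of :class:`~gestage.config.SimulationConfig` are used.
    """
    if bw_params is None:
        from .config import SimulationConfig
        from .simulate import birthweight_model_params

        bw_params = birthweight_model_params(SimulationConfig(n_infants=0))
    anchor = bw_params["ga_anchor_weeks"]
    off = bw_params["sex_offset_g"] / 2.0
    params = {
        sex: {
            "location_at_40_g": bw_params["mean_at_anchor_g"]
            + bw_params["slope_g_per_week"] * (40.0 - anchor)
            + (off if sex == "male" else -off),
            "slope_g_per_week": bw_params["slope_g_per_week"],
            "scale_g": bw_params["resid_sd_g"],
        }
        for sex in ("female", "male")
    }
    return build_reference_chart(params)


def classify_sga(birthweight_g, ga_obs_weeks, sex, chart: ReferenceChart, cut: str = "P10"):
    """Flag birthweights strictly below the cut percentile for (sex,
    completed week).  ``cut`` is ``"P10"`` or ``"P3"``; vectorized."""
    col = {"P10": "p10_g", "P3": "p03_g"}.get(cut)
    if col is None:
        raise ValueError(f"cut must be 'P10' or 'P3', got {cut!r}")
    bw = np.atleast_1d(np.asarray(birthweight_g, dtype=float))
    ga = np.atleast_1d(np.asarray(ga_obs_weeks, dtype=float))
    sx = np.atleast_1d(np.asarray(sex, dtype=object))
    out = np.zeros(len(bw), dtype=bool)
    for i in range(len(bw)):
        week = int(np.floor(ga[i]))
        out[i] = bw[i] < chart.row(str(sx[i]), week)[col]
    return out if np.ndim(birthweight_g) else bool(out[0])


def simulate_from_chart(
    chart: ReferenceChart, n: int, seed: int, week_range: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Draw (sex, completed week, birthweight) directly from a Gaussian
    chart's location/scale rows — a self-consistency harness for percentile
    rate recovery."""
    rng = np.random.default_rng(seed)
    lo, hi = week_range or chart.weeks
    weeks = rng.integers(lo, hi + 1, size=n)
    sexes = np.where(rng.random(n) < 0.5, "male", "female")
    loc = np.empty(n)
    scale = np.empty(n)
    for i in range(n):
        row = chart.row(str(sexes[i]), int(weeks[i]))
        loc[i], scale[i] = row["location_g"], row["scale_g"]
    bw = rng.normal(loc, scale)
    return pd.DataFrame(
        {"sex": sexes, "ga_obs_weeks": weeks + 0.5, "birthweight_g": bw}
    )
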