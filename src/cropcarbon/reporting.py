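"""Presentation surfaces: tidy summary tables and optional plots.

Aggregates scenario results the way the analysis presents them:
cropland area by tillage x cover technology class (C_F, C_NonLgm,
C_Lgm, N_F, N_NonLgm, N_Lgm), production by crop, and LUC emissions per
region and globally, per period and cumulative.  Summaries are pure
functions of the scenario results; rendering never changes numbers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .landsim import GLOBAL, ScenarioResult
from .technologies import ManagementTechnology

TECH_CLASSES = ("C_F", "C_NonLgm", "C_Lgm", "N_F", "N_NonLgm", "N_Lgm")


def _check_same_grid(results: list[ScenarioResult]) -> None:
    periods = [tuple(sorted(r.areas.period.unique())) for r in results]
    crops = [tuple(sorted(r.areas.crop.unique())) for r in results]
    if len(set(periods)) > 1 or len(set(crops)) > 1:
        raise ValueError("scenario results do not share a common grid")


def summarize(*results: ScenarioResult) -> pd.DataFrame:
    """Build one long summary table over one or more scenario runs.

    Columns: metric, region, scenario, period, value, units, plus a
    ``group`` column carrying the technology class or crop where the
    metric is grouped.
    """
    if not results:
        raise ValueError("need at least one scenario result")
    _check_same_grid(list(results))

    rows = []
    for res in results:
        name = res.scenario.name
        areas = res.areas.copy()
        us = areas[areas.region != GLOBAL].copy()
        cls = []
        for tech in us.technology:
            if tech == "aggregate":
                cls.append("aggregate")
            else:
                cls.append(ManagementTechnology.from_code(tech).class_label)
        us["group"] = cls
        by_class = us.groupby(["region", "group", "period"], as_index=False).area.sum()
        for r in by_class.itertuples():
            rows.append(dict(metric="cropland_area_by_class", region=r.region,
                             scenario=name, group=r.group, period=r.period,
                             value=r.area, units="thousand km2"))
        prod = res.production.groupby(["region", "crop", "period"], as_index=False).production_mt.sum()
        for r in prod.itertuples():
            rows.append(dict(metric="production_by_crop", region=r.region,
                             scenario=name, group=r.crop, period=r.period,
                             value=r.production_mt, units="Mt"))
        for r in res.emissions.itertuples():
            rows.append(dict(metric=f"luc_emissions_{r.scope}", region=r.region,
                             scenario=name, group=r.scope, period=r.period,
                             value=r.emissions_gtco2, units="GtCO2"))
            rows.append(dict(metric=f"cumulative_luc_emissions_{r.scope}",
                             region=r.region, scenario=name, group=r.scope,
                             period=r.period, value=r.cumulative_gtco2,
                             units="GtCO2"))
    return pd.DataFrame(rows)


def render(summary: pd.DataFrame, fmt: str, outdir, metrics=None) -> list[Path]:
    """Write summary tables (fmt="table") or plots (fmt="plot").

    Returns the list of files written.  Numeric outputs are a pure
    function of the summary; rendering twice is idempotent.
    """
    if summary.empty:
        raise ValueError("summary is empty")
    if metrics is not None:
        if not list(metrics):
            raise ValueError("empty metric filter")
        summary = summary[summary.metric.isin(list(metrics))]
        if summary.empty:
            raise ValueError(f"no rows left after metric filter {list(metrics)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "table":
        for metric, group in summary.groupby("metric"):
            path = out / f"{metric}.csv"
            group.sort_values(["scenario", "region", "group", "period"]).to_csv(
                path, index=False
            )
            written.append(path)
    elif fmt == "plot":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric, group in summary.groupby("metric"):
            fig, ax = plt.subplots(figsize=(7, 4))
            for (scen, region, grp), sub in group.groupby(
                ["scenario", "region", "group"]
            ):
                ax.plot(sub.period, sub.value, label=f"{scen}/{region}/{grp}")
            ax.set_xlabel("period")
            ax.set_ylabel(f"{metric} ({group.units.iloc[0]})")
            ax.legend(fontsize=5, ncol=2)
            path = out / f"{metric}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    else:
        raise ValueError(f"unknown render format: {fmt!r}")
    return written
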