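"""Summarize scenario runs into tidy tables and plots.

Aggregates cropland by tillage x cover class (the C_F ... N_Lgm legend
of the scenario figures), production by crop, and LUC emissions per
region; tables go to scratch/report as CSV.
"""

import cropcarbon as cc

pipe = cc.run_pipeline(seed=1, scenarios={
    k: v for k, v in cc.scenario_presets().items() if k in ("REF", "CCPL")
})
summary = cc.summarize(*pipe.results.values())

classes = summary.query(
    "metric == 'cropland_area_by_class' and region == 'US' and period == 2100"
).pivot(index="group", columns="scenario", values="value")
print("US cropland by technology class in 2100 (thousand km2):")
print(classes.round(1))

files = cc.render(summary, "table", "scratch/report")
print(f"\nwrote {len(files)} summary tables to scratch/report/")
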