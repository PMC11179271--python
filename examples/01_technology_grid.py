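"""Enumerate the factorial management-technology grid and a study design.

Each crop can be grown under 2 water x 2 fertilizer x 2 tillage x 3
cover-crop options = 24 technologies; crossing the 30 basin-crop
systems of the reference design with their crop's grid gives the 720
run specifications of the study.
"""

import cropcarbon as cc

techs = cc.enumerate_technologies("corn")
print(f"corn technologies: {len(techs)}")
print("first four:", ", ".join(t.code for t in techs[:4]))

nl = cc.ManagementTechnology("wheat", "RFD", "hi", "N", "Lgm")
print(f"{nl.code}: conservation={nl.is_conservation}, "
      f"reference={nl.reference().code}")

design = cc.default_study_design()
runs = cc.enumerate_runs(design)
print(f"study design: {len(design)} basin-crop systems -> {len(runs)} runs")
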