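"""Simulate a hierarchical spore population and print its description line.

Draws the C. mediterraneensis preset (17 collections x 10 basidiomes x
5 spores), pushes every spore through rasterization, contour extraction and
measurement, and prints "(min) mean ± SD (max)" summaries over collection
means in the standard sporological notation: [n/m/p] = n spores from m
basidiomes of p collections.
"""

from sporemorph import format_summary, load_preset, summarize_by_collection
from sporemorph.pipeline import measure_population

cfg = load_preset("mediterraneensis", seed=1)
df = measure_population(cfg, scale_um_per_px=0.05)

for var, unit in [("L_um", "μm"), ("W_um", "μm"), ("Q", ""), ("apV_um3", "μm³"),
                  ("depression_pct", "%")]:
    s = summarize_by_collection(df, var)
    print(f"{var:15s} {format_summary(s, unit=unit)}")
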