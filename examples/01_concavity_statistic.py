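"""Measure the suprahilar depression of synthetic spore silhouettes.

Builds one silhouette per species at its published mean dimensions and
prints the convex-hull concavity statistic: the percentage of the hull's
area not covered by the spore.  Values above 3% mark the pronounced
depression typical of C. pulverulentus; below 2.5% the shallow regime of
C. mediterraneensis.
"""

from sporemorph import (
    measure_contour,
    mediterraneensis_like,
    poikilochromus_like,
    pulverulentus_like,
)

for maker in (pulverulentus_like, mediterraneensis_like, poikilochromus_like):
    g = measure_contour(maker())
    print(
        f"{maker.__name__:24s} L={g.L_um:5.2f} µm  W={g.W_um:4.2f} µm  "
        f"A={g.shape_area_um2:5.2f} µm²  depression={g.depression_pct:4.2f}% of hull"
    )
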