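"""Run the quantitative microscopy key on collection-average features.

The key uses average spore width and length, the dominant side-view shape,
the suprahilar-depression percentage, and gloeocystidia abundance.  Inputs
falling in the key's own numeric gaps (width exactly 5 µm, depression
between 2.5 and 3%) stay indeterminate rather than being forced to a
species; the printed path lists the couplets traversed.
"""

from sporemorph import MicroFeatures, classify_microscopy

profiles = {
    "pulverulentus-average": MicroFeatures(4.87, 12.29, "narrowly_amygdaliform", 3.5, "sparse"),
    "mediterraneensis-average": MicroFeatures(5.33, 12.67, "narrowly_subamygdaliform", 1.8, "sparse"),
    "poikilochromus-average": MicroFeatures(5.03, 11.83, "ellipsoid_blunt", 1.0, "abundant"),
    "depression-gap": MicroFeatures(5.4, 12.6, "narrowly_subamygdaliform", 2.7, "sparse"),
}

for name, features in profiles.items():
    out = classify_microscopy(features)
    label = out.label if out.label != "indeterminate" else (
        "indeterminate {" + ", ".join(sorted(out.candidates)) + "}"
    )
    print(f"{name:26s} -> {label:45s} path {out.path_string}")
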