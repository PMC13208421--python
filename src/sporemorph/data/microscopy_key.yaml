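# Quantitative microscopy key for Mediterranean Cyanoboletus, to be applied
# to mature basidiospores in side view only.  Thresholds are the printed
# ones; the key's own gaps (width exactly 5 µm, depression between 2.5 and
# 3 % of hull area, the 12.0-12.5 µm length overlap at couplet 4) are
# deliberately preserved: inputs falling in a gap are indeterminate.
version: 1
thresholds:
  width_split_um: 5.0
  length_long_um: 12.5
  length_min_um: 12.0
  depression_pronounced_pct: 3.0
  depression_shallow_pct: 2.5
couplets:
  1:
    a: {test: "avg_width_um < width_split_um", goto: 2}
    b: {test: "avg_width_um > width_split_um", goto: 4}
  2:
    a: {test: "avg_length_um > length_long_um", label: pulverulentus}
    b: {test: "avg_length_um < length_long_um", goto: 3}
  3:
    a:
      test: "dominant_shape == ellipsoid_blunt and gloeocystidia == abundant"
      label: poikilochromus
    b:
      test: >-
        dominant_shape == narrowly_amygdaliform and
        depression_pct > depression_pronounced_pct and gloeocystidia == sparse
      label: pulverulentus
  4:
    a:
      test: >-
        avg_length_um < length_long_um and dominant_shape == ellipsoid_blunt
        and gloeocystidia == abundant
      label: poikilochromus
    b:
      test: >-
        avg_length_um > length_min_um and dominant_shape in
        (narrowly_subamygdaliform, narrowly_amygdaliform) and
        gloeocystidia == sparse
      goto: 5
  5:
    a: {test: "depression_pct > depression_pronounced_pct", label: pulverulentus}
    b: {test: "depression_pct < depression_shallow_pct", label: mediterraneensis}
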