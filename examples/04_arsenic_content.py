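"""Summarise the packaged per-sample arsenic table.

Prints per-species medians and ranges (mg As per kg dry basidiome), the
hyperaccumulation flag at the 50 mg/kg threshold, and the QC check of the
oyster-tissue reference material against its certified interval.
"""

from sporemorph import check_reference_material, load_reference_table, summarize_arsenic

for s in summarize_arsenic(load_reference_table()):
    print(s.display())

qc = check_reference_material(7.72)
print(
    f"\nQC {qc['label']}: measured {qc['measured']} vs certified "
    f"{qc['certified']} ± {qc['tolerance']} mg/kg -> {'pass' if qc['pass'] else 'FAIL'}"
)
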