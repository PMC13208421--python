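"""Site-category tally of an aligned FASTA file.

Classifies each column of the packaged toy alignment as constant,
parsimony-informative (>= 2 bases each in >= 2 sequences) or singleton,
treating gaps and ambiguity codes as missing, and prints the percentage of
informative characters — the per-locus statistic usually displayed beside
single-gene phylogenies.
"""

from dataclasses import asdict

from sporemorph import read_alignment, tally_sites, toy_alignment_path

counts = tally_sites(read_alignment(toy_alignment_path()))
for key, value in asdict(counts).items():
    print(f"{key}: {value}")
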