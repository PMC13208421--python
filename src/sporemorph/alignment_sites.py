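"""Alignment site-category tallies (variable / parsimony-informative /
singleton / constant).

Per column of an equal-length nucleotide alignment, gaps ('-', '.') and
IUPAC ambiguity codes (including N) count as missing.  A column is constant
when exactly one distinct resolved base occurs, variable with >= 2 distinct
resolved bases, parsimony-informative when >= 2 distinct bases are each
present in >= 2 sequences, and a singleton when variable but not
informative.  All-missing columns belong to none of these categories (they
still count toward the alignment length).  The headline percentage is
100 x informative / alignment length — the per-locus statistic usually
shown beside single-gene phylogenies.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

__all__ = ["SiteCounts", "tally_sites", "read_alignment", "toy_alignment_path"]

_RESOLVED = set("ACGT")
_MISSING = set("-.NRYSWKMBDHV")


@dataclass(frozen=True)
class SiteCounts:
    alignment_length: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    n_constant: int
    pct_parsimony_informative: float

    def __post_init__(self):
        if self.n_constant + self.n_variable > self.alignment_length:
            raise ValueError("category counts exceed alignment length")
        if self.n_singleton + self.n_parsimony_informative != self.n_variable:
            raise ValueError("singleton + informative must equal variable")
        if not (0.0 <= self.pct_parsimony_informative <= 100.0):
            raise ValueError("percentage outside [0, 100]")


def read_alignment(path) -> list[str]:
    """Sequences of an aligned FASTA file as uppercase strings."""
    aln = AlignIO.read(str(path), "fasta")
    return [str(rec.seq) for rec in aln]


def toy_alignment_path() -> Path:
    """Path of the packaged 4-sequence, 5-column toy alignment."""
    return Path(str(importlib.resources.files("sporemorph.data") / "toy_alignment.fasta"))


def tally_sites(alignment) -> SiteCounts:
    """Tally the site categories of an alignment.

    ``alignment`` is an iterable of equal-length nucleotide strings (or
    Biopython records); case-insensitive, U mapped to T.  Raises on unequal
    lengths or symbols outside the nucleotide/ambiguity/gap vocabulary.
    """
    seqs = [str(getattr(s, "seq", s)).upper().replace("U", "T") for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(seqs[0])
    if length == 0:
        raise ValueError("alignment length must be > 0")
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have equal length")
    offenders = sorted(
        {ch for s in seqs for ch in s if ch not in _RESOLVED | _MISSING}
    )
    if offenders:
        raise ValueError(f"non-nucleotide symbols in alignment: {offenders}")

    arr = np.array([list(s) for s in seqs])
    n_constant = n_variable = n_informative = n_singleton = 0
    for col in arr.T:
        bases = col[np.isin(col, list(_RESOLVED))]
        if bases.size == 0:
            continue  # all-missing column: uninformative, outside both counts
        uniq, counts = np.unique(bases, return_counts=True)
        if len(uniq) == 1:
            n_constant += 1
        else:
            n_variable += 1
            if np.sum(counts >= 2) >= 2:
                n_informative += 1
            else:
                n_singleton += 1
    return SiteCounts(
        alignment_length=length,
        n_variable=n_variable,
        n_parsimony_informative=n_informative,
        n_singleton=n_singleton,
        n_constant=n_constant,
        pct_parsimony_informative=100.0 * n_informative / length,
    )
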