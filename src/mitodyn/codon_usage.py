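"""Codon counting, relative synonymous codon usage (RSCU) and start/stop
codon census over the core protein-coding genes.

RSCU(c) = count(c) * k / sum of counts over c's synonymous family, where k
is the family size under genetic code 4 (TGA = Trp, so the Trp family is
{TGA, TGG} with k = 2).  Within any family with a nonzero total the mean
RSCU is exactly 1; single-codon families get RSCU 1 by convention and
empty families are reported as NaN.  Stop codons are counted but excluded
from RSCU.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._genetics import AA_TO_CODONS, CODON_TO_AA, FAMILY_SIZE, STOP_CODONS
from .genome_io import CodingSequence

ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product("TCAG", repeat=3))


@dataclass
class CodonUsageTable:
    species_id: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    rscu: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class StartStopCensus:
    #: (species_id, gene) -> (start_codon, stop_codon)
    entries: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)


def count_codons(cds_set: list[CodingSequence], species_id: str | None = None) -> CodonUsageTable:
    """Aggregate codon counts over a genome's coding sequences.

    CDS whose length is not divisible by 3 are skipped with a warning;
    codons containing N are excluded.  All codons including the terminal
    stop are counted (stops are later ignored by RSCU).
    """
    if species_id is None:
        species_id = cds_set[0].species_id if cds_set else "NA"
    table = CodonUsageTable(species_id)
    for cds in cds_set:
        seq = cds.spliced_seq
        if len(seq) % 3:
            warnings.warn(f"{cds.species_id}:{cds.gene_name}: length not divisible by 3, skipped")
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in table.counts:
                table.counts[codon] += 1
    return table


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill the RSCU map of a codon-usage table (in place; also returned)."""
    for aa, codons in AA_TO_CODONS.items():
        family_total = sum(table.counts[c] for c in codons)
        k = FAMILY_SIZE[aa]
        for c in codons:
            if family_total == 0:
                table.rscu[c] = math.nan
            elif k == 1:
                table.rscu[c] = 1.0
            else:
                table.rscu[c] = table.counts[c] * k / family_total
    return table


def census_start_stop(cds_set: list[CodingSequence]) -> StartStopCensus:
    census = StartStopCensus()
    for cds in cds_set:
        if len(cds.spliced_seq) < 6:
            warnings.warn(f"{cds.species_id}:{cds.gene_name}: CDS shorter than 6 nt, skipped")
            continue
        start = cds.spliced_seq[:3]
        last = cds.spliced_seq[len(cds.spliced_seq) - len(cds.spliced_seq) % 3 - 3:][:3]
        census.entries[(cds.species_id, cds.gene_name)] = (start, last)
    return census


def rscu_table(tables: list[CodonUsageTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for codon in ALL_CODONS:
            aa = CODON_TO_AA[codon]
            if codon in STOP_CODONS:
                continue
            rows.append({"species": t.species_id, "codon": codon, "aa": aa,
                         "count": t.counts[codon], "rscu": t.rscu.get(codon, math.nan)})
    return pd.DataFrame(rows, columns=["species", "codon", "aa", "count", "rscu"])


def census_table(census: StartStopCensus) -> pd.DataFrame:
    rows = [{"species": sp, "gene": g, "start_codon": s, "stop_codon": e}
            for (sp, g), (s, e) in sorted(census.entries.items())]
    return pd.DataFrame(rows, columns=["species", "gene", "start_codon", "stop_codon"])
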