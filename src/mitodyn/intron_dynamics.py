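"""Intron extraction, insertion-position mapping onto a reference species,
intron-position-set (IPS) clustering, and flanking-sequence profiling.

An intron's insertion position is expressed as ``local_pos``: the number
of coding (exonic) nucleotides of its host gene lying 5' of the intron.
Positions are projected onto a reference species through a codon-aware
protein alignment (nucleotide alignment for rRNA hosts), and introns of
the same gene whose reference positions form a single-linkage chain with
adjacent gaps of at most the tolerance (default 3 nt) are pooled into one
IPS.  An IPS present in two or more species is called shared; the phase
of a protein-gene intron is ``local_pos mod 3`` (0 = between codons).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from ._genetics import IUPAC_FROM_SET, reverse_complement
from .evol_rates import _aligned_proteins, _strip_stop, align_nucleotide
from .genome_io import (CORE_PCGS, CodingSequence, Feature, MitogenomeRecord,
                        extract_cds)

FLANK = 15


@dataclass
class IntronRecord:
    species_id: str
    host_gene: str
    ordinal: int               # 1-based index within the gene
    start: int
    end: int
    length: int
    local_pos: int
    phase: int | None          # 0/1/2 for protein hosts, None for rRNA
    flank_up: str
    flank_down: str
    dinucleotide_5p: str
    has_heg: bool
    ref_pos: int | None = None
    indirect: bool = False     # mapped via a non-reference species


@dataclass
class IPS:
    id: str
    gene: str
    ref_pos: int
    members: dict[str, list[IntronRecord]] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.members)

    @property
    def shared(self) -> bool:
        return self.n_species >= 2


@dataclass
class IpsCatalog:
    reference_species: str
    tolerance: int
    ips_list: list[IPS]

    @property
    def n_introns(self) -> int:
        return sum(len(v) for ips in self.ips_list for v in ips.members.values())

    def per_species_totals(self) -> dict[str, int]:
        totals: Counter = Counter()
        for ips in self.ips_list:
            for sp, members in ips.members.items():
                totals[sp] += len(members)
        return dict(totals)

    def presence_absence(self) -> pd.DataFrame:
        species = sorted({sp for ips in self.ips_list for sp in ips.members})
        rows = []
        for ips in sorted(self.ips_list, key=lambda x: (x.gene, x.ref_pos)):
            row = {"ips": ips.id, "gene": ips.gene, "ref_pos": ips.ref_pos,
                   "n_species": ips.n_species}
            for sp in species:
                row[sp] = int(sp in ips.members)
            rows.append(row)
        return pd.DataFrame(rows, columns=["ips", "gene", "ref_pos", "n_species"] + species)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_introns(record: MitogenomeRecord) -> list[IntronRecord]:
    """One IntronRecord per intron feature, ordered by host gene and
    transcript position."""
    out: list[IntronRecord] = []
    hegs = record.features_by("heg")
    host_genes = sorted({f.parent for f in record.features_by("intron") if f.parent})
    for gene in host_genes:
        host = record.get_gene(gene)
        if host is None:
            warnings.warn(f"{record.id}: intron with unresolvable parent {gene!r} skipped")
            continue
        cds = extract_cds(record, gene)
        introns = record.introns_of(gene)
        if host.strand == "-":
            introns = introns[::-1]  # transcript order
        if len(cds.exon_offsets) != len(introns):
            warnings.warn(f"{record.id}:{gene}: {len(introns)} intron features but "
                          f"{len(cds.exon_offsets)} join gaps; using feature spans")
        for ordinal, (feat, local_pos) in enumerate(zip(introns, cds.exon_offsets), start=1):
            out.append(_make_intron(record, cds, gene, ordinal, feat, local_pos, hegs))
    return out


def _make_intron(record: MitogenomeRecord, cds: CodingSequence, gene: str,
                 ordinal: int, feat: Feature, local_pos: int,
                 hegs: list[Feature]) -> IntronRecord:
    phase = local_pos % 3 if gene in CORE_PCGS else None
    up = cds.spliced_seq[max(0, local_pos - FLANK):local_pos]
    down = cds.spliced_seq[local_pos:local_pos + FLANK]
    if len(up) < FLANK or len(down) < FLANK:
        warnings.warn(f"{record.id}:{gene} intron {ordinal}: truncated flank at gene end")
    if feat.strand == "-":
        dinuc = reverse_complement(record.sequence[feat.end - 2:feat.end])
    else:
        dinuc = record.sequence[feat.start:feat.start + 2]
    has_heg = any(h.start < feat.end and h.end > feat.start for h in hegs)
    return IntronRecord(record.id, gene, ordinal, feat.start, feat.end,
                        feat.genomic_length, local_pos, phase, up, down,
                        dinuc, has_heg)


# ---------------------------------------------------------------------------
# Reference mapping
# ---------------------------------------------------------------------------

def map_to_reference(intron: IntronRecord, query_cds: CodingSequence,
                     ref_cds: CodingSequence, rrna_host: bool = False) -> int:
    """Project ``intron.local_pos`` onto the reference gene's coordinate
    system: the number of reference nucleotides aligned strictly 5' of
    the insertion point (positions inside a reference gap map to the
    nearest 5' reference nucleotide)."""
    if query_cds.species_id == ref_cds.species_id:
        return intron.local_pos
    if rrna_host:
        pairs = align_nucleotide(query_cds.spliced_seq, ref_cds.spliced_seq)
        q_nt = r_nt = 0
        for cq, cr in pairs:
            if q_nt == intron.local_pos and cq != "-":
                return r_nt
            if cq != "-":
                q_nt += 1
            if cr != "-":
                r_nt += 1
        return r_nt
    gq, gr = _aligned_proteins(_strip_stop(query_cds), _strip_stop(ref_cds))
    q_nt = r_nt = 0
    for cq, cr in zip(gq, gr):
        if cq != "-":
            if q_nt <= intron.local_pos < q_nt + 3:
                if cr != "-":
                    return r_nt + (intron.local_pos - q_nt)
                return r_nt
            q_nt += 3
        if cr != "-":
            r_nt += 3
    return r_nt


def map_all(introns: list[IntronRecord],
            cds_by_gene: dict[str, dict[str, CodingSequence]],
            reference_species: str) -> list[IntronRecord]:
    """Fill ``ref_pos`` for every intron.  When the host gene is missing
    in the reference, positions are mapped onto the alphabetically first
    species carrying the gene and flagged ``indirect``."""
    mapped = []
    for intron in introns:
        per_species = cds_by_gene.get(intron.host_gene, {})
        query = per_species.get(intron.species_id)
        if query is None:
            warnings.warn(f"{intron.species_id}:{intron.host_gene}: no CDS, intron skipped")
            continue
        rrna_host = intron.host_gene not in CORE_PCGS
        if reference_species in per_species:
            ref = per_species[reference_species]
            pos = map_to_reference(intron, query, ref, rrna_host)
            mapped.append(replace(intron, ref_pos=pos, indirect=False))
        else:
            fallback = sorted(per_species)[0]
            pos = map_to_reference(intron, query, per_species[fallback], rrna_host)
            warnings.warn(f"{intron.species_id}:{intron.host_gene}: host gene absent in "
                          f"reference; mapped via {fallback} (indirect)")
            mapped.append(replace(intron, ref_pos=pos, indirect=True))
    return mapped


# ---------------------------------------------------------------------------
# IPS clustering
# ---------------------------------------------------------------------------

def cluster_ips(introns: list[IntronRecord], tolerance: int = 3,
                reference_species: str = "") -> IpsCatalog:
    """Single-linkage clustering of mapped insertion positions per gene:
    adjacent positions at most ``tolerance`` nt apart join one IPS (so a
    chain 100-103-106 forms a single set).  The representative position
    is the reference species' own, falling back to the cluster minimum."""
    unmapped = [i for i in introns if i.ref_pos is None]
    if unmapped:
        raise ValueError(f"{len(unmapped)} introns lack ref_pos; run map_all first")
    by_gene: dict[str, list[IntronRecord]] = {}
    for i in introns:
        by_gene.setdefault(i.host_gene, []).append(i)
    ips_list: list[IPS] = []
    for gene in sorted(by_gene):
        members = sorted(by_gene[gene], key=lambda i: (i.ref_pos, i.species_id, i.ordinal))
        cluster: list[IntronRecord] = []
        for intron in members:
            if cluster and intron.ref_pos - cluster[-1].ref_pos > tolerance:
                ips_list.append(_build_ips(gene, cluster, reference_species))
                cluster = []
            cluster.append(intron)
        if cluster:
            ips_list.append(_build_ips(gene, cluster, reference_species))
    return IpsCatalog(reference_species, tolerance, ips_list)


def _build_ips(gene: str, cluster: list[IntronRecord], reference_species: str) -> IPS:
    ref_members = [i.ref_pos for i in cluster if i.species_id == reference_species]
    rep = min(ref_members) if ref_members else min(i.ref_pos for i in cluster)
    members: dict[str, list[IntronRecord]] = {}
    for i in cluster:
        members.setdefault(i.species_id, []).append(i)
    return IPS(f"{gene}-{rep}", gene, rep, members)


# ---------------------------------------------------------------------------
# Classification and profiling
# ---------------------------------------------------------------------------

def classify(catalog: IpsCatalog, bin_width: int = 500) -> dict:
    """Shared/specific partition plus per-gene counts, intron length
    histogram and per-species phase histogram."""
    shared = sum(1 for ips in catalog.ips_list if ips.shared)
    specific = sum(1 for ips in catalog.ips_list if not ips.shared)
    per_gene: Counter = Counter(ips.gene for ips in catalog.ips_list)
    lengths: Counter = Counter()
    phases: dict[str, Counter] = {}
    spectrum: Counter = Counter(ips.n_species for ips in catalog.ips_list)
    for ips in catalog.ips_list:
        for sp, members in ips.members.items():
            for m in members:
                lengths[(m.length // bin_width) * bin_width] += 1
                if m.phase is not None:
                    phases.setdefault(sp, Counter())[m.phase] += 1
    return {
        "n_ips": len(catalog.ips_list),
        "shared": shared,
        "specific": specific,
        "n_species_spectrum": dict(sorted(spectrum.items())),
        "per_gene": dict(sorted(per_gene.items())),
        "length_histogram": dict(sorted(lengths.items())),
        "phase_histogram": {sp: dict(sorted(c.items())) for sp, c in sorted(phases.items())},
    }


def flank_profile(members: list[IntronRecord], window: int = FLANK):
    """Position frequency matrix over the exonic sequence flanking the
    insertion site (-window..-1, +1..+window), a majority/IUPAC consensus,
    and the tally of intron 5' dinucleotides.

    Truncated flanks are padded with N, and N is excluded from each
    position's frequencies.
    """
    if not members:
        raise ValueError("flank_profile needs at least one intron")
    positions = list(range(-window, 0)) + list(range(1, window + 1))
    freq = pd.DataFrame(0.0, index=list("ACGT"), columns=positions)
    for m in members:
        up = m.flank_up.rjust(window, "N")[-window:]
        down = m.flank_down.ljust(window, "N")[:window]
        for pos, base in zip(positions, up + down):
            if base in "ACGT":
                freq.loc[base, pos] += 1
    consensus = []
    for pos in positions:
        col = freq[pos]
        total = col.sum()
        if total == 0:
            consensus.append("N")
            continue
        top = col[col == col.max()].index
        consensus.append(IUPAC_FROM_SET[frozenset(top)])
        freq[pos] = col / total
    dinucs = Counter(m.dinucleotide_5p for m in members)
    return freq, "".join(consensus), dict(dinucs)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def intron_table(introns: list[IntronRecord]) -> pd.DataFrame:
    rows = [{"species": i.species_id, "gene": i.host_gene, "ordinal": i.ordinal,
             "start": i.start, "end": i.end, "length": i.length,
             "local_pos": i.local_pos, "ref_pos": i.ref_pos,
             "phase": -1 if i.phase is None else i.phase,
             "dinucleotide_5p": i.dinucleotide_5p, "has_heg": int(i.has_heg),
             "indirect": int(i.indirect)} for i in introns]
    return pd.DataFrame(rows, columns=["species", "gene", "ordinal", "start", "end",
                                       "length", "local_pos", "ref_pos", "phase",
                                       "dinucleotide_5p", "has_heg", "indirect"])


def ips_table(catalog: IpsCatalog) -> pd.DataFrame:
    rows = []
    for ips in sorted(catalog.ips_list, key=lambda x: (x.gene, x.ref_pos)):
        rows.append({"ips": ips.id, "gene": ips.gene, "ref_pos": ips.ref_pos,
                     "n_species": ips.n_species, "shared": int(ips.shared),
                     "species": ",".join(sorted(ips.members))})
    return pd.DataFrame(rows, columns=["ips", "gene", "ref_pos", "n_species",
                                       "shared", "species"])
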