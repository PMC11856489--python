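"""Reading, writing and slicing annotated mitochondrial genome records.

The in-memory model is deliberately small: a :class:`MitogenomeRecord` is a
nucleotide string plus an ordered list of typed :class:`Feature` objects.
Coordinates are 0-based half-open internally; the GenBank convention
(1-based inclusive) applies only at the file boundary, where Biopython
handles the conversion.

Gene labels are normalized through an explicit synonym table so that the
same core gene annotated as ``ATP6``, ``atpase 6`` or ``atp 6`` in
different submissions maps to a single canonical name.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._genetics import START_CODONS, STOP_CODONS, reverse_complement, translate

CORE_PCGS: tuple[str, ...] = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
)
RRNAS: tuple[str, ...] = ("rnl", "rns")
#: the 17 markers used for gene-order comparison
ORDER_MARKERS: tuple[str, ...] = CORE_PCGS + RRNAS

CATEGORIES = ("core_pcg", "trna", "rrna", "un_orf", "heg", "intron")

# Synonym folding for gene labels seen across fungal mitogenome submissions.
# Keys are lowercase with spaces/underscores/hyphens stripped.
_SYNONYMS: dict[str, str] = {
    "atp6": "atp6", "atpase6": "atp6", "atp6ase": "atp6",
    "atp8": "atp8", "atpase8": "atp8",
    "atp9": "atp9", "atpase9": "atp9", "oli1": "atp9",
    "cob": "cob", "cytb": "cob", "cytochromeb": "cob", "cobb": "cob",
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "nad1": "nad1", "nd1": "nad1", "nadh1": "nad1",
    "nad2": "nad2", "nd2": "nad2", "nadh2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nadh3": "nad3",
    "nad4": "nad4", "nd4": "nad4", "nadh4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L", "nadh4l": "nad4L",
    "nad5": "nad5", "nd5": "nad5", "nadh5": "nad5",
    "nad6": "nad6", "nd6": "nad6", "nadh6": "nad6",
    "rps3": "rps3", "rps3gene": "rps3", "var1": "rps3",
    "rnl": "rnl", "rrnl": "rnl", "lrrna": "rnl", "lsu": "rnl", "23srrna": "rnl",
    "21srrna": "rnl", "largesubunitribosomalrna": "rnl",
    "rns": "rns", "rrns": "rns", "srrna": "rns", "ssu": "rns", "16srrna": "rns",
    "15srrna": "rns", "smallsubunitribosomalrna": "rns",
}

_HEG_PATTERN = re.compile(r"homing|endonuclease|laglidadg|giy", re.IGNORECASE)
_VALID_NT = frozenset("ACGTN")


def normalize_gene_name(label: str) -> str:
    """Fold a raw gene label onto its canonical name where recognized."""
    key = re.sub(r"[\s_\-\.]+", "", label.strip().lower())
    return _SYNONYMS.get(key, label.strip())


class Segment(NamedTuple):
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Feature:
    category: str
    gene_name: str
    segments: list[Segment]
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if not self.segments:
            raise ValueError(f"feature {self.gene_name!r} has no segments")

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    @property
    def start(self) -> int:
        return min(s.start for s in self.segments)

    @property
    def end(self) -> int:
        return max(s.end for s in self.segments)

    @property
    def genomic_length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass
class MitogenomeRecord:
    id: str
    organism: str
    topology: str  # 'circular' or 'linear'
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_by(self, *categories: str) -> list[Feature]:
        return [f for f in self.features if f.category in categories]

    def get_gene(self, gene_name: str) -> Feature | None:
        for f in self.features:
            if f.gene_name == gene_name and f.category != "intron":
                return f
        return None

    def introns_of(self, gene_name: str) -> list[Feature]:
        out = [f for f in self.features if f.category == "intron" and f.parent == gene_name]
        return sorted(out, key=lambda f: f.start)


@dataclass
class CodingSequence:
    gene_name: str
    species_id: str
    spliced_seq: str
    protein: str
    exon_offsets: list[int]
    complete: bool = True   # length divisible by 3 and no internal stop


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

def _segments_from_location(location) -> list[Segment]:
    parts = sorted(location.parts, key=lambda p: int(p.start))
    strand = "-" if (location.strand or 1) < 0 else "+"
    return [Segment(int(p.start), int(p.end), strand) for p in parts]


def _label_of(feat: SeqFeature) -> str:
    for key in ("gene", "label", "standard_name", "product", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return ""


def _classify_cds(name: str, product: str) -> tuple[str, str]:
    if _HEG_PATTERN.search(product) or _HEG_PATTERN.search(name or ""):
        return "heg", name or "heg"
    canonical = normalize_gene_name(name) if name else ""
    if canonical in CORE_PCGS:
        return "core_pcg", canonical
    return "un_orf", name or "orf"


def _join_gap_introns(segments: list[Segment], parent: str) -> list[Feature]:
    introns = []
    for a, b in zip(segments, segments[1:]):
        if b.start > a.end:
            introns.append(
                Feature("intron", f"{parent}-i", [Segment(a.end, b.start, a.strand)], parent=parent)
            )
    return introns


def read_genbank(path: str | Path, strict: bool = False) -> list[MitogenomeRecord]:
    """Parse a GenBank flat file into annotated mitogenome records.

    Feature labels are normalized via the synonym table; CDS features not
    matching a core gene become ``un_orf`` (or ``heg`` when the product
    mentions a homing endonuclease).  Introns are taken from explicit
    ``intron`` features when present, otherwise inferred from the gaps of
    ``join()`` CDS locations; when both exist and disagree a warning is
    emitted and the explicit annotation wins.

    With ``strict`` any malformed feature or non-ACGTN sequence character
    raises; otherwise problems produce a warning and the offending feature
    is skipped (ambiguity codes are mapped to N).
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id}: empty sequence")
        bad = set(seq) - _VALID_NT
        if bad:
            if strict:
                raise ValueError(f"record {rec.id}: ambiguity codes {sorted(bad)}")
            warnings.warn(f"record {rec.id}: mapping ambiguity codes {sorted(bad)} to N")
            seq = re.sub(f"[{''.join(re.escape(b) for b in bad)}]", "N", seq)

        topology = rec.annotations.get("topology", "linear")
        organism = rec.annotations.get("organism", rec.description)
        features: list[Feature] = []
        explicit_introns: list[Feature] = []
        inferred_introns: list[Feature] = []

        for feat in rec.features:
            if feat.type in ("source", "gene", "misc_feature"):
                continue
            try:
                segments = _segments_from_location(feat.location)
            except Exception as exc:  # malformed location
                if strict:
                    raise ValueError(f"record {rec.id}: bad location in {feat.type}: {exc}")
                warnings.warn(f"record {rec.id}: skipping {feat.type} with bad location")
                continue
            label = _label_of(feat)
            if feat.type == "CDS":
                product = str(feat.qualifiers.get("product", [""])[0])
                category, name = _classify_cds(label, product)
                parent = None
                if category == "heg":
                    note = str(feat.qualifiers.get("note", [""])[0])
                    m = re.search(r"within (\S+)", note)
                    parent = normalize_gene_name(m.group(1)) if m else None
                features.append(Feature(category, name, segments, parent=parent))
                if category in ("core_pcg", "un_orf"):
                    inferred_introns.extend(_join_gap_introns(segments, name))
            elif feat.type == "tRNA":
                features.append(Feature("trna", label or "trn", segments))
            elif feat.type == "rRNA":
                name = normalize_gene_name(label)
                if name not in RRNAS:
                    warnings.warn(f"record {rec.id}: unrecognized rRNA label {label!r}")
                features.append(Feature("rrna", name, segments))
                inferred_introns.extend(_join_gap_introns(segments, name))
            elif feat.type == "intron":
                parent = feat.qualifiers.get("gene", [label or None])[0]
                parent = normalize_gene_name(parent) if parent else None
                if parent is None:
                    if strict:
                        raise ValueError(f"record {rec.id}: intron without parent gene")
                    warnings.warn(f"record {rec.id}: intron without parent gene skipped")
                    continue
                explicit_introns.append(
                    Feature("intron", f"{parent}-i", segments, parent=parent)
                )

        if explicit_introns:
            inferred_spans = {(i.start, i.end, i.parent) for i in inferred_introns}
            explicit_spans = {(i.start, i.end, i.parent) for i in explicit_introns}
            if inferred_spans and inferred_spans != explicit_spans:
                warnings.warn(
                    f"record {rec.id}: explicit intron features disagree with "
                    f"join() gaps; using explicit annotation"
                )
            features.extend(explicit_introns)
        else:
            features.extend(inferred_introns)

        features.sort(key=lambda f: (f.start, f.end, f.category, f.gene_name))
        record = MitogenomeRecord(rec.id, organism, topology, seq, features)
        record = _unwrap_if_needed(record)
        records.append(record)
    return records


def _unwrap_if_needed(record: MitogenomeRecord) -> MitogenomeRecord:
    """Rotate a circular record so that no feature spans the origin."""
    wrap = [f for f in record.features if any(s.end > record.length for s in f.segments)]
    if not wrap or record.topology != "circular":
        return record
    offset = min(f.start for f in wrap)
    return rotate_record(record, offset)


def rotate_record(record: MitogenomeRecord, offset: int) -> MitogenomeRecord:
    """Rotate a circular genome so position ``offset`` becomes position 0."""
    n = record.length
    offset %= n
    seq = record.sequence[offset:] + record.sequence[:offset]
    feats = []
    for f in record.features:
        segs = []
        for s in f.segments:
            ns, ne = (s.start - offset) % n, (s.end - offset) % n or n
            if ns < ne:
                segs.append(Segment(ns, ne, s.strand))
            else:  # segment now spans the origin: split it
                segs.append(Segment(ns, n, s.strand))
                segs.append(Segment(0, ne, s.strand))
        feats.append(replace(f, segments=segs))
    feats.sort(key=lambda f: (f.start, f.end, f.category, f.gene_name))
    return replace(record, sequence=seq, features=feats)


# ---------------------------------------------------------------------------
# GenBank / FASTA writing
# ---------------------------------------------------------------------------

def _to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description=record.organism)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    rec.annotations["organism"] = record.organism
    rec.features.append(SeqFeature(SimpleLocation(0, record.length, 1), type="source",
                                   qualifiers={"organism": [record.organism]}))
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s.start, s.end, strand) for s in f.segments]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = {"core_pcg": "CDS", "un_orf": "CDS", "heg": "CDS",
                 "trna": "tRNA", "rrna": "rRNA", "intron": "intron"}[f.category]
        quals: dict[str, list[str]] = {"gene": [f.parent if f.category == "intron" and f.parent
                                                else f.gene_name]}
        if f.category == "heg":
            quals["product"] = ["homing endonuclease"]
            if f.parent:
                quals["note"] = [f"HEG within {f.parent}"]
        elif f.category == "un_orf":
            quals["product"] = ["hypothetical protein"]
        rec.features.append(SeqFeature(location, type=ftype, qualifiers=quals))
    return rec


def write_genbank(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    SeqIO.write([_to_seqrecord(r) for r in records], str(path), "genbank")


def write_fasta(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} {r.organism}\n")
            for i in range(0, r.length, 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> list[MitogenomeRecord]:
    """Read plain FASTA as feature-less linear records (sequence-only ops)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(MitogenomeRecord(rec.id, rec.description, "linear",
                                    str(rec.seq).upper(), []))
    return out


# ---------------------------------------------------------------------------
# CDS extraction and ORF finding
# ---------------------------------------------------------------------------

def extract_cds(record: MitogenomeRecord, gene: str,
                truncate_at_stop: bool = False) -> CodingSequence:
    """Splice the exons of ``gene`` and translate under genetic code 4.

    Exons are concatenated in transcript order (minus-strand genes are
    reverse-complemented, with genomic segment order reversed) and
    ``exon_offsets[i]`` records the number of coding nucleotides 5' of
    intron *i* — the quantity intron-position mapping runs on.
    """
    feat = record.get_gene(gene)
    if feat is None:
        raise KeyError(f"gene {gene!r} not annotated in {record.id}")
    segs = sorted(feat.segments, key=lambda s: s.start)
    if feat.strand == "-":
        segs = segs[::-1]
    pieces, offsets, acc = [], [], 0
    for i, s in enumerate(segs):
        raw = record.sequence[s.start:s.end]
        pieces.append(reverse_complement(raw) if s.strand == "-" else raw)
        acc += s.length
        if i < len(segs) - 1:
            offsets.append(acc)
    spliced = "".join(pieces)
    if feat.category in ("rrna", "trna"):  # RNA genes: no translation
        return CodingSequence(gene, record.id, spliced, "", offsets, True)
    protein = translate(spliced, to_stop=truncate_at_stop)
    complete = len(spliced) % 3 == 0 and "*" not in protein[:-1]
    if not complete:
        warnings.warn(f"{record.id}:{gene}: CDS flagged incomplete "
                      f"(len={len(spliced)}, frame or internal stop)")
    return CodingSequence(gene, record.id, spliced, protein, offsets, complete)


def find_orfs(record: MitogenomeRecord, min_aa: int) -> list[Feature]:
    """Find maximal ORFs on both strands under genetic code 4.

    Starts are ATG/TTG/GTG/TTA; stops TAA/TAG.  Spans overlapping an
    annotated gene by more than half the ORF length are dropped.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = record.length
    annotated = [(f.start, f.end) for f in record.features if f.category != "intron"]
    hits: list[Feature] = []
    for strand, seq in (("+", record.sequence), ("-", reverse_complement(record.sequence))):
        for frame in range(3):
            start_of_orf = None
            i = frame
            while i + 3 <= len(seq):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    if start_of_orf is not None:
                        _emit_orf(hits, start_of_orf, i + 3, strand, n, min_aa)
                        start_of_orf = None
                elif start_of_orf is None and codon in START_CODONS and "N" not in codon:
                    start_of_orf = i
                i += 3
    kept = []
    for orf in hits:
        ol = sum(max(0, min(orf.end, e) - max(orf.start, s)) for s, e in annotated)
        if ol <= 0.5 * orf.genomic_length:
            kept.append(orf)
    kept.sort(key=lambda f: (f.start, f.end))
    return kept


def _emit_orf(hits: list[Feature], start: int, end: int, strand: str,
              n: int, min_aa: int) -> None:
    aa_len = (end - start) // 3 - 1  # exclude the stop codon
    if aa_len < min_aa:
        return
    if strand == "+":
        g0, g1 = start, end
    else:  # coordinates on the reverse-complement map back
        g0, g1 = n - end, n - start
    hits.append(Feature("un_orf", f"orf{aa_len}", [Segment(g0, g1, strand)]))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_tables(df: pd.DataFrame, path: str | Path) -> None:
    """Write a stage result as a TSV with fixed column order, 4-decimal floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
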