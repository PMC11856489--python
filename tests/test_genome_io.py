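"""GenBank parsing, CDS extraction, ORF finding and table round trips."""

import numpy as np
import pandas as pd
import pytest

from mitodyn._genetics import reverse_complement
from mitodyn.genome_io import (MitogenomeRecord, Feature, Segment,
                               extract_cds, find_orfs, read_genbank,
                               normalize_gene_name, read_table,
                               rotate_record, write_genbank, write_tables)


def _record(seq, features, topology="linear", rid="R1"):
    return MitogenomeRecord(rid, "test", topology, seq, features)


class TestReadGenbank:
    def test_join_gap_becomes_intron(self, handwritten_genbank):
        rec = read_genbank(handwritten_genbank)[0]
        cox1 = rec.get_gene("cox1")
        assert cox1.category == "core_pcg"
        assert cox1.segments == [Segment(100, 300, "+"), Segment(1500, 1900, "+")]
        introns = rec.introns_of("cox1")
        assert len(introns) == 1
        assert (introns[0].start, introns[0].end) == (300, 1500)
        assert introns[0].parent == "cox1"

    def test_synonym_folding(self, handwritten_genbank):
        rec = read_genbank(handwritten_genbank)[0]
        nd4l = rec.get_gene("nad4L")
        assert nd4l is not None and nd4l.category == "core_pcg"
        assert rec.get_gene("rns").category == "rrna"
        assert any(f.category == "un_orf" for f in rec.features)
        assert any(f.category == "trna" and f.strand == "-" for f in rec.features)

    @pytest.mark.parametrize("raw,expected", [
        ("ATP6", "atp6"), ("atpase 6", "atp6"), ("ND1", "nad1"),
        ("cytb", "cob"), ("ND4L", "nad4L"), ("rrnL", "rnl"), ("CoX-1", "cox1"),
    ])
    def test_synonym_table(self, raw, expected):
        assert normalize_gene_name(raw) == expected


class TestExtractCds:
    def test_single_exon_plus(self):
        rec = _record("ATGTTA" + "A" * 10,
                      [Feature("core_pcg", "atp8", [Segment(0, 6, "+")])])
        cds = extract_cds(rec, "atp8")
        assert cds.spliced_seq == "ATGTTA"
        assert cds.protein == "ML"  # code 4: TTA = Leu
        assert cds.exon_offsets == []

    def test_two_exons_offset(self):
        rec = _record("ATG" + "C" * 7 + "TAA" + "G" * 5,
                      [Feature("core_pcg", "atp8",
                               [Segment(0, 3, "+"), Segment(10, 13, "+")]),
                       Feature("intron", "atp8-i", [Segment(3, 10, "+")], parent="atp8")])
        cds = extract_cds(rec, "atp8")
        assert cds.spliced_seq == "ATGTAA"
        assert cds.exon_offsets == [3]  # 3 coding nt precede the intron

    def test_minus_strand(self):
        rec = _record("TTACAT" + "G" * 6,
                      [Feature("core_pcg", "atp8", [Segment(0, 6, "-")])])
        assert extract_cds(rec, "atp8").spliced_seq == "ATGTAA"

    def test_minus_extraction_mirrors_plus(self, conserved7):
        """Extracting a minus-strand gene equals the plus extraction of
        the reverse-complemented record."""
        rec = conserved7[0][0]
        gene = "cox1"
        feat = rec.get_gene(gene)
        n = rec.length
        flipped_feats = []
        for f in rec.features:
            segs = [Segment(n - s.end, n - s.start, "-" if s.strand == "+" else "+")
                    for s in reversed(f.segments)]
            flipped_feats.append(Feature(f.category, f.gene_name, segs, parent=f.parent))
        flipped = _record(reverse_complement(rec.sequence), flipped_feats, rid=rec.id)
        assert extract_cds(flipped, gene).spliced_seq == extract_cds(rec, gene).spliced_seq

    def test_footprint_conservation(self, conserved7):
        """Spliced length + intron lengths equals the gene's genomic
        footprint for every intron-bearing gene."""
        for rec in conserved7[0]:
            for gene in {f.parent for f in rec.features_by("intron")}:
                cds = extract_cds(rec, gene)
                introns = rec.introns_of(gene)
                footprint = rec.get_gene(gene).genomic_length + sum(
                    i.genomic_length for i in introns)
                assert len(cds.spliced_seq) + sum(i.genomic_length for i in introns) \
                    == footprint


def _oracle_orfs(seq, min_aa):
    """Independent ORF oracle: per frame, split at stops, take the first
    start codon of each inter-stop region."""
    starts, stops = {"ATG", "TTG", "GTG", "TTA"}, {"TAA", "TAG"}
    found = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            codons = [(i, s[i:i + 3]) for i in range(frame, n - 2, 3)]
            region = []
            for i, c in codons:
                if c in stops:
                    firsts = [j for j, cc in region if cc in starts and "N" not in cc]
                    if firsts:
                        a, b = firsts[0], i + 3
                        if (b - a) // 3 - 1 >= min_aa:
                            if strand == "+":
                                found.add((a, b, "+"))
                            else:
                                found.add((n - b, n - a, "-"))
                    region = []
                else:
                    region.append((i, c))
    return found


class TestFindOrfs:
    def test_minimal_orf(self):
        rec = _record("ATGAAATAA", [])
        orfs = find_orfs(rec, min_aa=2)
        assert len(orfs) == 1
        assert orfs[0].segments[0] == Segment(0, 9, "+")

    def test_all_n(self):
        assert find_orfs(_record("N" * 300, []), min_aa=1) == []

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), p=[0.38, 0.125, 0.145, 0.35], size=10_000))
        rec = _record(seq, [])
        got = {(f.start, f.end, f.strand) for f in find_orfs(rec, min_aa=60)}
        assert got == _oracle_orfs(seq, 60)
        assert got  # the scan actually found something at this threshold

    def test_overlap_exclusion(self):
        seq = "ATGAAAAAAAAATAA" + "C" * 20
        gene = Feature("core_pcg", "atp8", [Segment(0, 15, "+")])
        assert find_orfs(_record(seq, [gene]), min_aa=2) == []


class TestRoundTrip:
    def test_genbank_round_trip_preserves_features(self, transposed, tmp_path):
        records, _ = transposed
        path = tmp_path / "cohort.gb"
        write_genbank(records, path)
        back = read_genbank(path)
        assert [r.id for r in back] == [r.id for r in records]
        for a, b in zip(records, back):
            assert a.sequence == b.sequence
            assert a.topology == b.topology
            key = lambda f: (f.category, f.gene_name, tuple(f.segments), f.parent)
            assert list(map(key, a.features)) == list(map(key, b.features))

    def test_rotation_preserves_feature_lengths(self, transposed):
        rec = transposed[0][0]
        rot = rotate_record(rec, 1234)
        assert rot.length == rec.length
        assert sorted(f.genomic_length for f in rot.features) == \
            sorted(f.genomic_length for f in rec.features)


class TestWriteTables:
    def test_empty_table_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["species", "value"])
        path = tmp_path / "t.tsv"
        write_tables(df, path)
        assert path.read_text().strip() == "species\tvalue"

    def test_round_trip_values(self, tmp_path):
        df = pd.DataFrame({"species": ["a", "b"], "value": [0.123456, 2.0]})
        path = tmp_path / "t.tsv"
        write_tables(df, path)
        back = read_table(path)
        assert list(back.columns) == ["species", "value"]
        assert back["value"].tolist() == [0.1235, 2.0]  # 4-decimal rounding
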