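"""Intron phases, position mapping, IPS clustering and flank profiles."""

import numpy as np
import pytest

from mitodyn._genetics import translate
from mitodyn.genome_io import CodingSequence, Feature, MitogenomeRecord, Segment
from mitodyn.intron_dynamics import (IntronRecord, classify, cluster_ips,
                                     extract_introns, flank_profile,
                                     map_to_reference)
from mitodyn.synthetic_data import _random_cds


def _gene_with_intron(offset, intron_len=40):
    """Record with one plus-strand gene split by one intron after
    ``offset`` coding nt."""
    rng = np.random.default_rng(offset)
    exonic = _random_cds(rng, 40)
    intron = "GT" + "".join(rng.choice(list("ACGT"), size=intron_len - 2))
    seq = exonic[:offset] + intron + exonic[offset:]
    feats = [
        Feature("core_pcg", "cob",
                [Segment(0, offset, "+"),
                 Segment(offset + intron_len, len(seq), "+")]),
        Feature("intron", "cob-i", [Segment(offset, offset + intron_len, "+")],
                parent="cob"),
    ]
    return MitogenomeRecord("S1", "t", "linear", seq, feats)


def _intron(sp, gene, ref_pos, length=1000, phase=0, flank_up="A" * 15,
            flank_down="G" * 15, dinuc="GT"):
    return IntronRecord(sp, gene, 1, 0, length, length, ref_pos, phase,
                        flank_up, flank_down, dinuc, False, ref_pos=ref_pos)


class TestExtractIntrons:
    @pytest.mark.parametrize("offset,phase", [(3, 0), (4, 1), (5, 2), (30, 0)])
    def test_phase_from_local_position(self, offset, phase):
        introns = extract_introns(_gene_with_intron(offset))
        assert len(introns) == 1
        assert introns[0].local_pos == offset
        assert introns[0].phase == phase

    def test_flanks_and_dinucleotide(self):
        rec = _gene_with_intron(30)
        intron = extract_introns(rec)[0]
        exonic = intron.flank_up + intron.flank_down
        spliced = rec.sequence[:30] + rec.sequence[70:]
        assert exonic == spliced[15:45]
        assert intron.dinucleotide_5p == "GT"

    def test_counts_match_truth(self, conserved7):
        records, truth = conserved7
        counts = truth.per_species_intron_counts()
        for rec in records:
            assert len(extract_introns(rec)) == counts[rec.id]


class TestMapToReference:
    def _cds(self, seq, sp):
        return CodingSequence("cob", sp, seq, translate(seq), [])

    def test_identity_mapping(self):
        rng = np.random.default_rng(1)
        seq = _random_cds(rng, 60)
        cds = self._cds(seq, "A")
        intron = _intron("A", "cob", 33)
        intron.local_pos = 33
        assert map_to_reference(intron, cds, cds) == 33

    def test_query_insertion_shifts_position(self):
        rng = np.random.default_rng(2)
        ref_seq = _random_cds(rng, 100)
        query_seq = ref_seq[:15] + "GGTGGA" + ref_seq[15:]  # +2 codons, 6 nt
        ref = self._cds(ref_seq, "REF")
        query = self._cds(query_seq, "Q")
        intron = _intron("Q", "cob", 0)
        intron.local_pos = 33  # 5' of the intron: 33 query nt, 6 inserted
        assert map_to_reference(intron, query, ref) == 27

    def test_rrna_nucleotide_mapping(self):
        rng = np.random.default_rng(3)
        ref_seq = "".join(rng.choice(list("ACGT"), size=400))
        query_seq = ref_seq[:100] + "ACGTAC" + ref_seq[100:]
        ref = CodingSequence("rnl", "REF", ref_seq, "", [])
        query = CodingSequence("rnl", "Q", query_seq, "", [])
        intron = _intron("Q", "rnl", 0, phase=None)
        intron.local_pos = 206
        assert map_to_reference(intron, query, ref, rrna_host=True) == 200


class TestClusterIps:
    def test_tolerance_chain_examples(self):
        cat = cluster_ips([_intron("A", "cob", 100), _intron("B", "cob", 102),
                           _intron("C", "cob", 103)], tolerance=3)
        assert len(cat.ips_list) == 1
        assert cat.ips_list[0].shared

        cat = cluster_ips([_intron("A", "cob", 100), _intron("B", "cob", 104)],
                          tolerance=3)
        assert len(cat.ips_list) == 2

    def test_single_linkage_chain(self):
        cat = cluster_ips([_intron("A", "cob", 100), _intron("B", "cob", 103),
                           _intron("C", "cob", 106)], tolerance=3)
        assert len(cat.ips_list) == 1  # chained despite 6 nt overall span

    def test_representative_prefers_reference(self):
        cat = cluster_ips([_intron("A", "cob", 395), _intron("B", "cob", 393)],
                          tolerance=3, reference_species="B")
        assert cat.ips_list[0].id == "cob-393"

    def test_permutation_invariance(self):
        introns = [_intron(s, g, p) for s, g, p in
                   [("A", "cob", 100), ("B", "cob", 102), ("A", "cox1", 50),
                    ("C", "cox1", 300), ("B", "rnl", 700)]]
        a = cluster_ips(introns, tolerance=3)
        b = cluster_ips(introns[::-1], tolerance=3)
        assert [(i.id, sorted(i.members)) for i in a.ips_list] == \
            [(i.id, sorted(i.members)) for i in b.ips_list]

    def test_tolerance_zero_counts_distinct_positions(self):
        rng = np.random.default_rng(9)
        introns = [_intron(f"S{i%4}", "cob", int(p))
                   for i, p in enumerate(rng.integers(0, 500, size=30))]
        cat = cluster_ips(introns, tolerance=0)
        distinct = len({i.ref_pos for i in introns})
        assert len(cat.ips_list) == distinct

    def test_member_count_conservation(self, conserved7):
        records, truth = conserved7
        introns = [i for rec in records for i in extract_introns(rec)]
        for i in introns:
            i.ref_pos = i.local_pos  # indel-free cohort: identity mapping
        cat = cluster_ips(introns, tolerance=3)
        assert cat.n_introns == len(introns)
        assert sum(cat.per_species_totals().values()) == len(introns)


class TestClassify:
    def test_all_singletons_no_shared(self):
        cat = cluster_ips([_intron("A", "cob", 100), _intron("B", "cob", 500)],
                          tolerance=3)
        out = classify(cat)
        assert out["shared"] == 0
        assert out["specific"] == 2

    def test_shared_count_matches_truth(self, conserved7):
        records, truth = conserved7
        introns = [i for rec in records for i in extract_introns(rec)]
        for i in introns:
            i.ref_pos = i.local_pos
        out = classify(cluster_ips(introns, tolerance=0))
        assert out["shared"] == truth.shared_lineages()

    def test_length_histogram_modal_bin(self, conserved7):
        """Simulated intron lengths are drawn to land mostly in the
        1000-2000 bp region."""
        records, truth = conserved7
        introns = [i for rec in records for i in extract_introns(rec)]
        for i in introns:
            i.ref_pos = i.local_pos
        hist = classify(cluster_ips(introns, tolerance=0))["length_histogram"]
        merged = {}
        for b, c in hist.items():
            merged[1000 <= b < 2000] = merged.get(1000 <= b < 2000, 0) + c
        assert merged[True] > merged.get(False, 0)

    def test_phase_totals_cover_pcg_introns(self, conserved7):
        records, _ = conserved7
        introns = [i for rec in records for i in extract_introns(rec)]
        for i in introns:
            i.ref_pos = i.local_pos
        out = classify(cluster_ips(introns, tolerance=0))
        n_pcg = sum(1 for i in introns if i.phase is not None)
        assert sum(sum(c.values()) for c in out["phase_histogram"].values()) == n_pcg


class TestFlankProfile:
    def test_identical_flanks_consensus(self):
        members = [_intron(s, "cob", 100, flank_up="ACGTACGTACGTACG",
                           flank_down="TTTTTGGGGGCCCCC") for s in "ABC"]
        freq, consensus, dinucs = flank_profile(members)
        assert consensus == "ACGTACGTACGTACG" + "TTTTTGGGGGCCCCC"
        assert (freq.max(axis=0) == 1.0).all()

    def test_gt_dinucleotide_dominates(self, conserved7):
        records, _ = conserved7
        introns = [i for rec in records for i in extract_introns(rec)]
        _, _, dinucs = flank_profile(introns)
        assert dinucs.get("GT", 0) == len(introns)

    def test_tie_becomes_iupac(self):
        members = [_intron("A", "cob", 1, flank_up="A" * 15, flank_down="G" * 15),
                   _intron("B", "cob", 1, flank_up="C" * 15, flank_down="G" * 15)]
        _, consensus, _ = flank_profile(members)
        assert consensus == "M" * 15 + "G" * 15

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            flank_profile([])
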