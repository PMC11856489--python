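"""K2P and NG86 against closed forms and exhaustive oracles; NJ trees."""

import io
import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio
from Bio.Seq import Seq

from mitodyn.evol_rates import (DistanceMatrix, align_codon_aware, k2p, ng86,
                                nj_tree, summarize_gene)
from mitodyn.genome_io import CORE_PCGS, CodingSequence, extract_cds
from mitodyn.synthetic_data import SimulationConfig, simulate


def _columns(n_same, n_ti, n_tv):
    return ([("A", "A")] * n_same + [("A", "G")] * n_ti + [("A", "C")] * n_tv)


class TestK2P:
    def test_identical_is_zero(self):
        d = k2p([("ATG", "ATG"), ("TTA", "TTA")])
        assert d.d_k2p == 0
        assert d.p_transitions == d.q_transversions == 0

    def test_closed_form_example(self):
        # P = 0.2, Q = 0.1 over 20 sites
        d = k2p(_columns(14, 4, 2))
        expected = -0.5 * math.log(1 - 2 * 0.2 - 0.1) - 0.25 * math.log(1 - 2 * 0.1)
        assert d.d_k2p == pytest.approx(expected)
        assert d.d_k2p == pytest.approx(0.4024, abs=2e-4)

    def test_log_domain_violation_undefined(self):
        with pytest.warns(UserWarning):
            d = k2p(_columns(2, 9, 9))
        assert math.isnan(d.d_k2p)

    def test_monotone_in_p_and_q(self):
        """Within the defined domain, d grows with both P and Q."""
        n = 1000
        for q in (0, 50, 100):
            ds = [k2p(_columns(n - p - q, p, q)).d_k2p for p in range(0, 300, 50)]
            assert all(a < b for a, b in zip(ds, ds[1:]))
        for p in (0, 50, 100):
            ds = [k2p(_columns(n - p - q, p, q)).d_k2p for q in range(0, 300, 50)]
            assert all(a < b for a, b in zip(ds, ds[1:]))


# --- independent NG86 oracle built on Biopython's code-4 translation ------

def _aa(codon):
    return str(Seq(codon).translate(table=4))


def _oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1:]
            if _aa(m) != "*" and _aa(m) == _aa(codon):
                s += 1 / 3
    return s


def _oracle_diffs(a, b):
    diff = [i for i in range(3) if a[i] != b[i]]
    outcomes = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for step, i in enumerate(order):
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if _aa(nxt) == "*" and step < len(order) - 1:
                ok = False
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        outcomes.append((sd, nd, ok))
    pool = [(s, n) for s, n, k in outcomes if k] or [(s, n) for s, n, _ in outcomes]
    return (sum(s for s, _ in pool) / len(pool), sum(n for _, n in pool) / len(pool))


class TestNG86:
    def test_identical_zero(self):
        r = ng86([("ATG", "ATG"), ("TTA", "TTA")])
        assert r.ka == r.ks == 0

    def test_synonymous_leucine_pair(self):
        # TTA vs TTG are both Leu under code 4: one synonymous difference
        r = ng86([("TTA", "TTG")] + [("ATG", "ATG")] * 9)
        assert r.sd == pytest.approx(1.0)
        assert r.nd == pytest.approx(0.0)
        assert r.ka == 0

    def test_site_counts_partition(self):
        rng = np.random.default_rng(3)
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                  if _aa("".join(c)) != "*"]
        cols = [(codons[i], codons[j])
                for i, j in rng.integers(0, len(codons), size=(50, 2))]
        r = ng86(cols)
        assert r.s_sites + r.n_sites == pytest.approx(3 * len(cols), abs=1e-6)

    def test_matches_exhaustive_pathway_oracle(self):
        rng = np.random.default_rng(4)
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                  if _aa("".join(c)) != "*"]
        cols = [(codons[i], codons[j])
                for i, j in rng.integers(0, len(codons), size=(100, 2))]
        r = ng86(cols)
        exp_s = sum((_oracle_sites(a) + _oracle_sites(b)) / 2 for a, b in cols)
        exp_sd = sum(_oracle_diffs(a, b)[0] for a, b in cols)
        exp_nd = sum(_oracle_diffs(a, b)[1] for a, b in cols)
        assert r.s_sites == pytest.approx(exp_s, abs=1e-9)
        assert r.sd == pytest.approx(exp_sd, abs=1e-9)
        assert r.nd == pytest.approx(exp_nd, abs=1e-9)

    def test_saturated_p_undefined(self):
        r = ng86([("TTA", "TTG")])  # 1 difference over ~2 synonymous sites
        assert math.isnan(r.ks) or r.ks > 0  # ps may exceed the JC domain
        assert r.nd == 0


class TestAlignment:
    def test_identical_cds_all_columns(self, two_leaf):
        rec = two_leaf[0][0]
        cds = extract_cds(rec, "cox1")
        cols = align_codon_aware(cds, cds)
        assert len(cols) == len(cds.protein) - 1  # terminal stop dropped
        assert all(a == b for a, b in cols)

    def test_deleted_codon_drops_one_column(self, two_leaf):
        rec = two_leaf[0][0]
        cds = extract_cds(rec, "cox1")
        trimmed = CodingSequence(cds.gene_name, "other",
                                 cds.spliced_seq[:300] + cds.spliced_seq[303:],
                                 cds.protein[:100] + cds.protein[101:], [])
        cols = align_codon_aware(cds, trimmed)
        assert len(cols) == len(cds.protein) - 2


class TestRecovery:
    def test_k2p_estimate_recovers_truth(self, two_leaf):
        records, _ = two_leaf  # two leaves at total distance 0.2, omega = 1
        cols = []
        for g in CORE_PCGS:
            cols += align_codon_aware(extract_cds(records[0], g),
                                      extract_cds(records[1], g))
        d = k2p(cols)
        assert d.d_k2p == pytest.approx(0.2, abs=0.02)

    def test_purifying_selection_gives_ratio_below_one(self):
        cfg = SimulationConfig(seed=31, tree="(A:0.06,B:0.06);", omega=0.2,
                               intron_gain_rate=0, intron_loss_rate=0,
                               root_intron_count=0)
        records, _ = simulate(cfg)
        cols = []
        for g in CORE_PCGS:
            cols += align_codon_aware(extract_cds(records[0], g),
                                      extract_cds(records[1], g))
        assert ng86(cols).ratio < 1


class TestSummaries:
    def test_single_pair_median(self):
        df = pd.DataFrame({"gene": ["atp6"], "k2p": [0.12]})
        out = summarize_gene(df, "k2p")
        assert out.loc[0, "median"] == pytest.approx(0.12)
        assert out.loc[0, "n_pairs"] == 1

    def test_equal_values_zero_iqr(self):
        df = pd.DataFrame({"gene": ["cob"] * 4, "k2p": [0.3] * 4})
        out = summarize_gene(df, "k2p")
        assert out.loc[0, "iqr"] == 0

    def test_fast_gene_ranks_first(self):
        df = pd.DataFrame({"gene": ["slow"] * 3 + ["fast"] * 3,
                           "k2p": [0.01, 0.02, 0.015, 0.2, 0.25, 0.22]})
        out = summarize_gene(df, "k2p")
        assert out.loc[0, "gene"] == "fast"


def _tip_depths(newick):
    tree = skbio.TreeNode.read(io.StringIO(newick))
    return tree


class TestNJTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = _tip_depths(nj_tree(dm))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.2 + 0.3 - 0.4) / 2)
        assert lengths["B"] == pytest.approx((0.2 + 0.4 - 0.3) / 2)
        assert lengths["C"] == pytest.approx((0.3 + 0.4 - 0.2) / 2)

    @pytest.mark.parametrize("matrix", [
        # additive: ((A:1,B:2):3,(C:4,D:5))
        [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
        # ultrametric: ((A:1,B:1):1,(C:1,D:1):1)
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
    ])
    def test_additive_matrix_recovered_exactly(self, matrix):
        labels = ["A", "B", "C", "D"]
        dm = DistanceMatrix(labels, np.array(matrix, dtype=float))
        tree = _tip_depths(nj_tree(dm))
        for i, j in itertools.combinations(range(4), 2):
            path = tree.find(labels[i]).distance(tree.find(labels[j]))
            assert path == pytest.approx(matrix[i][j], abs=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]])))
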