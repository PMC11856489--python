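"""Per-gene pairwise evolutionary rates: Kimura two-parameter distances,
Nei–Gojobori (1986) Ka/Ks under genetic code 4, per-gene summaries and a
neighbor-joining tree.

The K2P distance corrects transitions (proportion P) and transversions
(proportion Q) separately:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and is undefined (NaN) outside the log domain.  The NG86 method counts
synonymous (S) and nonsynonymous (N) sites per codon as the mean
synonymous fraction over the three positions, tallies observed
differences by averaging over all mutational pathways between each codon
pair (paths through stop codons are excluded; if every path is blocked
the average falls back to all paths), and applies the Jukes–Cantor
correction d = -3/4 ln(1 - 4p/3) to pS and pN.
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._genetics import CODON_TO_AA, STOP_CODONS, is_transition
from .genome_io import CodingSequence

CodonColumns = list[tuple[str, str]]


@dataclass
class PairwiseGeneDistance:
    gene: str
    species_a: str
    species_b: str
    p_transitions: float
    q_transversions: float
    d_k2p: float
    sites_compared: int


@dataclass
class KaKsResult:
    gene: str
    species_a: str
    species_b: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m


# ---------------------------------------------------------------------------
# Codon-aware pairwise alignment
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


from functools import lru_cache


@lru_cache(maxsize=512)
def _aligned_proteins(pa: str, pb: str) -> tuple[str, str]:
    aln = _protein_aligner().align(pa, pb)[0]
    return str(aln[0]), str(aln[1])


def align_codon_aware(cds_a: CodingSequence, cds_b: CodingSequence) -> CodonColumns:
    """Globally align two CDS of the same gene at the protein level and
    back-map to gap-free codon columns (columns with gaps or N dropped)."""
    pa = _strip_stop(cds_a)
    pb = _strip_stop(cds_b)
    if not pa or not pb:
        raise ValueError(f"{cds_a.gene_name}: empty protein, cannot align")
    ga, gb = _aligned_proteins(pa, pb)
    columns: CodonColumns = []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca != "-" and cb != "-":
            codon_a = cds_a.spliced_seq[3 * ia : 3 * ia + 3]
            codon_b = cds_b.spliced_seq[3 * ib : 3 * ib + 3]
            if "N" not in codon_a and "N" not in codon_b:
                columns.append((codon_a, codon_b))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    if not columns:
        raise ValueError(f"{cds_a.gene_name}: no comparable codon columns")
    return columns


def _strip_stop(cds: CodingSequence) -> str:
    p = cds.protein
    return p[:-1] if p.endswith("*") else p


@lru_cache(maxsize=128)
def _aligned_nucleotides(seq_a: str, seq_b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def align_nucleotide(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    """Global nucleotide alignment (for rRNA hosts), returning per-site
    aligned character pairs including gaps."""
    ga, gb = _aligned_nucleotides(seq_a, seq_b)
    return list(zip(ga, gb))


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------

def k2p(columns: CodonColumns, gene: str = "", species_a: str = "",
        species_b: str = "") -> PairwiseGeneDistance:
    """Kimura two-parameter distance over paired (gap-free) columns."""
    transitions = transversions = sites = 0
    for a, b in columns:
        for x, y in zip(a, b):
            sites += 1
            if x == y:
                continue
            if is_transition(x, y):
                transitions += 1
            else:
                transversions += 1
    if sites == 0:
        raise ValueError("no sites to compare")
    P = transitions / sites
    Q = transversions / sites
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        warnings.warn(f"{gene} {species_a}-{species_b}: K2P log-domain violation "
                      f"(P={P:.3f}, Q={Q:.3f}); distance undefined")
        d = math.nan
    else:
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseGeneDistance(gene, species_a, species_b, P, Q, d, sites)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> float:
    """Synonymous-site count of one codon: mean synonymous fraction over
    the three positions; changes to stop codons count as nonsynonymous."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1
        s += syn / 3
    return s


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over the
    mutational pathways between two codons; intermediate stop codons block
    a path, and when all paths are blocked the average is over all paths."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        blocked = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS and step < len(order) - 1:
                blocked = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    pool = open_paths if open_paths else [(s, n) for s, n, _ in paths]
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86(columns: CodonColumns, gene: str = "", species_a: str = "",
         species_b: str = "") -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks over paired codon columns (code 4)."""
    s_a = s_b = 0.0
    sd = nd = 0.0
    for codon_a, codon_b in columns:
        s_a += _codon_site_counts(codon_a)
        s_b += _codon_site_counts(codon_b)
        d_s, d_n = _pathway_differences(codon_a, codon_b)
        sd += d_s
        nd += d_n
    n_codons = len(columns)
    s_sites = (s_a + s_b) / 2
    n_sites = 3 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else math.nan
    pn = nd / n_sites if n_sites > 0 else math.nan
    ks = _jc(ps) if not math.isnan(ps) else math.nan
    ka = _jc(pn) if not math.isnan(pn) else math.nan
    ratio = ka / ks if ks and not math.isnan(ks) and not math.isnan(ka) else math.nan
    return KaKsResult(gene, species_a, species_b, s_sites, n_sites, sd, nd,
                      ps, pn, ks, ka, ratio)


# ---------------------------------------------------------------------------
# Summaries, distance matrices, trees
# ---------------------------------------------------------------------------

def summarize_gene(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Per-gene median / mean / quartiles of one value column of a long
    pairwise table; undefined (NaN) pairs are dropped with a logged count."""
    n_nan = int(df[value_col].isna().sum())
    if n_nan:
        warnings.warn(f"summarize_gene({value_col}): dropping {n_nan} undefined pairs")
    ok = df.dropna(subset=[value_col])
    g = ok.groupby("gene")[value_col]
    out = pd.DataFrame({
        "gene": g.median().index,
        "n_pairs": g.size().values,
        "mean": g.mean().values,
        "median": g.median().values,
        "q1": g.quantile(0.25).values,
        "q3": g.quantile(0.75).values,
    })
    out["iqr"] = out["q3"] - out["q1"]
    return out.sort_values("median", ascending=False).reset_index(drop=True)


def pairwise_rates_table(cds_by_gene: dict[str, dict[str, CodingSequence]]) -> pd.DataFrame:
    """Long table of P, Q, K2P, Ka, Ks, Ka/Ks for every gene and ordered
    species pair present in ``cds_by_gene[gene][species]``."""
    rows = []
    for gene in sorted(cds_by_gene):
        per_species = cds_by_gene[gene]
        for sa, sb in itertools.combinations(sorted(per_species), 2):
            cols = align_codon_aware(per_species[sa], per_species[sb])
            dist = k2p(cols, gene, sa, sb)
            kk = ng86(cols, gene, sa, sb)
            rows.append({"gene": gene, "species_a": sa, "species_b": sb,
                         "P": dist.p_transitions, "Q": dist.q_transversions,
                         "k2p": dist.d_k2p, "sites": dist.sites_compared,
                         "S": kk.s_sites, "N": kk.n_sites, "Sd": kk.sd, "Nd": kk.nd,
                         "ka": kk.ka, "ks": kk.ks, "ka_ks": kk.ratio})
    return pd.DataFrame(rows, columns=["gene", "species_a", "species_b", "P", "Q",
                                       "k2p", "sites", "S", "N", "Sd", "Nd",
                                       "ka", "ks", "ka_ks"])


def mean_distance_matrix(rates: pd.DataFrame) -> DistanceMatrix:
    """Species-by-species matrix of mean K2P over genes (NaN pairs dropped)."""
    labels = sorted(set(rates["species_a"]) | set(rates["species_b"]))
    idx = {s: i for i, s in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))
    mean = rates.dropna(subset=["k2p"]).groupby(["species_a", "species_b"])["k2p"].mean()
    for (sa, sb), d in mean.items():
        m[idx[sa], idx[sb]] = m[idx[sb], idx[sa]] = d
    return DistanceMatrix(labels, m)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, returned as newick.

    Negative branch lengths (a known NJ artefact) are clamped to zero
    with a warning.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    import skbio

    sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.labels)
    tree = skbio.tree.nj(sk_dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"nj_tree: clamped {clamped} negative branch lengths to 0")
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def write_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.matrix):
            fh.write(label[:10].ljust(12) + " ".join(f"{x:.6f}" for x in row) + "\n")
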