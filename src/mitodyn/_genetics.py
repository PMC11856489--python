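"""Genetic-code utilities for the mold mitochondrial code (NCBI table 4).

Under code 4 the only stop codons are TAA and TAG; TGA encodes tryptophan,
so the Trp family has two synonymous codons and every RSCU / dN-dS
computation in this package must use these tables rather than the
universal code.
"""

from __future__ import annotations

from Bio.Data import CodonTable

CODE4 = CodonTable.unambiguous_dna_by_id[4]

STOP_CODONS: frozenset[str] = frozenset(CODE4.stop_codons)  # {TAA, TAG}

#: codon -> one-letter amino acid ('*' for stops), genetic code 4
CODON_TO_AA: dict[str, str] = dict(CODE4.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> sorted list of synonymous codons (stops excluded)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa == "*":
        continue
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

#: synonymous-family size per amino acid under code 4
FAMILY_SIZE: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

START_CODONS: tuple[str, ...] = ("ATG", "TTG", "GTG", "TTA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, to_stop: bool = False) -> str:
    """Translate a nucleotide string under genetic code 4.

    Codons containing characters outside {A,C,G,T} translate to 'X'.
    A trailing partial codon is ignored.  With ``to_stop`` translation
    halts at the first stop codon (which is not emitted).
    """
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa = CODON_TO_AA.get(codon, "X")
        if aa == "*" and to_stop:
            break
        aas.append(aa)
    return "".join(aas)


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T substitution."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)
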