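"""Synthetic mitogenome cohorts with known evolutionary truth.

The generator emulates fungal (Hypocreales-like) mitochondrial genomes:
circular AT-rich molecules carrying 15 core protein genes + rnl + rns in
the conserved gene order, 25-27 tRNAs, free-standing ORFs of unknown
function, and 1-2 kb group-I-like introns whose 5' ends start with GT and
which may carry a homing-endonuclease ORF.  An ancestral genome is built
once and evolved along a user-supplied phylogeny: sites substitute under
a Kimura two-parameter process (transition/transversion rate ratio
``kappa``), protein-coding sites additionally pass an acceptance filter
that rejects nonsynonymous changes with probability 1 - ``omega`` (a
simple stand-in for codon models), and introns are gained at random
exonic positions and lost as whole units along branches.

Every emitted annotation is backed by a :class:`SimulationTruth` ledger
(event log, true shared-intron matrix, true component lengths), so the
analysis stages can be tested against exact ground truth.  Identical
configurations produce byte-identical output.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
import skbio

from .gene_order_synteny import HYPOCREALES_ORDER
from .genome_io import CORE_PCGS, Feature, MitogenomeRecord, Segment
from ._genetics import CODON_TO_AA, STOP_CODONS, translate

# realistic core-gene lengths (amino acids, incl. start, excl. stop)
GENE_LENGTHS_AA: dict[str, int] = {
    "cox1": 530, "cox2": 250, "cox3": 270, "cob": 390,
    "nad1": 360, "nad2": 560, "nad3": 140, "nad4": 490, "nad4L": 90,
    "nad5": 660, "nad6": 220, "atp6": 255, "atp8": 48, "atp9": 74, "rps3": 450,
}

#: default 7-leaf tree emulating a small congeneric cohort (subs/site)
DEFAULT_TREE = ("((SpA:0.06,(SpB:0.04,SpC:0.04):0.02):0.02,"
                "((SpD:0.03,SpE:0.03):0.02,(SpF:0.02,SpG:0.02):0.02):0.03);")

# AT-rich base frequencies giving GC ~ 27% with positive AT and GC skew
BASE_PROBS = {"A": 0.38, "T": 0.35, "G": 0.145, "C": 0.125}

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}

INTRON_HOSTS: tuple[str, ...] = CORE_PCGS + ("rnl", "rns")


@dataclass
class SimulationConfig:
    seed: int = 1729
    tree: str = DEFAULT_TREE
    kappa: float = 2.0
    omega: float = 0.2
    gene_lengths_aa: dict[str, int] = field(default_factory=lambda: dict(GENE_LENGTHS_AA))
    gene_order: tuple[str, ...] = HYPOCREALES_ORDER
    order_overrides: dict[str, tuple[str, ...]] = field(default_factory=dict)
    intron_gain_rate: float = 8.0      # gains per host gene per unit branch length
    intron_loss_rate: float = 2.0      # loss rate per intron per unit branch length
    root_intron_count: int = 6
    intron_length_median: int = 1400   # log-normal median, lands in the 1-2 kb bin
    intron_length_sigma: float = 0.25
    heg_prob: float = 0.6
    phase_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)
    n_trna: int = 26
    trna_length: int = 72
    intergenic_mean: int = 150
    un_orf_count: int = 8
    un_orf_length_aa: int = 150
    rnl_length: int = 3100
    rns_length: int = 1500


@dataclass
class IntronLineage:
    lineage_id: str
    gene: str
    pos: int           # insertion offset in ancestral exonic coordinates
    phase: int | None
    sequence: str
    heg_span: tuple[int, int] | None   # offsets within the intron


@dataclass
class SimulationTruth:
    tree: str
    branch_substitutions: dict[str, int]
    events: list[dict]
    presence: pd.DataFrame            # lineage x species 0/1 matrix
    lineages: dict[str, IntronLineage]
    components: dict[str, dict[str, int]]
    gene_order: dict[str, tuple[str, ...]]

    def shared_lineages(self) -> int:
        return int((self.presence.sum(axis=1) >= 2).sum())

    def per_species_intron_counts(self) -> dict[str, int]:
        return {sp: int(self.presence[sp].sum()) for sp in self.presence.columns}


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    bases = rng.choice(list(BASE_PROBS), size=n, p=list(BASE_PROBS.values()))
    return "".join(bases)


_SENSE_CODONS = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
# base-composition-driven codon weights, with the strong UUA (Leu)
# preference characteristic of AT-rich fungal mitogenomes layered on top
_CODON_PREFERENCE = {"TTA": 2.0}
_CODON_WEIGHTS = np.array([np.prod([BASE_PROBS[b] for b in c]) * _CODON_PREFERENCE.get(c, 1.0)
                           for c in _SENSE_CODONS])
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    body = rng.choice(_SENSE_CODONS, size=n_aa - 1, p=_CODON_WEIGHTS)
    stop = "TAA" if rng.random() < 0.7 else "TAG"
    return "ATG" + "".join(body) + stop


def _k2p_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """Per-site base substitution probabilities after branch length ``t``
    expected substitutions/site, with ti/tv rate ratio ``kappa``."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4b = math.exp(-4.0 * beta * t)
    e2ab = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e4b + 0.5 * e2ab
    p_ti = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    m = np.full((4, 4), p_tv)
    np.fill_diagonal(m, p_same)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
        m[i, j] = p_ti
    return m


def _evolve_neutral(seq: str, t: float, kappa: float,
                    rng: np.random.Generator) -> tuple[str, int]:
    if t <= 0 or not seq:
        return seq, 0
    arr = np.array([_IDX[b] for b in seq], dtype=np.int8)
    cum = np.cumsum(_k2p_transition_matrix(t, kappa), axis=1)
    u = rng.random(arr.size)
    new = (u[:, None] > cum[arr]).sum(axis=1).astype(np.int8)
    n_subs = int((new != arr).sum())
    return "".join(_BASES[i] for i in new), n_subs


def _evolve_cds(seq: str, t: float, kappa: float, omega: float,
                rng: np.random.Generator) -> tuple[str, int]:
    """Evolve a protein-coding sequence: K2P proposals, with
    nonsynonymous changes accepted with probability ``omega`` and
    stop-creating or start/stop-codon changes rejected."""
    proposed, _ = _evolve_neutral(seq, t, kappa, rng)
    if proposed == seq:
        return seq, 0
    new = list(seq)
    n_subs = 0
    n_codons = len(seq) // 3
    for i, (old, prop) in enumerate(zip(seq, proposed)):
        if old == prop:
            continue
        codon_idx = i // 3
        if codon_idx == 0 or codon_idx == n_codons - 1:
            continue  # protect start and terminal stop
        c0 = 3 * codon_idx
        current = "".join(new[c0:c0 + 3])
        cand = current[: i - c0] + prop + current[i - c0 + 1:]
        if cand in STOP_CODONS:
            continue
        if CODON_TO_AA[cand] != CODON_TO_AA[current] and rng.random() >= omega:
            continue
        new[i] = prop
        n_subs += 1
    return "".join(new), n_subs


# ---------------------------------------------------------------------------
# Genome state along the tree
# ---------------------------------------------------------------------------

@dataclass
class _GenomeState:
    genes: dict[str, str]            # marker -> exonic/RNA sequence
    trnas: list[str]
    un_orfs: list[str]
    spacers: list[str]
    introns: list[IntronLineage]


def _copy_state(s: _GenomeState) -> _GenomeState:
    return _GenomeState(dict(s.genes), list(s.trnas), list(s.un_orfs),
                        list(s.spacers), list(s.introns))


def simulate(config: SimulationConfig) -> tuple[list[MitogenomeRecord], SimulationTruth]:
    """Generate an annotated cohort plus its ground-truth ledger."""
    rng = np.random.default_rng(config.seed)
    tree = skbio.TreeNode.read(io.StringIO(config.tree))
    leaves = [leaf.name for leaf in tree.tips()]
    if len(leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")

    root_state = _ancestral_state(config, rng)
    lineage_counter = [0]
    used_positions: dict[str, list[int]] = {g: [] for g in INTRON_HOSTS}
    lineages: dict[str, IntronLineage] = {}
    events: list[dict] = []
    branch_subs: dict[str, int] = {}

    for _ in range(config.root_intron_count):
        lin = _gain_intron(config, rng, root_state, lineage_counter, used_positions,
                           lineages, events, branch="root")
        root_state.introns.append(lin)

    leaf_states: dict[str, _GenomeState] = {}
    _recurse(tree, root_state, config, rng, lineage_counter, used_positions,
             lineages, events, branch_subs, leaf_states)

    records = []
    presence = pd.DataFrame(0, index=sorted(lineages), columns=leaves, dtype=int)
    components: dict[str, dict[str, int]] = {}
    order_truth: dict[str, tuple[str, ...]] = {}
    for leaf in leaves:
        state = leaf_states[leaf]
        order = config.order_overrides.get(leaf, config.gene_order)
        rec, comp = _assemble(leaf, state, order, config)
        records.append(rec)
        components[leaf] = comp
        order_truth[leaf] = tuple(order)
        for lin in state.introns:
            presence.loc[lin.lineage_id, leaf] = 1
    presence = presence.loc[presence.sum(axis=1) > 0]

    truth = SimulationTruth(config.tree, branch_subs, events, presence,
                            lineages, components, order_truth)
    return records, truth


def _ancestral_state(config: SimulationConfig, rng: np.random.Generator) -> _GenomeState:
    genes = {g: _random_cds(rng, config.gene_lengths_aa[g]) for g in CORE_PCGS}
    genes["rnl"] = _random_seq(rng, config.rnl_length)
    genes["rns"] = _random_seq(rng, config.rns_length)
    trnas = [_random_seq(rng, config.trna_length + int(rng.integers(-2, 3)))
             for _ in range(config.n_trna)]
    un_orfs = [_random_cds(rng, config.un_orf_length_aa + int(rng.integers(-50, 51)))
               for _ in range(config.un_orf_count)]
    n_slots = len(config.gene_order)
    spacer_lengths = 30 + rng.exponential(config.intergenic_mean, size=n_slots).astype(int)
    spacers = [_random_seq(rng, int(n)) for n in spacer_lengths]
    return _GenomeState(genes, trnas, un_orfs, spacers, [])


def _recurse(node, state, config, rng, lineage_counter, used_positions,
             lineages, events, branch_subs, leaf_states) -> None:
    for child in node.children:
        child_state = _copy_state(state)
        t = child.length or 0.0
        name = child.name or f"node{id(child) % 10000}"
        n_subs = 0
        for gene in CORE_PCGS:
            child_state.genes[gene], s = _evolve_cds(
                child_state.genes[gene], t, config.kappa, config.omega, rng)
            n_subs += s
        for gene in ("rnl", "rns"):
            child_state.genes[gene], s = _evolve_neutral(
                child_state.genes[gene], t, config.kappa, rng)
            n_subs += s
        for i, seq in enumerate(child_state.trnas):
            child_state.trnas[i], s = _evolve_neutral(seq, t, config.kappa, rng)
            n_subs += s
        for i, seq in enumerate(child_state.un_orfs):
            child_state.un_orfs[i], s = _evolve_cds(seq, t, config.kappa,
                                                    config.omega, rng)
            n_subs += s
        for i, seq in enumerate(child_state.spacers):
            child_state.spacers[i], s = _evolve_neutral(seq, t, config.kappa, rng)
            n_subs += s
        branch_subs[name] = n_subs

        # intron turnover
        if config.intron_loss_rate > 0 and t > 0:
            p_loss = 1.0 - math.exp(-config.intron_loss_rate * t)
            survivors = []
            for lin in child_state.introns:
                if rng.random() < p_loss:
                    events.append({"event": "loss", "branch": name, "gene": lin.gene,
                                   "pos": lin.pos, "lineage": lin.lineage_id})
                else:
                    survivors.append(lin)
            child_state.introns = survivors
        if config.intron_gain_rate > 0 and t > 0:
            for gene in INTRON_HOSTS:
                for _ in range(rng.poisson(config.intron_gain_rate * t)):
                    lin = _gain_intron(config, rng, child_state, lineage_counter,
                                       used_positions, lineages, events, branch=name)
                    child_state.introns.append(lin)

        if child.is_tip():
            leaf_states[child.name] = child_state
        else:
            _recurse(child, child_state, config, rng, lineage_counter,
                     used_positions, lineages, events, branch_subs, leaf_states)


_MIN_POSITION_GAP = 8  # keeps distinct lineages separable at tolerance 3


def _gain_intron(config, rng, state, lineage_counter, used_positions,
                 lineages, events, branch: str) -> IntronLineage:
    gene = INTRON_HOSTS[int(rng.integers(len(INTRON_HOSTS)))]
    exonic_len = len(state.genes[gene])
    for _ in range(200):
        if gene in CORE_PCGS:
            phase = int(rng.choice(3, p=config.phase_probs))
            n_codons = exonic_len // 3
            codon = int(rng.integers(3, n_codons - 3))
            pos = 3 * codon + phase
        else:
            phase = None
            pos = int(rng.integers(30, exonic_len - 30))
        if all(abs(pos - p) >= _MIN_POSITION_GAP for p in used_positions[gene]):
            break
    else:
        raise RuntimeError(f"could not place intron in {gene}: positions saturated")
    used_positions[gene].append(pos)
    seq, heg_span = _intron_sequence(config, rng)
    lineage_counter[0] += 1
    lid = f"L{lineage_counter[0]:04d}"
    lin = IntronLineage(lid, gene, pos, phase, seq, heg_span)
    lineages[lid] = lin
    events.append({"event": "gain", "branch": branch, "gene": gene, "pos": pos,
                   "phase": -1 if phase is None else phase, "lineage": lid})
    return lin


def _intron_sequence(config, rng) -> tuple[str, tuple[int, int] | None]:
    length = int(rng.lognormal(math.log(config.intron_length_median),
                               config.intron_length_sigma))
    length = max(500, min(4000, length))
    if rng.random() < config.heg_prob:
        orf_aa = int(rng.integers(200, min(380, (length - 120) // 3)))
        orf = _random_cds(rng, orf_aa)
        lead = int(rng.integers(20, max(21, length - len(orf) - 20)))
        tail = max(10, length - 2 - lead - len(orf))
        seq = "GT" + _random_seq(rng, lead - 2) + orf + _random_seq(rng, tail)
        return seq, (lead, lead + len(orf))
    return "GT" + _random_seq(rng, length - 2), None


# ---------------------------------------------------------------------------
# Assembly into annotated records
# ---------------------------------------------------------------------------

def _assemble(leaf: str, state: _GenomeState, order: tuple[str, ...],
              config: SimulationConfig) -> tuple[MitogenomeRecord, dict[str, int]]:
    parts: list[str] = []
    features: list[Feature] = []
    cursor = 0
    comp = {"core_pcg_exonic": 0, "rna_region": 0, "intronic": 0,
            "un_orf": 0, "intergenic": 0, "heg_length": 0}

    n_slots = len(order)
    trna_slots: dict[int, list[str]] = {i: [] for i in range(n_slots)}
    for i, seq in enumerate(state.trnas):
        trna_slots[i % n_slots].append(seq)
    orf_slots: dict[int, list[str]] = {i: [] for i in range(n_slots)}
    for i, seq in enumerate(state.un_orfs):
        orf_slots[(i * 2 + 1) % n_slots].append(seq)

    trna_letters = "ACDEFGHIKLMNPQRSTVWY"
    trna_n = 0
    for slot, marker in enumerate(order):
        spacer = state.spacers[slot]
        parts.append(spacer)
        comp["intergenic"] += len(spacer)
        cursor += len(spacer)
        for seq in trna_slots[slot]:
            features.append(Feature("trna", f"trn{trna_letters[trna_n % 20]}{trna_n}",
                                    [Segment(cursor, cursor + len(seq), "+")]))
            comp["rna_region"] += len(seq)
            parts.append(seq)
            cursor += len(seq)
            parts.append("TA")  # 2 nt micro-spacer
            comp["intergenic"] += 2
            cursor += 2
        for seq in orf_slots[slot]:
            aa = len(seq) // 3 - 1
            features.append(Feature("un_orf", f"orf{aa}",
                                    [Segment(cursor, cursor + len(seq), "+")]))
            comp["un_orf"] += len(seq)
            parts.append(seq)
            cursor += len(seq)
            parts.append("TA")
            comp["intergenic"] += 2
            cursor += 2
        cursor = _emit_gene(marker, state, parts, features, cursor, comp)

    sequence = "".join(parts)
    features.sort(key=lambda f: (f.start, f.end, f.category, f.gene_name))
    comp["total"] = len(sequence)
    record = MitogenomeRecord(leaf, f"Synthetica {leaf.lower()}", "circular",
                              sequence, features)
    return record, comp


def _emit_gene(marker: str, state: _GenomeState, parts, features, cursor, comp) -> int:
    exonic = state.genes[marker]
    introns = sorted((lin for lin in state.introns if lin.gene == marker),
                     key=lambda lin: lin.pos)
    category = "core_pcg" if marker in CORE_PCGS else "rrna"
    comp_key = "core_pcg_exonic" if category == "core_pcg" else "rna_region"
    segments: list[Segment] = []
    prev = 0
    for lin in introns:
        exon = exonic[prev:lin.pos]
        segments.append(Segment(cursor, cursor + len(exon), "+"))
        parts.append(exon)
        comp[comp_key] += len(exon)
        cursor += len(exon)
        features.append(Feature("intron", f"{marker}-i",
                                [Segment(cursor, cursor + len(lin.sequence), "+")],
                                parent=marker))
        if lin.heg_span is not None:
            h0, h1 = lin.heg_span
            features.append(Feature("heg", f"heg-{lin.lineage_id}",
                                    [Segment(cursor + h0, cursor + h1, "+")],
                                    parent=marker))
            comp["heg_length"] += h1 - h0
        parts.append(lin.sequence)
        comp["intronic"] += len(lin.sequence)
        cursor += len(lin.sequence)
        prev = lin.pos
    exon = exonic[prev:]
    segments.append(Segment(cursor, cursor + len(exon), "+"))
    parts.append(exon)
    comp[comp_key] += len(exon)
    cursor += len(exon)
    features.append(Feature(category, marker, segments))
    return cursor


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str) -> tuple[list[MitogenomeRecord], SimulationTruth]:
    """Deterministic named cohorts used across tests and examples.

    - ``conserved7``: seven genomes, shared gene order, mixed intron sharing.
    - ``transposed``: three genomes, one with cox2 relocated between nad4
      and atp8 (two arrangement classes).
    - ``intron_rich`` / ``intron_poor``: six independent genomes each with
      heavy respectively light intron loads and cross-genome variation in
      RNA, un_ORF and intergenic content — combine them for
      size-correlation analyses.
    - ``two_leaf``: minimal pair at distance 0.2, no introns, for
      estimator checks.
    """
    if name == "conserved7":
        return simulate(SimulationConfig(seed=424243))
    if name == "intron_rich":
        return _standalone_cohort("Rich", seed=51001, intron_counts=(16, 22, 27, 30, 33, 35))
    if name == "intron_poor":
        return _standalone_cohort("Poor", seed=52002, intron_counts=(0, 2, 4, 5, 7, 8))
    if name == "transposed":
        moved = ("cox1", "nad1", "nad4", "cox2", "atp8", "atp6", "rns", "cox3",
                 "nad6", "rnl", "rps3", "nad2", "nad3", "atp9", "nad4L",
                 "nad5", "cob")
        cfg = SimulationConfig(
            seed=77001, tree="((SpA:0.04,SpB:0.04):0.01,SpC:0.05);",
            intron_gain_rate=2.0, root_intron_count=2,
            order_overrides={"SpC": moved})
        return simulate(cfg)
    if name == "two_leaf":
        cfg = SimulationConfig(seed=99003, tree="(A:0.1,B:0.1);", omega=1.0,
                               intron_gain_rate=0.0, intron_loss_rate=0.0,
                               root_intron_count=0)
        return simulate(cfg)
    raise KeyError(f"unknown fixture {name!r}")


def _standalone_cohort(prefix: str, seed: int,
                       intron_counts: tuple[int, ...]) -> tuple[list[MitogenomeRecord],
                                                                SimulationTruth]:
    """Independent genomes (no shared ancestry) whose non-intron
    components also vary, emulating a cross-species cohort for
    size-correlation analyses."""
    rng = np.random.default_rng(seed)
    records, components, order_truth = [], {}, {}
    lineages: dict[str, IntronLineage] = {}
    events: list[dict] = []
    presence_rows = {}
    labels = [f"{prefix}{i+1}" for i in range(len(intron_counts))]
    for label, n_introns in zip(labels, intron_counts):
        cfg = SimulationConfig(
            seed=seed,
            intergenic_mean=int(rng.integers(100, 300)),
            un_orf_count=int(rng.integers(0, 14)),
            un_orf_length_aa=int(rng.integers(100, 220)),
            n_trna=int(rng.integers(25, 28)),
            rnl_length=3100 + int(rng.integers(-300, 301)),
            rns_length=1500 + int(rng.integers(-150, 151)),
        )
        state = _ancestral_state(cfg, rng)
        used = {g: [] for g in INTRON_HOSTS}
        counter = [0]
        local: dict[str, IntronLineage] = {}
        for _ in range(n_introns):
            lin = _gain_intron(cfg, rng, state, counter, used, local, events,
                               branch=label)
            lin = dc_replace(lin, lineage_id=f"{label}:{lin.lineage_id}")
            state.introns.append(lin)
            local[lin.lineage_id] = lin
        for lid, lin in local.items():
            lineages[f"{label}:{lid}" if not lid.startswith(label) else lid] = lin
        rec, comp = _assemble(label, state, cfg.gene_order, cfg)
        records.append(rec)
        components[label] = comp
        order_truth[label] = tuple(cfg.gene_order)
        for lin in state.introns:
            presence_rows[lin.lineage_id] = label
    presence = pd.DataFrame(0, index=sorted(presence_rows), columns=labels, dtype=int)
    for lid, label in presence_rows.items():
        presence.loc[lid, label] = 1
    truth = SimulationTruth("", {}, events, presence, lineages, components,
                            order_truth)
    return records, truth


def sanity_check_state(records: list[MitogenomeRecord]) -> None:
    """Debug helper: assert every emitted core CDS still translates
    without internal stops."""
    from .genome_io import extract_cds
    for rec in records:
        for gene in CORE_PCGS:
            cds = extract_cds(rec, gene)
            prot = translate(cds.spliced_seq)
            assert "*" not in prot[:-1], f"{rec.id}:{gene} internal stop"
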