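"""Circular gene-order comparison and pairwise synteny block detection.

The order of the 17 standard markers (15 core protein genes + rnl + rns)
is read off the linearized circle and canonicalized by rotating to cox1,
making orders comparable across records regardless of where the circle
was opened.  The breakpoint distance counts circular adjacencies of one
order missing from the other.  Synteny blocks are homologous segments
found by seed-and-extend self-alignment of two genomes, reported with
orientation so inversions are visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .composition import _pairwise_blocks
from .genome_io import ORDER_MARKERS, MitogenomeRecord

#: the gene order shared by most Hypocreales mitogenomes
HYPOCREALES_ORDER: tuple[str, ...] = (
    "cox1", "nad1", "nad4", "atp8", "atp6", "rns", "cox3", "nad6", "rnl",
    "rps3", "nad2", "nad3", "atp9", "cox2", "nad4L", "nad5", "cob",
)
#: the divergent order reported for Stachybotrys / Metacordyceps
STACHYBOTRYS_ORDER: tuple[str, ...] = (
    "cox1", "nad2", "nad3", "atp9", "cox2", "nad4L", "nad5", "cob", "nad1",
    "nad4", "atp8", "atp6", "rns", "cox3", "nad6", "rnl", "rps3",
)


@dataclass
class GeneOrder:
    species_id: str
    markers: tuple[str, ...]      # canonical rotation, starting at cox1
    strands: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.markers) != sorted(ORDER_MARKERS):
            missing = set(ORDER_MARKERS) - set(self.markers)
            extra = set(self.markers) - set(ORDER_MARKERS)
            raise ValueError(f"gene order needs the 17 standard markers exactly "
                             f"(missing {sorted(missing)}, extra {sorted(extra)})")
        if self.markers[0] != "cox1":
            raise ValueError("canonical order must start at cox1")


@dataclass
class SyntenyBlock:
    species_a: str
    species_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    length: int
    identity: float
    orientation: str  # 'same' or 'inverted'


def extract_order(record: MitogenomeRecord) -> GeneOrder:
    """Canonical circular order of the 17 markers, sorted by start
    coordinate and rotated to cox1.  rps3 nested inside rnl is ordered by
    its own start coordinate."""
    feats = [f for f in record.features
             if f.category in ("core_pcg", "rrna") and f.gene_name in ORDER_MARKERS]
    by_name = {}
    for f in feats:
        by_name.setdefault(f.gene_name, f)
    missing = [m for m in ORDER_MARKERS if m not in by_name]
    if missing:
        raise ValueError(f"{record.id}: markers not annotated: {missing}")
    ordered = sorted(by_name.values(), key=lambda f: (f.start, f.gene_name != "rps3"))
    names = [f.gene_name for f in ordered]
    strands = [f.strand for f in ordered]
    if len(set(strands)) > 1:
        warnings.warn(f"{record.id}: markers on both strands; adjacency "
                      f"comparison becomes strand-aware")
    pivot = names.index("cox1")
    return GeneOrder(record.id,
                     tuple(names[pivot:] + names[:pivot]),
                     tuple(strands[pivot:] + strands[:pivot]))


def make_order(species_id: str, markers, strands=None) -> GeneOrder:
    """Build a GeneOrder from a marker list (e.g. one of the shipped
    reference permutations), canonicalizing the rotation."""
    markers = list(markers)
    strands = list(strands) if strands else ["+"] * len(markers)
    pivot = markers.index("cox1")
    return GeneOrder(species_id, tuple(markers[pivot:] + markers[:pivot]),
                     tuple(strands[pivot:] + strands[:pivot]))


def _adjacencies(order: GeneOrder) -> set[frozenset]:
    """Circular adjacencies as unordered signed pairs.  When all markers
    share a strand the sign is immaterial; mixed strands make the
    comparison strand-aware."""
    out = set()
    n = len(order.markers)
    for i in range(n):
        j = (i + 1) % n
        a = (order.markers[i], order.strands[i])
        b = (order.markers[j], order.strands[j])
        out.add(frozenset((a, b)))
    return out


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of circular adjacencies of ``a`` absent from ``b``."""
    if sorted(a.markers) != sorted(b.markers):
        raise ValueError("orders cover different marker sets")
    return len(_adjacencies(a) - _adjacencies(b))


def group_arrangements(orders: list[GeneOrder]) -> list[list[GeneOrder]]:
    """Partition gene orders into identical-arrangement classes."""
    classes: dict[tuple, list[GeneOrder]] = {}
    for o in orders:
        classes.setdefault((o.markers, o.strands), []).append(o)
    return [classes[k] for k in sorted(classes)]


def find_blocks(rec_a: MitogenomeRecord, rec_b: MitogenomeRecord,
                min_len: int = 500, min_identity: float = 0.7) -> list[SyntenyBlock]:
    """Homologous blocks between two genomes by 12-mer seeding and
    gapless x-drop extension on both strands; blocks under ``min_len`` or
    ``min_identity`` are dropped, and a minus-strand winner is reported
    as an inverted block."""
    raw = _pairwise_blocks(rec_a.sequence, rec_b.sequence, min_len, min_identity)
    return [SyntenyBlock(rec_a.id, rec_b.id, a0, a1, b0, b1, a1 - a0, ident, orient)
            for (a0, a1, b0, b1, ident, orient) in raw]


def order_table(orders: list[GeneOrder]) -> pd.DataFrame:
    rows = []
    for o in orders:
        row = {"species": o.species_id}
        for i, m in enumerate(o.markers, start=1):
            row[f"pos{i:02d}"] = m
        rows.append(row)
    cols = ["species"] + [f"pos{i:02d}" for i in range(1, len(ORDER_MARKERS) + 1)]
    return pd.DataFrame(rows, columns=cols)


def block_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = [{"species_a": b.species_a, "species_b": b.species_b,
             "start_a": b.start_a, "end_a": b.end_a,
             "start_b": b.start_b, "end_b": b.end_b, "length": b.length,
             "identity": b.identity, "orientation": b.orientation} for b in blocks]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "start_a", "end_a",
                                       "start_b", "end_b", "length", "identity",
                                       "orientation"])
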