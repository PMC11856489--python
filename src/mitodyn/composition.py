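"""Base composition, strand skews, genome component decomposition and
simplified intragenomic repeat detection.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C); both measure
strand compositional asymmetry and are undefined (NaN) when the
denominator is empty rather than being reported as zero.

``decompose`` partitions every genome position into exactly one of five
exclusive categories (core-gene exons, RNA regions, introns, free-standing
un_ORFs, intergenic) with homing-endonuclease genes measured as an overlay
on top of their host intron/ORF, so the five exclusive lengths always sum
to the genome length while the HEG total remains available for
correlation analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._genetics import reverse_complement
from .genome_io import MitogenomeRecord


@dataclass
class BaseComposition:
    a: int
    c: int
    g: int
    t: int
    n_other: int
    gc_content: float
    at_skew: float
    gc_skew: float


@dataclass
class ComponentDecomposition:
    species_id: str
    core_pcg_exonic: int
    rna_region: int
    intronic: int
    un_orf: int
    intergenic: int
    heg_length: int
    total: int

    @property
    def proportions(self) -> dict[str, float]:
        return {k: getattr(self, k) / self.total
                for k in ("core_pcg_exonic", "rna_region", "intronic", "un_orf", "intergenic")}


@dataclass
class RepeatHit:
    kind: str                     # 'tandem' or 'dispersed'
    start: int
    end: int
    unit_length: int | None       # tandem only
    copy_number: float | None     # tandem only
    mate_start: int | None        # dispersed only
    mate_end: int | None
    identity: float
    total_length: int
    orientation: str = "same"     # dispersed: 'same' or 'inverted'


def base_composition(seq: str) -> BaseComposition:
    if not seq:
        raise ValueError("empty sequence")
    a, c, g, t = (seq.count(b) for b in "ACGT")
    n_other = len(seq) - (a + c + g + t)
    acgt = a + c + g + t
    gc_content = (g + c) / acgt if acgt else math.nan
    at_skew = (a - t) / (a + t) if (a + t) else math.nan
    gc_skew = (g - c) / (g + c) if (g + c) else math.nan
    return BaseComposition(a, c, g, t, n_other, gc_content, at_skew, gc_skew)


# category codes, ascending priority: a higher code overwrites a lower one
_PRIORITY = {"intergenic": 0, "un_orf": 1, "intron": 2, "rna": 3, "core": 4}


def decompose(record: MitogenomeRecord) -> ComponentDecomposition:
    """Assign every position to one exclusive component by priority
    core exon > RNA (rRNA exon + tRNA) > intron > un_ORF > intergenic;
    HEG spans are tallied as an overlay."""
    paint = np.zeros(record.length, dtype=np.int8)
    heg = np.zeros(record.length, dtype=bool)

    def mark(feature, code):
        for s in feature.segments:
            paint[s.start:s.end] = np.maximum(paint[s.start:s.end], code)

    for f in record.features:
        if f.category == "un_orf":
            mark(f, _PRIORITY["un_orf"])
    for f in record.features:
        if f.category == "intron":
            mark(f, _PRIORITY["intron"])
    for f in record.features:
        if f.category in ("rrna", "trna"):
            mark(f, _PRIORITY["rna"])
    for f in record.features:
        if f.category == "core_pcg":
            mark(f, _PRIORITY["core"])
    for f in record.features:
        if f.category == "heg":
            for s in f.segments:
                heg[s.start:s.end] = True

    counts = np.bincount(paint, minlength=5)
    return ComponentDecomposition(
        species_id=record.id,
        core_pcg_exonic=int(counts[4]),
        rna_region=int(counts[3]),
        intronic=int(counts[2]),
        un_orf=int(counts[1]),
        intergenic=int(counts[0]),
        heg_length=int(heg.sum()),
        total=record.length,
    )


# ---------------------------------------------------------------------------
# Tandem repeats: unit-autocorrelation scan with greedy extension
# ---------------------------------------------------------------------------

def find_tandem_repeats(seq: str, min_unit: int = 10, max_unit: int = 200,
                        min_copies: float = 1.9,
                        min_identity: float = 0.8) -> list[RepeatHit]:
    """Detect maximal tandem arrays by comparing the sequence against
    itself shifted by each candidate unit length.

    A run where ``seq[i] == seq[i+p]`` holds at ``min_identity`` density
    and spans at least ``(min_copies - 1)`` units is reported with copy
    number ``(run + p) / p``.  Nested hits (the 2p, 3p echoes of a p-array)
    are suppressed by preferring the smallest period covering a region.
    """
    if not (1 <= min_unit <= max_unit <= 500):
        raise ValueError("require 1 <= min_unit <= max_unit <= 500")
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[RepeatHit] = []
    for p in range(min_unit, min(max_unit, n // 2) + 1):
        match = arr[:-p] == arr[p:]
        for run_start, run_end in _dense_runs(match, min_identity,
                                              int(math.ceil((min_copies - 1) * p))):
            ident = float(match[run_start:run_end].mean())
            total = run_end - run_start + p
            candidates.append(RepeatHit(
                kind="tandem", start=run_start, end=run_start + total,
                unit_length=p, copy_number=round(total / p, 2),
                mate_start=None, mate_end=None,
                identity=ident, total_length=total))
    return _suppress_nested(candidates)


def _dense_runs(match: np.ndarray, min_identity: float, min_len: int,
                seed_len: int = 8):
    """Maximal segments of a boolean array that start/end on a match and
    keep overall identity >= min_identity.

    Extension only starts at a streak of ``seed_len`` consecutive matches
    (random sequence rarely seeds) and stops after a long mismatch run,
    keeping the scan near-linear.
    """
    n = len(match)
    if n < min_len:
        return []
    seed_len = min(seed_len, max(1, min_len))
    # run length of consecutive matches ending at each position (vectorized)
    pos = np.arange(1, n + 1)
    last_miss = np.maximum.accumulate(np.where(~match, pos, 0))
    run_ending = pos - last_miss
    seed_ends = np.where(run_ending >= seed_len)[0]
    candidates = seed_ends - (seed_len - 1)
    max_gap = max(12, min_len // 4)
    runs = []
    i = 0
    for cand in candidates:
        if cand < i:
            continue
        i = int(cand)
        j, hits, best_j, miss_run = i, 0, i, 0
        while j < n and miss_run <= max_gap:
            if match[j]:
                hits += 1
                miss_run = 0
            else:
                miss_run += 1
            j += 1
            if match[j - 1] and hits / (j - i) >= min_identity:
                best_j = j
        if best_j - i >= min_len:
            runs.append((i, best_j))
        i = max(best_j, i + 1)
    return runs


def _suppress_nested(hits: list[RepeatHit]) -> list[RepeatHit]:
    hits = sorted(hits, key=lambda h: (h.start, h.unit_length or 0, -h.total_length))
    kept: list[RepeatHit] = []
    for h in hits:
        if any(k.start <= h.start and h.end <= k.end + (h.unit_length or 0)
               and (k.unit_length or 0) <= (h.unit_length or 0) for k in kept):
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Dispersed repeats: exact k-mer seeding + gapless x-drop extension
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH, _XDROP = 1.0, -2.0, 12.0


def find_dispersed_repeats(record: MitogenomeRecord, min_len: int = 35,
                           min_identity: float = 0.76) -> list[RepeatHit]:
    """Self-comparison of a genome for dispersed (interspersed) repeats.

    Exact 12-mers seed gapless extensions scored +1/-2 with an x-drop
    cutoff; the trivial self-diagonal and mirrored duplicates are
    excluded.  Both orientations are searched.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    seq = record.sequence
    hits = _pairwise_blocks(seq, seq, min_len, min_identity, self_compare=True)
    out = []
    for (a0, a1, b0, b1, ident, orient) in hits:
        out.append(RepeatHit("dispersed", a0, a1, None, None, b0, b1,
                             ident, a1 - a0, orient))
    return out


def _pairwise_blocks(sa: str, sb: str, min_len: int, min_identity: float,
                     self_compare: bool = False, k: int = 12):
    """Shared seed-and-extend engine for dispersed repeats and synteny
    blocks; returns (a0, a1, b0, b1, identity, orientation) tuples."""
    results = []
    for orient, sb_o in (("same", sb), ("inverted", reverse_complement(sb))):
        index: dict[str, list[int]] = {}
        for i in range(len(sa) - k + 1):
            kmer = sa[i : i + k]
            if "N" not in kmer:
                index.setdefault(kmer, []).append(i)
        seen_diag: dict[int, int] = {}  # diagonal -> rightmost b end extended
        for j in range(len(sb_o) - k + 1):
            kmer = sb_o[j : j + k]
            for i in index.get(kmer, ()):
                if self_compare and orient == "same" and i == j:
                    continue
                if self_compare and orient == "same" and i > j:
                    continue  # mirrored duplicate
                diag = i - j
                if seen_diag.get(diag, -1) >= j:
                    continue
                a0, a1, b0, b1, ident = _xdrop_extend(sa, sb_o, i, j, k)
                seen_diag[diag] = b1
                if a1 - a0 >= min_len and ident >= min_identity:
                    if orient == "inverted":
                        rb0, rb1 = len(sb) - b1, len(sb) - b0
                        results.append((a0, a1, rb0, rb1, ident, orient))
                    else:
                        results.append((a0, a1, b0, b1, ident, orient))
    return _dedupe_blocks(results)


def _xdrop_extend(sa: str, sb: str, i: int, j: int, k: int):
    score = best = float(k)
    a0, b0 = i, j
    ai, bj = i - 1, j - 1
    best_a0, best_b0 = a0, b0
    while ai >= 0 and bj >= 0:
        score += _MATCH if sa[ai] == sb[bj] else _MISMATCH
        if score > best:
            best, best_a0, best_b0 = score, ai, bj
        if best - score > _XDROP:
            break
        ai -= 1
        bj -= 1
    a0, b0 = best_a0, best_b0
    score = best
    a1, b1 = i + k, j + k
    ai, bj = a1, b1
    best_a1, best_b1 = a1, b1
    while ai < len(sa) and bj < len(sb):
        score += _MATCH if sa[ai] == sb[bj] else _MISMATCH
        ai += 1
        bj += 1
        if score > best:
            best, best_a1, best_b1 = score, ai, bj
        if best - score > _XDROP:
            break
    a1, b1 = best_a1, best_b1
    matches = sum(1 for x, y in zip(sa[a0:a1], sb[b0:b1]) if x == y)
    ident = matches / (a1 - a0) if a1 > a0 else 0.0
    return a0, a1, b0, b1, ident


def _dedupe_blocks(results):
    results = sorted(results, key=lambda r: (-(r[1] - r[0]), r[0], r[2]))
    kept = []
    for r in results:
        a0, a1, b0, b1 = r[:4]
        dup = False
        for q in kept:
            if (min(a1, q[1]) - max(a0, q[0]) > 0.8 * (a1 - a0)
                    and min(b1, q[3]) - max(b0, q[2]) > 0.8 * (b1 - b0)
                    and q[5] == r[5]):
                dup = True
                break
        if not dup:
            kept.append(r)
    kept.sort(key=lambda r: (r[0], r[2]))
    return kept


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def composition_table(records) -> pd.DataFrame:
    rows = []
    for r in records:
        bc = base_composition(r.sequence)
        rows.append({"species": r.id, "length": r.length,
                     "gc_content": bc.gc_content, "at_skew": bc.at_skew,
                     "gc_skew": bc.gc_skew, "A": bc.a, "C": bc.c,
                     "G": bc.g, "T": bc.t, "N": bc.n_other})
    return pd.DataFrame(rows, columns=["species", "length", "gc_content",
                                       "at_skew", "gc_skew", "A", "C", "G", "T", "N"])


def decomposition_table(records) -> pd.DataFrame:
    rows = []
    for r in records:
        d = decompose(r)
        rows.append({"species": d.species_id, "total": d.total,
                     "core_pcg_exonic": d.core_pcg_exonic, "rna_region": d.rna_region,
                     "intronic": d.intronic, "un_orf": d.un_orf,
                     "intergenic": d.intergenic, "heg_length": d.heg_length})
    return pd.DataFrame(rows, columns=["species", "total", "core_pcg_exonic",
                                       "rna_region", "intronic", "un_orf",
                                       "intergenic", "heg_length"])


def repeat_table(species_id: str, hits: list[RepeatHit]) -> pd.DataFrame:
    rows = [{"species": species_id, "kind": h.kind, "start": h.start, "end": h.end,
             "unit_length": h.unit_length, "copy_number": h.copy_number,
             "mate_start": h.mate_start, "mate_end": h.mate_end,
             "identity": h.identity, "total_length": h.total_length,
             "orientation": h.orientation} for h in hits]
    return pd.DataFrame(rows, columns=["species", "kind", "start", "end", "unit_length",
                                       "copy_number", "mate_start", "mate_end",
                                       "identity", "total_length", "orientation"])
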