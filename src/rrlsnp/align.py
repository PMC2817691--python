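"""Seeded ungapped alignment of short reads and pileup construction.

Reads are placed full-length, without gaps, on either strand of the
reference, tolerating a bounded number of mismatches (default 1 for a
33 bp read, i.e. 32 or 33 matching nucleotides). Placement uses
seed-and-verify with a pigeonhole guarantee of completeness:

    A query of length L aligned with at most m mismatches is divided
    into m+1 disjoint intervals, each at least ``seed_len`` long. The
    mismatches can corrupt at most m of those intervals, so at least one
    interval — and therefore its leading ``seed_len``-mer — matches the
    reference exactly. Looking up the leading seed of every interval in
    an exact-match index and verifying each candidate placement by a
    full Hamming comparison thus finds every valid placement.

A read's placements are classified as unique / multiple / unmapped and
given a deterministic mapping score that is monotone in uniqueness: 37
for an unchallenged unique placement, minus 10 per sub-optimal
competitor (capped), and 0 whenever the best placement is ambiguous.
The score-30 cutoff used by the SNP filters therefore passes exactly
the uniquely placed reads with no competing placement at all.

Reference positions holding ``N`` (assembly gaps) match no read base,
so alignments never extend into gaps.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import QualityRead, SequenceRecord, revcomp

__all__ = [
    "AlignmentHit",
    "PlacedRead",
    "PileupColumn",
    "GenomeIndex",
    "build_index",
    "align_read",
    "classify_placement",
    "place_reads",
    "pileup",
    "coverage_stats",
]

UNIQUE_SCORE = 37
SUBOPT_PENALTY = 10
MAX_PENALIZED_COMPETITORS = 3


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped full-length placement of a read on the reference."""

    read_id: str
    target_id: str
    pos: int  # 0-based leftmost reference coordinate
    strand: str  # "+" or "-"
    mismatches: int
    mismatch_positions: tuple[tuple[int, str, str], ...]  # (offset, ref, read) in ref orientation


@dataclass(frozen=True)
class PlacedRead:
    read: QualityRead
    best_hits: tuple[AlignmentHit, ...]
    placement: str  # unique | multiple | unmapped
    mapping_score: int
    read_copy: int  # number of equally-best placements


@dataclass
class PileupColumn:
    target_id: str
    pos: int
    ref_base: str
    # (base, quality, read_id, strand)
    observations: list[tuple[str, int, str, str]]


class GenomeIndex:
    """Exact-match seed index over a set of reference sequences."""

    def __init__(self, records: Sequence[SequenceRecord], seed_len: int = 11):
        if seed_len < 4:
            raise ValueError("seed_len must be >= 4")
        self.seed_len = seed_len
        self.records = list(records)
        self.seqs = {rec.id: rec.seq for rec in self.records}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rec in self.records:
            seq = rec.seq
            for i in range(len(seq) - seed_len + 1):
                seed = seq[i : i + seed_len]
                if "N" not in seed:
                    self._index[seed].append((rec.id, i))
        self._index = dict(self._index)

    def seed_positions(self, seed: str) -> list[tuple[str, int]]:
        return self._index.get(seed, [])

    def _verify(self, query: str, target_id: str, pos: int, max_mismatch: int):
        """Hamming-verify a candidate placement; N in the reference never matches."""
        seq = self.seqs[target_id]
        if pos < 0 or pos + len(query) > len(seq):
            return None
        window = seq[pos : pos + len(query)]
        mm: list[tuple[int, str, str]] = []
        for j, (r, q) in enumerate(zip(window, query)):
            if r != q or r == "N":
                mm.append((j, r, q))
                if len(mm) > max_mismatch:
                    return None
        return tuple(mm)

    def _search_strand(self, query: str, max_mismatch: int) -> list[tuple[str, int, tuple]]:
        n_seeds = max_mismatch + 1
        stride = len(query) // n_seeds
        if stride < self.seed_len:
            raise ValueError(
                f"query length {len(query)} too short for {max_mismatch} mismatches "
                f"with seed_len {self.seed_len} (pigeonhole needs "
                f"{n_seeds} disjoint {self.seed_len}-mers)"
            )
        candidates: set[tuple[str, int]] = set()
        for i in range(n_seeds):
            off = i * stride
            seed = query[off : off + self.seed_len]
            if "N" in seed:
                continue
            for target_id, pos in self.seed_positions(seed):
                candidates.add((target_id, pos - off))
        out = []
        for target_id, pos in candidates:
            mm = self._verify(query, target_id, pos, max_mismatch)
            if mm is not None:
                out.append((target_id, pos, mm))
        return out

    def search(
        self,
        query: str,
        max_mismatch: int = 1,
        read_id: str = "",
        max_hits: int | None = None,
        exclude: tuple[str, int, str] | None = None,
    ) -> list[AlignmentHit]:
        """All ungapped full-length placements of ``query`` on both strands.

        ``exclude`` drops one (target_id, pos, strand) self-placement —
        used by repetitiveness scans that ask for *other* genome
        locations. Hits are sorted by (mismatches, target, pos, strand).
        """
        hits: list[AlignmentHit] = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            for target_id, pos, mm in self._search_strand(q, max_mismatch):
                if exclude is not None and (target_id, pos, strand) == exclude:
                    continue
                hits.append(AlignmentHit(read_id, target_id, pos, strand, len(mm), mm))
                if max_hits is not None and len(hits) >= max_hits:
                    break
            if max_hits is not None and len(hits) >= max_hits:
                break
        hits.sort(key=lambda h: (h.mismatches, h.target_id, h.pos, h.strand))
        return hits


def build_index(reference: Sequence[SequenceRecord], seed_len: int = 11) -> GenomeIndex:
    """Build the seed index used by :func:`align_read`."""
    return GenomeIndex(reference, seed_len=seed_len)


def align_read(read: QualityRead, index: GenomeIndex, max_mismatch: int = 1) -> list[AlignmentHit]:
    """All placements of a read with at most ``max_mismatch`` mismatches."""
    return index.search(read.seq, max_mismatch=max_mismatch, read_id=read.id)


def classify_placement(hits: Sequence[AlignmentHit], max_mismatch: int = 1) -> tuple[str, int, int]:
    """(placement, mapping_score, read_copy) from a read's hit list.

    read_copy counts the hits at the minimal mismatch count. A unique
    read with no competing placement scores 37; each sub-optimal
    competitor costs 10 (at most 3 are penalized, keeping the score
    non-negative); an ambiguous best placement scores 0.
    """
    if not hits:
        return "unmapped", 0, 0
    best_mm = min(h.mismatches for h in hits)
    read_copy = sum(1 for h in hits if h.mismatches == best_mm)
    if read_copy > 1:
        return "multiple", 0, read_copy
    subopt = len(hits) - 1
    score = UNIQUE_SCORE - SUBOPT_PENALTY * min(subopt, MAX_PENALIZED_COMPETITORS)
    return "unique", score, 1


def place_reads(
    reads: Iterable[QualityRead], index: GenomeIndex, max_mismatch: int = 1
) -> list[PlacedRead]:
    placed = []
    for read in reads:
        hits = align_read(read, index, max_mismatch=max_mismatch)
        placement, score, read_copy = classify_placement(hits, max_mismatch)
        best_mm = hits[0].mismatches if hits else 0
        best = tuple(h for h in hits if h.mismatches == best_mm)
        placed.append(PlacedRead(read, best, placement, score, read_copy))
    return placed


def oriented_observation(read: QualityRead, hit: AlignmentHit, offset: int) -> tuple[str, int]:
    """(base, quality) the read contributes at reference offset ``offset``."""
    if hit.strand == "+":
        return read.seq[offset], read.quals[offset]
    j = len(read.seq) - 1 - offset
    return revcomp(read.seq)[offset], read.quals[j]


def pileup(
    placed_reads: Sequence[PlacedRead], reference: Sequence[SequenceRecord]
) -> list[PileupColumn]:
    """Per-position base observations from uniquely placed reads only.

    Reverse-strand reads contribute complemented bases at the correct
    reference offsets. Columns are returned sorted by (target, pos);
    total observations equal the summed length of the unique reads.
    """
    seqs = {rec.id: rec.seq for rec in reference}
    columns: dict[tuple[str, int], PileupColumn] = {}
    for placed in placed_reads:
        if placed.placement != "unique":
            continue
        hit = placed.best_hits[0]
        read = placed.read
        oriented = read.seq if hit.strand == "+" else revcomp(read.seq)
        for j, base in enumerate(oriented):
            pos = hit.pos + j
            key = (hit.target_id, pos)
            col = columns.get(key)
            if col is None:
                col = PileupColumn(hit.target_id, pos, seqs[hit.target_id][pos], [])
                columns[key] = col
            q = read.quals[j] if hit.strand == "+" else read.quals[len(read.seq) - 1 - j]
            col.observations.append((base, q, read.id, hit.strand))
    return [columns[k] for k in sorted(columns)]


def coverage_stats(placed_reads: Sequence[PlacedRead]) -> tuple[int, float]:
    """(covered_bases, fold_coverage) over uniquely placed reads.

    covered_bases counts reference positions with at least one
    observation; fold_coverage is total aligned bases / covered bases
    (0.0 when nothing is covered).
    """
    covered: set[tuple[str, int]] = set()
    aligned_bases = 0
    for placed in placed_reads:
        if placed.placement != "unique":
            continue
        hit = placed.best_hits[0]
        L = len(placed.read.seq)
        aligned_bases += L
        for j in range(L):
            covered.add((hit.target_id, hit.pos + j))
    if not covered:
        return 0, 0.0
    return len(covered), aligned_bases / len(covered)
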