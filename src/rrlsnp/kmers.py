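"""33-mer occurrence profiling and pre-alignment read screening.

Before alignment, the read set is screened in two steps:

1. occurrence filtering — every distinct 33-mer is counted (strand
   literal, no canonicalization: the counts then sum to the raw read
   count) and reads whose 33-mer was sequenced 300 or more times are
   excluded as repetitive nuclear DNA or organelle contamination;
2. organelle screening — remaining reads that align ungapped to a
   chloroplast/mitochondrion reference on either strand with at most
   one mismatch are discarded.

The occurrence histogram is also summarised into a banded table
(occurrence category, unique 33-mers, reads, bases) in which the total
bases of every band equal 33 x reads — an internal arithmetic identity
asserted on every generated table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import QualityRead, SequenceRecord

__all__ = [
    "OccurrenceBin",
    "OccurrenceTable",
    "DEFAULT_BIN_EDGES",
    "count_kmers",
    "build_occurrence_table",
    "occurrence_table_from_profile",
    "filter_reads_by_occurrence",
    "screen_organelle",
]


@dataclass(frozen=True)
class OccurrenceBin:
    label: str
    min_occ: int
    max_occ: int  # inclusive; use a large sentinel for open-ended top bin
    unique_kmers: int
    reads: int
    bases: int


@dataclass(frozen=True)
class OccurrenceTable:
    k: int
    bins: tuple[OccurrenceBin, ...]
    total_unique_kmers: int
    total_reads: int
    total_bases: int

    def __post_init__(self) -> None:
        # the table's internal identities: bases = k * reads everywhere,
        # totals are the column sums
        for b in self.bins:
            if b.bases != self.k * b.reads:
                raise ValueError(f"bin {b.label}: bases != {self.k} * reads")
        if self.total_unique_kmers != sum(b.unique_kmers for b in self.bins):
            raise ValueError("unique-kmer total is not the column sum")
        if self.total_reads != sum(b.reads for b in self.bins):
            raise ValueError("read total is not the column sum")
        if self.total_bases != self.k * self.total_reads:
            raise ValueError("base total != k * read total")

    def fraction_at_most(self, max_occ: int) -> float:
        """Fraction of unique k-mers with occurrence <= max_occ."""
        low = sum(b.unique_kmers for b in self.bins if b.max_occ <= max_occ)
        return low / self.total_unique_kmers if self.total_unique_kmers else 0.0


_TOP = 10**12  # sentinel for the open-ended top bin

# Occurrence bands of the summary table, written (min, max) inclusive.
# The gel-report style labels "300-500" / "500 plus" and "15-20" / "20-34"
# overlap at their shared boundary; boundaries here are resolved downward
# (a count of 500 is "300-500", a count of 20 is "15-20").
DEFAULT_BIN_EDGES: tuple[tuple[str, int, int], ...] = (
    ("500 plus", 501, _TOP),
    ("300-500", 300, 500),
    ("100-299", 100, 299),
    ("35-99", 35, 99),
    ("20-34", 21, 34),
    ("15-20", 15, 20),
    ("11-14", 11, 14),
    ("9-10", 9, 10),
    ("7-8", 7, 8),
    ("6", 6, 6),
    ("5", 5, 5),
    ("4", 4, 4),
    ("3", 3, 3),
    ("2", 2, 2),
    ("1", 1, 1),
)


def count_kmers(reads: Iterable[QualityRead], k: int = 33) -> tuple[Counter, int]:
    """Count each read's leading k-mer (strand literal).

    In this pipeline reads are exactly k long so every read contributes
    its full sequence; shorter reads are skipped and counted. Returns
    (counter, n_skipped). Sum of counts == number of counted reads.
    """
    counts: Counter = Counter()
    skipped = 0
    for read in reads:
        if len(read.seq) < k:
            skipped += 1
            continue
        counts[read.seq[:k]] += 1
    return counts, skipped


def _check_edges(bin_edges: Sequence[tuple[str, int, int]]) -> None:
    spans = sorted((lo, hi) for _, lo, hi in bin_edges)
    for (lo, hi), (lo2, _) in zip(spans, spans[1:]):
        if lo2 <= hi:
            raise ValueError(f"overlapping occurrence bins at {lo2}")
        if lo2 != hi + 1:
            raise ValueError(f"occurrence bins leave a gap between {hi} and {lo2}")


def build_occurrence_table(
    counts: Counter,
    k: int = 33,
    bin_edges: Sequence[tuple[str, int, int]] = DEFAULT_BIN_EDGES,
) -> OccurrenceTable:
    """Summarise a k-mer occurrence histogram into banded form."""
    if not counts:
        raise ValueError("empty k-mer counts")
    _check_edges(bin_edges)
    bins = []
    for label, lo, hi in bin_edges:
        occs = [c for c in counts.values() if lo <= c <= hi]
        uniq = len(occs)
        reads = sum(occs)
        bins.append(OccurrenceBin(label, lo, hi, uniq, reads, k * reads))
    return OccurrenceTable(
        k,
        tuple(bins),
        total_unique_kmers=sum(b.unique_kmers for b in bins),
        total_reads=sum(b.reads for b in bins),
        total_bases=sum(b.bases for b in bins),
    )


def occurrence_table_from_profile(
    rows: Sequence[tuple[str, int, int, int]],
    k: int = 33,
    bin_edges: Sequence[tuple[str, int, int]] = DEFAULT_BIN_EDGES,
) -> OccurrenceTable:
    """Build an :class:`OccurrenceTable` from published per-band numbers.

    ``rows`` are (label, occurrence, unique_kmers, reads) with one row
    per band (occurrence is a representative count inside the band, used
    only to locate the band). Bases are recomputed as k * reads and the
    totals as column sums, so the table's arithmetic identities are
    verified rather than copied.
    """
    _check_edges(bin_edges)
    by_label = {label: (lo, hi) for label, lo, hi in bin_edges}
    bins = []
    for label, _occ, uniq, reads in rows:
        if label not in by_label:
            raise KeyError(f"unknown occurrence band {label!r}")
        lo, hi = by_label[label]
        bins.append(OccurrenceBin(label, lo, hi, uniq, reads, k * reads))
    return OccurrenceTable(
        k,
        tuple(bins),
        total_unique_kmers=sum(b.unique_kmers for b in bins),
        total_reads=sum(b.reads for b in bins),
        total_bases=sum(b.bases for b in bins),
    )


def filter_reads_by_occurrence(
    reads: Sequence[QualityRead],
    counts: Counter,
    max_occ: int = 299,
) -> tuple[list[QualityRead], list[QualityRead]]:
    """Partition reads by 33-mer occurrence: kept (<= max_occ) vs excluded.

    The default keeps occurrences up to 299: a 33-mer sequenced 300 or
    more times is taken to be repetitive or organellar.
    """
    kept, excluded = [], []
    for read in reads:
        if counts.get(read.seq, 0) > max_occ:
            excluded.append(read)
        else:
            kept.append(read)
    return kept, excluded


def screen_organelle(
    reads: Sequence[QualityRead],
    organelle_refs: Sequence[SequenceRecord],
    max_mismatch: int = 1,
) -> tuple[list[QualityRead], list[QualityRead]]:
    """Discard reads matching an organelle reference.

    A read is discarded iff it has an ungapped full-length placement on
    a chloroplast/mitochondrion sequence, either strand, with at most
    ``max_mismatch`` mismatches.
    """
    from .align import GenomeIndex  # local import to avoid a cycle

    if not organelle_refs:
        return list(reads), []
    read_len = max((len(r) for r in reads), default=33)
    seed_len = max(4, read_len // (max_mismatch + 1))
    index = GenomeIndex(organelle_refs, seed_len=seed_len)
    kept, discarded = [], []
    for read in reads:
        hits = index.search(read.seq, max_mismatch=max_mismatch, max_hits=1)
        (discarded if hits else kept).append(read)
    return kept, discarded
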