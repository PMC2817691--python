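"""Synthetic data: divergent accession, RRL short reads, contamination.

This module generates everything the wet lab would otherwise supply, with
complete truth tracking so the downstream caller can be scored exactly:

* :func:`random_genome` — an i.i.d. random reference sequence;
* :func:`mutate_genome` — a divergent accession at a given per-bp SNP
  rate (default 1/425 bp, the nucleotide diversity of wild soybean
  relative to the cultivated reference, theta ~= 0.00235);
* :func:`spike_repeats` — insertion of a high-copy repeat family to
  emulate repetitive nuclear DNA;
* :func:`sample_reads` — 33 bp reads from size-selected RRL fragments
  with per-base miscalls and matching quality scores, plus optional
  organelle contamination reads.

Only substitutions are simulated, never indels: the downstream aligner
and caller operate on ungapped full-length placements of 33-mers, so
indel variation would simply drop reads rather than create calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .digest import Fragment
from .seqio import QualityRead, SequenceRecord, revcomp

__all__ = [
    "TruthSnp",
    "SimConfig",
    "random_genome",
    "mutate_genome",
    "spike_repeats",
    "sample_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TruthSnp:
    """A planted substitution: the ground truth a caller should recover."""

    source_id: str
    pos: int  # 0-based coordinate on the reference
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for read simulation.

    Defaults encode the emulated experiment: 33 bp tags, one SNP per
    425 bp of divergence, modest sequencing error with qualities on the
    0-40 scale.
    """

    snp_rate: float = 1.0 / 425.0
    read_len: int = 33
    depth_target: float = 10.0  # mean fold-coverage of selected fragments
    error_rate: float = 0.002
    organelle_fraction: float = 0.0
    base_quality: int = 35  # constant per-base quality profile
    end_sampling: bool = True  # reads start at fragment ends (short-insert library)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "error_rate", "organelle_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.base_quality <= 40:
            raise ValueError("base_quality outside [0, 40]")


def random_genome(length: int, seed: int, gc: float = 0.35, id: str = "chr1") -> SequenceRecord:
    """An i.i.d. random nucleotide sequence (soybean-like GC by default)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=p).tobytes().decode()
    return SequenceRecord(id, seq)


def mutate_genome(
    reference: SequenceRecord, snp_rate: float, seed: int
) -> tuple[SequenceRecord, list[TruthSnp]]:
    """Derive a divergent accession by independent per-base substitution.

    Each non-N base mutates with probability ``snp_rate`` to a uniformly
    chosen different base. Returns the variant genome (same length) and
    the complete, position-sorted truth table.
    """
    if not 0.0 <= snp_rate <= 1.0:
        raise ValueError("snp_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(reference.seq.encode(), dtype="S1").copy()
    eligible = arr != b"N"
    hits = np.flatnonzero(eligible & (rng.random(arr.size) < snp_rate))
    truth: list[TruthSnp] = []
    for pos in hits:
        ref = arr[pos].decode()
        alt = rng.choice([b for b in "ACGT" if b != ref])
        arr[pos] = alt.encode()
        truth.append(TruthSnp(reference.id, int(pos), ref, alt))
    return SequenceRecord(reference.id, arr.tobytes().decode()), truth


def spike_repeats(
    reference: SequenceRecord, repeat_unit: str, copies: int, seed: int
) -> tuple[SequenceRecord, list[int]]:
    """Insert ``copies`` copies of a repeat unit at random positions.

    Returns the lengthened sequence and the insertion coordinates *in
    the output sequence* (sorted), for truth tracking. Output length is
    input length + copies * len(repeat_unit).
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if copies == 0:
        return reference, []
    rng = np.random.default_rng(seed)
    offsets = sorted(int(x) for x in rng.integers(0, len(reference.seq) + 1, size=copies))
    pieces: list[str] = []
    insertion_points: list[int] = []
    prev = 0
    shift = 0
    for off in offsets:
        pieces.append(reference.seq[prev:off])
        insertion_points.append(off + shift)
        pieces.append(repeat_unit)
        shift += len(repeat_unit)
        prev = off
    pieces.append(reference.seq[prev:])
    return SequenceRecord(reference.id, "".join(pieces)), insertion_points


def _qualities_for(seq_len: int, q: int) -> tuple[int, ...]:
    return (q,) * seq_len


def _apply_errors(window: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return window
    chars = list(window)
    for i, base in enumerate(chars):
        if base != "N" and rng.random() < error_rate:
            chars[i] = rng.choice([b for b in "ACGT" if b != base])
    return "".join(chars)


def sample_reads(
    fragments: Sequence[Fragment],
    config: SimConfig,
    organelle: Sequence[SequenceRecord] = (),
) -> tuple[list[QualityRead], int]:
    """Simulate sequencing of size-selected RRL fragments.

    In the default end-sampling mode each sampled read is the first
    ``read_len`` bases of one fragment end (either end, so either
    strand), mimicking a short-insert library where sequencing always
    starts at a ligated fragment end; a uniform-offset mode is available
    via ``config.end_sampling=False``. The number of reads per fragment
    is Poisson with mean ``depth_target * read_len_fraction`` chosen so
    the expected fold-coverage of the selected fragments is
    ``depth_target``. Each base is miscalled with ``error_rate`` and the
    assigned quality is q = round(-10*log10(error_rate)) capped at 40
    (or ``base_quality`` when error_rate is 0).

    With ``organelle_fraction`` > 0 and organelle reference sequences
    supplied, that fraction of reads (in expectation) is drawn uniformly
    from the organelle sequences instead, with provenance recorded.

    Returns (reads, n_fragments_skipped_too_short).
    """
    rng = np.random.default_rng(config.seed)
    L = config.read_len
    if config.error_rate > 0:
        q = min(40, int(round(-10.0 * np.log10(config.error_rate))))
    else:
        q = config.base_quality
    reads: list[QualityRead] = []
    skipped = 0
    serial = 0
    usable = [f for f in fragments if len(f) >= L]
    skipped = len(fragments) - len(usable)

    def emit(window: str, source_id: str, start: int, strand: str) -> None:
        nonlocal serial
        if strand == "-":
            window = revcomp(window)
        seq = _apply_errors(window, rng, config.error_rate)
        reads.append(
            QualityRead(
                f"read{serial:07d}",
                seq,
                _qualities_for(L, q),
                source=(source_id, start, strand),
            )
        )
        serial += 1

    for frag in usable:
        # expected reads per fragment so that mean per-base coverage of the
        # fragment equals depth_target: n * L / len(frag) = depth
        mean_reads = config.depth_target * len(frag) / L
        n = int(rng.poisson(mean_reads))
        for _ in range(n):
            if config.end_sampling:
                if rng.random() < 0.5:  # left end, forward read
                    start = frag.start
                    window = frag.seq[:L]
                    strand = "+"
                else:  # right end, reverse read
                    start = frag.end - L
                    window = frag.seq[-L:]
                    strand = "-"
            else:
                off = int(rng.integers(0, len(frag) - L + 1))
                start = frag.start + off
                window = frag.seq[off : off + L]
                strand = "+" if rng.random() < 0.5 else "-"
            emit(window, frag.source_id, start, strand)

    if config.organelle_fraction > 0 and organelle:
        # contamination reads on top, so that they are the stated fraction
        # of the final read set in expectation
        n_nuclear = len(reads)
        frac = config.organelle_fraction
        n_org = int(rng.poisson(n_nuclear * frac / (1.0 - frac))) if frac < 1 else 0
        pool = [rec for rec in organelle if len(rec.seq) >= L]
        for _ in range(n_org):
            rec = pool[int(rng.integers(0, len(pool)))]
            off = int(rng.integers(0, len(rec.seq) - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            emit(rec.seq[off : off + L], rec.id, off, strand)

    return reads, skipped
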