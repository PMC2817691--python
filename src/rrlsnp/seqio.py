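"""Sequence records, FASTA/FASTQ I/O and base-level utilities.

Every other stage of the pipeline works with the two small containers
defined here: :class:`SequenceRecord` for reference sequences and
:class:`QualityRead` for short sequencing reads (33 bp tags with
per-base Phred-like qualities capped at 40).

Conventions fixed here and relied on everywhere else:

* nucleotide alphabet is ``{A, C, G, T, N}`` upper case; ``N`` marks
  assembly gaps and never satisfies any IUPAC pattern position, so no
  restriction cut or alignment is ever placed inside a gap;
* FASTQ is Phred+33 only, quality range 0-40;
* FASTA output is wrapped at 80 columns.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "SequenceRecord",
    "QualityRead",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "revcomp",
    "complement_base",
    "iupac_match",
    "IUPAC",
]

DNA_ALPHABET = frozenset("ACGTN")

# IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input; message names the line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QualityRead:
    """A short read with per-base quality scores in [0, 40].

    ``source`` optionally records truth provenance for simulated reads
    as ``(source_id, start, strand)`` in source coordinates.
    """

    id: str
    seq: str
    quals: tuple[int, ...]
    source: tuple[str, int, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.seq)} bases but {len(self.quals)} qualities"
            )
        if any(q < 0 or q > 40 for q in self.quals):
            raise ValueError(f"read {self.id!r}: quality outside [0, 40]")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r}: bad characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Sequences are uppercased; the DNA alphabet is enforced (``U`` is
    rejected: this is a DNA pipeline). Malformed input raises
    :class:`FormatError` naming the offending line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_chunks: list[str] = []
    cur_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_chunks)
        if not seq:
            raise FormatError(f"line {cur_line}: record {cur_id!r} has no sequence")
        try:
            records.append(SequenceRecord(cur_id, seq))
        except ValueError as exc:
            raise FormatError(f"record ending near line {cur_line}: {exc}") from exc

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                if not cur_id:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                if cur_id in seen:
                    raise FormatError(f"line {lineno}: duplicate record id {cur_id!r}")
                seen.add(cur_id)
                cur_chunks = []
                cur_line = lineno
            else:
                if cur_id is None:
                    raise FormatError(f"line {lineno}: sequence before first '>' header")
                cur_chunks.append(line.upper())
                cur_line = lineno
        flush()
    if not records:
        raise FormatError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[QualityRead]:
    """Read 4-line Phred+33 FASTQ; raises :class:`FormatError` on defects."""
    reads: list[QualityRead] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        raise FormatError(f"truncated FASTQ: {len(lines)} lines is not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"line {lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"line {lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise FormatError(
                f"line {lineno}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        quals = tuple(ord(c) - 33 for c in qual)
        if any(q < 0 for q in quals):
            raise FormatError(f"line {lineno + 3}: quality character below '!' (Phred+33)")
        try:
            reads.append(QualityRead(head[1:].split()[0], seq.upper(), quals))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualityRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} plus IUPAC ambiguity codes."""
    bad = set(seq) - set("ACGTNRYSWKMBDHV")
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def iupac_match(pattern: str, window: str) -> bool:
    """True iff ``window`` satisfies the IUPAC ``pattern`` position-wise.

    A genomic ``N`` (assembly gap) never satisfies any pattern position,
    pattern ``N`` included: gaps must not look like restriction sites or
    alignment targets.
    """
    if len(pattern) != len(window):
        raise ValueError(f"pattern length {len(pattern)} != window length {len(window)}")
    for code, base in zip(pattern, window):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"unknown IUPAC code {code!r}")
        if base not in allowed:  # genomic N is in no code's set
            return False
    return True


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield (offset, k-mer) for every window of length k."""
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]
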