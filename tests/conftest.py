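"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's seeded/indexed code
paths: digestion is checked against a window-by-window IUPAC scan,
alignment against an exhaustive Hamming scan of every placement, and
flank repetitiveness against a full all-window scan.
"""

from __future__ import annotations

import numpy as np
import pytest

from rrlsnp.seqio import IUPAC, QualityRead, SequenceRecord, revcomp


def random_seq(n: int, seed: int, alphabet: str = "ACGT") -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def small_genome() -> SequenceRecord:
    return SequenceRecord("chr1", random_seq(5_000, seed=42))


def brute_force_cuts(seq: str, enzymes) -> set[int]:
    """Every blunt cut position by scanning all windows on both strands."""
    cuts: set[int] = set()
    for enz in enzymes:
        for pattern, offset in (
            (enz.site, enz.cut_offset),
            (revcomp(enz.site), len(enz.site) - enz.cut_offset),
        ):
            m = len(pattern)
            for i in range(len(seq) - m + 1):
                window = seq[i : i + m]
                if all(b in IUPAC[c] for c, b in zip(pattern, window)):
                    cuts.add(i + offset)
    return {c for c in cuts if 0 < c < len(seq)}


def brute_force_placements(query: str, refs: dict[str, str], max_mismatch: int):
    """Every ungapped full-length placement (target, pos, strand, mismatches).

    Reference N matches nothing, mirroring the aligner's gap rule.
    """
    out = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        for target, seq in refs.items():
            for pos in range(len(seq) - len(q) + 1):
                window = seq[pos : pos + len(q)]
                mm = sum(1 for a, b in zip(window, q) if a != b or a == "N")
                if mm <= max_mismatch:
                    out.add((target, pos, strand, mm))
    return out


def make_reads(seqs, q: int = 35) -> list[QualityRead]:
    return [QualityRead(f"r{i}", s, (q,) * len(s)) for i, s in enumerate(seqs)]
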