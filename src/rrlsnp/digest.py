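"""In-silico reduced-representation-library construction.

A reduced representation library (RRL) subsamples a genome by complete
restriction digestion with a cocktail of blunt-end enzymes followed by
gel size selection (here 100-150 bp inclusive). Because digestion is
sequence-deterministic, different genotypes of the same species yield
largely the same fragment set, which is what makes deep resequencing of
an RRL informative for SNP discovery.

The default enzyme cocktail is the five-blunt-cutter set used for
soybean RRL construction (HaeIII, PsiI, SspI, RsaI, MslI); recognition
sites and blunt cut offsets follow REBASE. Candidate cocktails can be
ranked by an electrophoresis-banding surrogate: a "band" is a distinct
fragment sequence in the size window present at high copy number, and
the least-banding cocktail is preferred because visible bands betray
repetitive DNA that would dominate the library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import SequenceRecord, iupac_match, revcomp

__all__ = [
    "RestrictionEnzyme",
    "Fragment",
    "DEFAULT_ENZYMES",
    "get_enzymes",
    "find_cut_positions",
    "digest",
    "size_select",
    "rank_enzyme_sets",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A blunt cutter: IUPAC recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (0 < self.cut_offset < len(self.site)):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside site {self.site!r}"
            )


# Recognition sites and blunt cut positions per REBASE.
DEFAULT_ENZYMES: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("HaeIII", "GGCC", 2),
    RestrictionEnzyme("PsiI", "TTATAA", 3),
    RestrictionEnzyme("SspI", "AATATT", 3),
    RestrictionEnzyme("RsaI", "GTAC", 2),
    RestrictionEnzyme("MslI", "CAYNNNNRTG", 5),
)

_BY_NAME = {e.name.lower(): e for e in DEFAULT_ENZYMES}


def get_enzymes(names: Iterable[str]) -> list[RestrictionEnzyme]:
    """Resolve enzyme names (case-insensitive) against the built-in set."""
    out = []
    for name in names:
        enz = _BY_NAME.get(name.strip().lower())
        if enz is None:
            raise KeyError(f"unknown enzyme {name!r}; known: {[e.name for e in DEFAULT_ENZYMES]}")
        out.append(enz)
    return out


@dataclass(frozen=True)
class Fragment:
    """A digestion product: half-open interval [start, end) on its source."""

    source_id: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("fragment interval does not match its sequence length")

    def __len__(self) -> int:
        return len(self.seq)


def find_cut_positions(seq: str, enzymes: Sequence[RestrictionEnzyme]) -> list[int]:
    """All blunt cut positions of a complete digest, deduplicated and sorted.

    Sites are located by IUPAC window matching on both strands; genomic N
    satisfies no pattern position, so sites spanning assembly gaps never
    cut. For a palindromic site the bottom-strand scan rediscovers the
    same cuts; non-palindromic sites are handled by also scanning the
    reverse-complement pattern with the mirrored cut offset.
    """
    cuts: set[int] = set()
    for enz in enzymes:
        patterns = {enz.site: enz.cut_offset}
        rc = revcomp(enz.site)
        # blunt cut mirrors across the site midpoint on the bottom strand
        patterns.setdefault(rc, len(enz.site) - enz.cut_offset)
        for pattern, offset in patterns.items():
            m = len(pattern)
            for i in range(len(seq) - m + 1):
                if iupac_match(pattern, seq[i : i + m]):
                    cuts.add(i + offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(record: SequenceRecord, enzymes: Sequence[RestrictionEnzyme]) -> list[Fragment]:
    """Complete digestion of one sequence: fragments tile the input.

    Every site occurrence on either strand is cut (overnight complete
    digest; partial-digest kinetics are not modelled).
    """
    if not enzymes:
        raise ValueError("need at least one enzyme")
    cuts = find_cut_positions(record.seq, enzymes)
    bounds = [0, *cuts, len(record.seq)]
    return [
        Fragment(record.id, a, b, record.seq[a:b])
        for a, b in zip(bounds, bounds[1:])
    ]


def size_select(
    fragments: Iterable[Fragment], min_len: int = 100, max_len: int = 150
) -> list[Fragment]:
    """Gel size selection: keep fragments with min_len <= length <= max_len."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [f for f in fragments if min_len <= len(f) <= max_len]


def rank_enzyme_sets(
    record: SequenceRecord,
    candidate_sets: dict[str, Sequence[RestrictionEnzyme]],
    window: tuple[int, int] = (100, 150),
    band_copy_threshold: int = 10,
) -> list[tuple[str, int]]:
    """Rank enzyme cocktails by a gel-banding surrogate, fewest bands first.

    band_count = number of distinct fragment sequences inside the size
    window whose copy number is >= band_copy_threshold (a visible band on
    a gel is a high-copy identical fragment). Ties are broken by set name.
    """
    if not candidate_sets:
        raise ValueError("need at least one candidate enzyme set")
    ranked: list[tuple[str, int]] = []
    for name, enzymes in candidate_sets.items():
        selected = size_select(digest(record, enzymes), *window)
        copy_numbers: dict[str, int] = {}
        for frag in selected:
            copy_numbers[frag.seq] = copy_numbers.get(frag.seq, 0) + 1
        bands = sum(1 for n in copy_numbers.values() if n >= band_copy_threshold)
        ranked.append((name, bands))
    ranked.sort(key=lambda item: (item[1], item[0]))
    return ranked
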