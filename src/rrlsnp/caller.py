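"""Consensus SNP calling and the two filter cascades.

Candidate SNPs are pileup positions whose quality-weighted consensus
base differs from the reference. Candidates then pass through one of two
rule cascades modelled on the two families of filters used in RRL SNP
discovery, each recording a per-candidate ledger of every rule applied:

* the alignment-identity cascade (``GMAP`` mode): quality-screened
  reads, unique full-length placement, unanimity of the covering reads,
  a both-25-bp-flanks repetitiveness exclusion, at least two supporting
  reads, and no N near the site;

* the consensus-quality cascade (``VMS`` / ``VSS`` / ``PRODUCTION``
  modes): no second SNP within a 25-base window, an unambiguous
  consensus base, a minimum consensus quality (20 for the validation
  runs, 27 for the production run), an average read copy of exactly
  1.00, a minimum mapping score of 30 for every supporting read, at
  least two supporting reads in VMS only, and mode-specific flank
  repetitiveness rules (121 nt N-free context with the both-flanks rule
  for VMS/VSS; 601 nt N-free context with a >1/3-repetitive-windows rule
  for the production run).

The consensus quality is the capped quality-sum difference
``min(60, sum q(supporting) - sum q(discordant))`` — a deterministic
stand-in for a Bayesian consensus score that is monotone in both support
and opposition, which is all the cascades require of it.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Sequence

from .align import GenomeIndex, PileupColumn, PlacedRead
from .seqio import SequenceRecord

__all__ = [
    "SnpCandidate",
    "FilterConfig",
    "call_consensus",
    "candidate_snps",
    "density_filter",
    "flank_repetitive",
    "gmap_cascade",
    "maq_cascade",
    "write_snp_report",
]

CONSENSUS_QUALITY_CAP = 60
FLANK_LEN = 25
FLANK_MAX_MISMATCH = 2
PRODUCTION_HIT_THRESHOLD = 5  # a window is repetitive at >= 5 other positions
PRODUCTION_FLANK_REGION = 300
PRODUCTION_REPETITIVE_FRACTION = 1.0 / 3.0


@dataclass
class SnpCandidate:
    target_id: str
    pos: int  # 0-based
    ref_base: str
    consensus_base: str
    consensus_quality: int
    support: int  # uniquely placed reads showing the consensus (alt) base
    conflict: int  # reads showing any other base at the site
    avg_read_copy: float
    supporting_reads: tuple[str, ...] = ()
    min_support_map_score: int = 0
    filter_ledger: list[tuple[str, bool]] = field(default_factory=list)

    def record(self, rule: str, passed: bool) -> bool:
        self.filter_ledger.append((rule, passed))
        return passed

    @property
    def passed_all(self) -> bool:
        return all(ok for _, ok in self.filter_ledger)

    @property
    def first_failed_rule(self) -> str | None:
        for rule, ok in self.filter_ledger:
            if not ok:
                return rule
        return None


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of one cascade run; ``mode`` fixes the defaults."""

    mode: str  # GMAP | VMS | VSS | PRODUCTION
    min_base_q: int = 10  # GMAP read screen
    min_consensus_q: int = 20
    min_support: int = 2
    min_map_score: int = 30
    density_window: int = 25
    center_region: int = 121  # N-free context length, centered on the SNP
    flank_region: int = FLANK_LEN  # per-side repetitiveness scan length
    pooled_flank_fraction: bool = True  # production: pool both flanks

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "FilterConfig":
        mode = mode.upper()
        if mode == "GMAP":
            base = dict(min_support=2, center_region=51)
        elif mode == "VMS":
            base = dict(min_consensus_q=20, min_support=2, center_region=121)
        elif mode == "VSS":
            base = dict(min_consensus_q=20, min_support=1, center_region=121)
        elif mode == "PRODUCTION":
            base = dict(
                min_consensus_q=27,
                min_support=1,
                center_region=601,
                flank_region=PRODUCTION_FLANK_REGION,
            )
        else:
            raise ValueError(f"unknown filter mode {mode!r}")
        base.update(overrides)
        return cls(mode=mode, **base)


def call_consensus(column: PileupColumn) -> tuple[str, int]:
    """Quality-weighted consensus of one pileup column.

    The consensus base is the base with the largest summed quality;
    consensus quality is the quality-sum margin over all discordant
    observations, clipped to [0, 60]. A tie yields ("N", 0), which the
    ambiguity rule downstream eliminates.
    """
    if not column.observations:
        raise ValueError("empty pileup column")
    weight: Counter = Counter()
    for base, q, _read_id, _strand in column.observations:
        weight[base] += q
    ranked = weight.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "N", 0
    best, w = ranked[0]
    quality = max(0, min(CONSENSUS_QUALITY_CAP, 2 * w - sum(weight.values())))
    return best, quality


def candidate_snps(
    pileup_columns: Sequence[PileupColumn],
    placed_reads: Sequence[PlacedRead],
) -> list[SnpCandidate]:
    """One candidate per column whose consensus differs from the reference.

    ``avg_read_copy`` and the minimum mapping score are taken over the
    reads supporting the consensus base; because the pileup admits only
    unique placements, read copy is 1.00 by construction — the filters
    still assert it.
    """
    by_id = {p.read.id: p for p in placed_reads}
    out: list[SnpCandidate] = []
    for col in pileup_columns:
        if col.ref_base == "N":
            continue
        base, quality = call_consensus(col)
        if base == col.ref_base:
            continue
        supporting = [obs for obs in col.observations if obs[0] == base]
        conflicting = [obs for obs in col.observations if obs[0] != base]
        support_ids = tuple(obs[2] for obs in supporting)
        copies = [by_id[rid].read_copy for rid in support_ids if rid in by_id]
        scores = [by_id[rid].mapping_score for rid in support_ids if rid in by_id]
        out.append(
            SnpCandidate(
                target_id=col.target_id,
                pos=col.pos,
                ref_base=col.ref_base,
                consensus_base=base,
                consensus_quality=quality,
                support=len(supporting),
                conflict=len(conflicting),
                avg_read_copy=(sum(copies) / len(copies)) if copies else 0.0,
                supporting_reads=support_ids,
                min_support_map_score=min(scores) if scores else 0,
            )
        )
    out.sort(key=lambda c: (c.target_id, c.pos))
    return out


def density_filter(
    candidates: Sequence[SnpCandidate], window: int = 25
) -> tuple[set[tuple[str, int]], dict[tuple[str, int], bool]]:
    """Mark candidates with a neighbour closer than ``window`` bases.

    Two or more SNPs within a 25-base window are all eliminated: any
    candidate with another candidate on the same target at pairwise
    distance < window fails. Returns (failing keys, pass map).
    """
    by_target: dict[str, list[int]] = defaultdict(list)
    for c in candidates:
        by_target[c.target_id].append(c.pos)
    failing: set[tuple[str, int]] = set()
    for target, positions in by_target.items():
        positions.sort()
        for a, b in zip(positions, positions[1:]):
            if b - a < window:
                failing.add((target, a))
                failing.add((target, b))
    passes = {(c.target_id, c.pos): (c.target_id, c.pos) not in failing for c in candidates}
    return failing, passes


def _flank_capable(index: GenomeIndex) -> GenomeIndex:
    """An index whose seed length supports 25-mer / 2-mismatch searches.

    The read aligner's index typically uses a longer seed; the flank
    scan needs seeds of at most floor(25/3) = 8 for its pigeonhole
    guarantee. A derived index is built once and cached on the original.
    """
    max_seed = FLANK_LEN // (FLANK_MAX_MISMATCH + 1)
    if index.seed_len <= max_seed:
        return index
    cached = getattr(index, "_flank_index", None)
    if cached is None:
        cached = GenomeIndex(index.records, seed_len=max_seed)
        index._flank_index = cached
    return cached


def flank_repetitive(
    index: GenomeIndex,
    target_id: str,
    pos: int,
    mode: str = "VMS",
    flank_region: int = PRODUCTION_FLANK_REGION,
) -> tuple[bool, bool] | float:
    """Repetitiveness of the sequence flanking a SNP site.

    GMAP/VMS/VSS modes test the single 25-mer immediately upstream and
    the single 25-mer immediately downstream: a flank is repetitive iff
    it matches at least one *other* genome location, either strand, with
    at most two mismatches; returns (upstream_flag, downstream_flag).

    PRODUCTION mode slides every 25-mer window across the ``flank_region``
    nt upstream and downstream regions; a window is repetitive iff it
    hits five or more other positions with at most two mismatches;
    returns the repetitive fraction pooled over both flanks. Windows
    truncated by a sequence end are simply not scanned; windows
    containing N cannot match anything and count as non-repetitive.
    """
    index = _flank_capable(index)
    seq = index.seqs[target_id]

    def window_hits(start: int) -> int:
        if start < 0 or start + FLANK_LEN > len(seq):
            return -1  # truncated: no window here
        window = seq[start : start + FLANK_LEN]
        if "N" in window:
            return 0
        hits = index.search(
            window,
            max_mismatch=FLANK_MAX_MISMATCH,
            exclude=(target_id, start, "+"),
        )
        return len(hits)

    mode = mode.upper()
    if mode in ("GMAP", "VMS", "VSS"):
        up = window_hits(pos - FLANK_LEN)
        down = window_hits(pos + 1)
        return (up >= 1, down >= 1)
    if mode == "PRODUCTION":
        starts = []
        for s in range(pos - flank_region, pos - FLANK_LEN + 1):
            starts.append(s)
        for s in range(pos + 1, pos + 1 + flank_region - FLANK_LEN + 1):
            starts.append(s)
        counts = [window_hits(s) for s in starts]
        valid = [c for c in counts if c >= 0]
        if not valid:
            return 0.0
        repetitive = sum(1 for c in valid if c >= PRODUCTION_HIT_THRESHOLD)
        return repetitive / len(valid)
    raise ValueError(f"unknown flank mode {mode!r}")


def _center_region_n_free(seq: str, pos: int, region: int) -> bool:
    half = region // 2
    lo = max(0, pos - half)
    hi = min(len(seq), pos + half + 1)
    return "N" not in seq[lo:hi]


def gmap_cascade(
    candidates: Sequence[SnpCandidate],
    placed_reads: Sequence[PlacedRead],
    index: GenomeIndex,
    config: FilterConfig | None = None,
    repetitive_read_ids: frozenset[str] = frozenset(),
) -> list[SnpCandidate]:
    """Alignment-identity filter cascade (direct base comparison, no
    consensus quality).

    Rules, in order, each recorded in the candidate's ledger:

    1. every supporting read passed the base-quality screen (no base
       with q < ``min_base_q``; screened reads are identified upstream
       and passed via ``repetitive_read_ids``-style exclusion at pileup
       time — here re-asserted per candidate);
    2. every supporting read is uniquely placed, full length, and not
       flagged repetitive by the 33-mer occurrence screen;
    3. no conflicting nucleotides among the covering reads (unanimity);
    4. not both 25-bp flanks repetitive;
    5. at least ``min_support`` supporting reads;
    6. no N in the emitted flanking context.
    """
    if config is None:
        config = FilterConfig.for_mode("GMAP")
    by_id = {p.read.id: p for p in placed_reads}
    kept: list[SnpCandidate] = []
    for cand in candidates:
        c = replace(cand, filter_ledger=[])
        support = [by_id[r] for r in c.supporting_reads if r in by_id]
        ok = c.record(
            "read_quality",
            all(min(p.read.quals) >= config.min_base_q for p in support),
        )
        ok &= c.record(
            "unique_placement",
            bool(support)
            and all(p.placement == "unique" for p in support)
            and not any(p.read.id in repetitive_read_ids for p in support),
        )
        ok &= c.record("no_conflict", c.conflict == 0)
        up_rep, down_rep = flank_repetitive(index, c.target_id, c.pos, mode="GMAP")
        ok &= c.record("flank_repeat", not (up_rep and down_rep))
        ok &= c.record("min_support", c.support >= config.min_support)
        ok &= c.record(
            "no_N_context",
            _center_region_n_free(index.seqs[c.target_id], c.pos, config.center_region),
        )
        kept.append(c)
    return [c for c in kept if c.passed_all]


def maq_cascade(
    candidates: Sequence[SnpCandidate],
    placed_reads: Sequence[PlacedRead],
    index: GenomeIndex,
    config: FilterConfig,
) -> list[SnpCandidate]:
    """Consensus-quality filter cascade (VMS / VSS / PRODUCTION modes).

    See the module docstring for the rule list; every rule outcome is
    recorded in each candidate's ledger and a candidate passes iff all
    rules pass. Organelle-matching reads are assumed removed upstream.
    """
    if config.mode not in ("VMS", "VSS", "PRODUCTION"):
        raise ValueError(f"maq_cascade needs mode VMS/VSS/PRODUCTION, got {config.mode}")
    failing, _ = density_filter(candidates, window=config.density_window)
    out: list[SnpCandidate] = []
    for cand in candidates:
        c = replace(cand, filter_ledger=[])
        ok = c.record("snp_density", (c.target_id, c.pos) not in failing)
        ok &= c.record("unambiguous_consensus", c.consensus_base in "ACGT")
        ok &= c.record("consensus_quality", c.consensus_quality >= config.min_consensus_q)
        ok &= c.record("read_copy", c.support > 0 and abs(c.avg_read_copy - 1.0) < 1e-12)
        ok &= c.record("mapping_score", c.min_support_map_score >= config.min_map_score)
        ok &= c.record("min_support", c.support >= config.min_support)
        seq = index.seqs[c.target_id]
        ok &= c.record(
            "no_N_context", _center_region_n_free(seq, c.pos, config.center_region)
        )
        if config.mode in ("VMS", "VSS"):
            up_rep, down_rep = flank_repetitive(index, c.target_id, c.pos, mode=config.mode)
            ok &= c.record("flank_repeat", not (up_rep and down_rep))
        else:
            frac = flank_repetitive(
                index, c.target_id, c.pos, mode="PRODUCTION", flank_region=config.flank_region
            )
            ok &= c.record("flank_repeat", frac <= PRODUCTION_REPETITIVE_FRACTION)
        out.append(c)
    return [c for c in out if c.passed_all]


def write_snp_report(
    candidates: Sequence[SnpCandidate],
    vcf_path,
    ledger_path=None,
    reference_ids: Sequence[str] = (),
    sample: str = "accession",
) -> None:
    """Write candidates as a VCF 4.2 file plus an optional ledger TSV.

    POS is 1-based; QUAL is the consensus quality; FILTER is PASS or the
    first failing rule; INFO carries support depth and average read copy.
    The ledger TSV has one row per candidate per rule evaluated.
    """
    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting read depth">\n')
        vcf.write('##INFO=<ID=RC,Number=1,Type=Float,Description="Average read copy of supporting reads">\n')
        vcf.write('##INFO=<ID=CF,Number=1,Type=Integer,Description="Conflicting observations">\n')
        for rid in reference_ids:
            vcf.write(f"##contig=<ID={rid}>\n")
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(candidates, key=lambda c: (c.target_id, c.pos)):
            filt = "PASS" if c.passed_all or not c.filter_ledger else c.first_failed_rule
            alt = c.consensus_base if c.consensus_base in "ACGT" else "."
            vcf.write(
                f"{c.target_id}\t{c.pos + 1}\t.\t{c.ref_base}\t{alt}\t"
                f"{c.consensus_quality}\t{filt}\t"
                f"DP={c.support};RC={c.avg_read_copy:.2f};CF={c.conflict}\n"
            )
    if ledger_path is not None:
        with open(ledger_path, "w") as tsv:
            tsv.write("target\tpos\trule\tpassed\n")
            for c in candidates:
                for rule, passed in c.filter_ledger:
                    tsv.write(f"{c.target_id}\t{c.pos + 1}\t{rule}\t{int(passed)}\n")
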