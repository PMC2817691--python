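# Methods

`rrlsnp` re-creates, end to end and on fully synthetic data, a
reduced-representation-library (RRL) SNP discovery workflow for a large
plant genome: in-silico restriction digestion and size selection, short
33 bp read simulation, 33-mer occurrence screening, seeded ungapped
alignment, consensus SNP calling under two filter cascades, and the
downstream use of the resulting markers — recombinant-inbred-line (RIL)
genetic mapping and scaffold anchoring/orientation. This note records
the models, the parameters that matter, and the places where the design
was genuinely open.

## The reduced representation library

An RRL subsamples a genome deterministically: a cocktail of blunt-end
restriction enzymes digests the DNA to completion and a gel slice keeps
fragments of 100–150 bp (inclusive). Because digestion is a pure
function of sequence, two accessions of the same species yield largely
the same fragment subset, which is what makes deep resequencing of an
RRL informative for SNP discovery between a reference cultivar and a
divergent accession.

Digestion is simulated as *complete*: every site occurrence on either
strand is cut (the emulated protocol digests overnight; partial-digest
kinetics would only blur the size selection, which dominates library
content anyway). Sites are located by IUPAC window matching, which is
needed for MslI's degenerate site CAYNN^NNRTG. One deliberate rule
shapes everything downstream: a genomic `N` (assembly gap) satisfies
*no* pattern position, pattern `N` included. No cut, seed, or alignment
is therefore ever placed inside a gap.

The default cocktail is HaeIII, PsiI, SspI, RsaI and MslI (sites and
blunt cut offsets per REBASE). Cocktails can be ranked by a gel-banding
surrogate: a "band" is a distinct fragment sequence in the size window
present at ≥ `band_copy_threshold` copies (default 10), and fewer bands
is better, since a visible band is high-copy — i.e. repetitive — DNA
that would swamp the library. The copy-number surrogate is our
formalization; gel visibility has no crisp published model, and the
threshold is an explicit config knob.

## Synthetic study conditions

The generator's defaults are the emulated study's conditions:

| parameter | default | meaning |
|---|---|---|
| `snp_rate` | 1/425 per bp | divergence of the wild accession vs the reference (θ ≈ 0.00235) |
| `read_len` | 33 bp | sequencing tag length |
| `depth_target` | 10 | expected sequenced bases per selected fragment / fragment length |
| `error_rate` | 0.002 per base | miscall probability; implies base quality q = round(−10·log10 e) = 27 |
| `base_quality` | 35 | constant quality profile when `error_rate` is 0 (0–40 scale) |
| `organelle_fraction` | 0.05 in the pipeline demo | chloroplast contamination share of reads |

Mutation is independent per-base substitution to a uniformly chosen
different base, with a complete, sorted truth table; `N` bases never
mutate. Only substitutions are simulated: the caller operates on
ungapped full-length 33-mer placements, so indel variation would drop
reads, not create calls.

Read sampling defaults to *end sampling*: each read is the first 33 bp
of one fragment end (either end, hence either strand), as in a
short-insert library where sequencing starts at a ligated fragment end;
a uniform-offset mode is available (`end_sampling=False`). The real
library's read-start distribution is not knowable from the emulated
protocol; both modes are assumptions, and end sampling is the default
because it reproduces the same-fragments-across-genotypes property that
motivates RRLs. Reads per fragment are Poisson with mean
`depth_target · fragment_length / 33`, so expected sequenced bases per
fragment equal `depth_target ×` its length; under end sampling those
bases pile onto the two 33 bp end windows, so realized per-covered-base
depth is correspondingly higher than `depth_target`.

What the generator does *not* emulate: position- and cycle-dependent
Illumina error profiles, quality miscalibration, PCR duplicates, indels,
structural variation, and heterozygous residual variation within the
accessions. Tests passing on this generator therefore demonstrate the
pipeline's logic (filter semantics, coordinate bookkeeping, boundary
behaviour, statistical expectations), not robustness to real-instrument
artefacts.

## Occurrence screening

Every read's 33-mer is counted strand-literally (no canonicalization),
so counts sum to the raw read count and the occurrence summary table
obeys `bases = 33 × reads` per band — an identity asserted on every
constructed table. Reads whose 33-mer occurs ≥ 300 times are excluded as
repetitive or organellar; the remaining reads are screened against
organelle references by ungapped full-length alignment with ≤ 1 mismatch
on either strand (the threshold is our formalization of "matches to
chloroplast/mitochondrion sequence"). Occurrence filtering runs first,
organelle screening second. The published band labels of the occurrence
table overlap at shared boundaries ("300-500" vs "500 plus"); we resolve
boundaries downward, which leaves the table arithmetic unchanged.

## Alignment

Placement is seed-and-verify, full-length and ungapped, default
`max_mismatch = 1` (32 or 33 matching nucleotides out of 33). The
completeness argument is the pigeonhole: a query aligned with ≤ m
mismatches, divided into m+1 disjoint intervals, has at least one
interval mismatch-free, so the leading `seed_len`-mer of some interval
matches exactly. Every candidate from the exact-seed lookup is verified
by a Hamming comparison in which reference `N` matches nothing. The same
engine runs the 25-mer/2-mismatch repetitiveness scans through a derived
seed_len = 8 index built lazily.

The mapping score is deterministic and ours (the emulated tools'
internal scores are not published): 37 for a uniquely placed read with
no competing placement, −10 per sub-optimal competitor (at most three
penalized), 0 whenever the best placement is ambiguous. It is calibrated
so that the cascades' score ≥ 30 rule passes exactly the uniquely placed
reads with no competition — the filter's intent — without modelling any
particular aligner's statistics.

## Consensus and the filter cascades

A pileup column's consensus is the base with the largest quality sum;
the consensus quality is the margin over all discordant observations,
clipped to [0, 60]; ties give `N`, which the ambiguity rule eliminates.
This is a monotone stand-in for a Bayesian consensus score — monotone in
support and in opposition is all the cascades require.

Two cascades are provided, both recording a per-candidate ledger of
every rule evaluated:

**Alignment-identity cascade (`GMAP` mode)** — reads with any base
quality < 10 dropped; unique, full-length, ≤ 1-mismatch placement with
no repeat flag (the ≥ 300-occurrence 33-mer screen stands in for an
aligner-reported repeat column) and no `N`; unanimity of the covering
reads at the site; elimination when *both* flanking 25-mers match
another genome location with ≤ 2 mismatches; support ≥ 2; `N`-free
51-nt emitted context (our reading of "any remaining sequence containing
an N": the context that would be emitted for primer design).

**Consensus-quality cascade (`VMS` / `VSS` / `PRODUCTION` modes)** —
two or more candidates within a 25-base window all eliminated
(interpreted as pairwise distance < 25; positions exactly 25 apart are
kept, a boundary that is unit-tested); unambiguous consensus base;
consensus quality ≥ 20 (VMS, VSS) or ≥ 27 (PRODUCTION); average read
copy exactly 1.00 (every supporting read uniquely placed); mapping score
≥ 30 for every supporting read; support ≥ 2 for VMS only. Flank rules:
VMS/VSS require an `N`-free 121-nt centered context and eliminate when
both adjacent 25-mers are repetitive (≥ 1 other location, ≤ 2
mismatches); PRODUCTION requires an `N`-free 601-nt context and slides
all 25-mers across 300 nt on each side, a window being repetitive at
≥ 5 other locations, eliminating when more than 1/3 of the windows
(pooled over both flanks) are repetitive. Pooling across flanks is our
choice where the rule's grouping was unstated. The flank length is
configurable (an alternative reading of the production rule uses 120-nt
flanks with the same 2/3-non-repetitive requirement).

These cascades are deterministic rule filters, not statistical tests;
no multiple-testing machinery applies. Useful consequences that the
suite asserts: the VMS pass set is contained in the VSS pass set;
raising the consensus-quality threshold never adds a candidate; on
error-free simulations VMS recovers exactly the planted SNPs with ≥ 2
uniquely-placed covering reads outside dense clusters, with no false
calls; with sequencing errors switched on, the false calls that pass
VSS are single-read wonders — the qualitative gap behind the difference
between multi-read and single-read validation rates.

## RIL simulation and genetic mapping

An F_g-derived RIL is simulated by single-seed descent from an F1
(heterozygous everywhere): each selfing generation transmits two
independently produced gametes, each gamete choosing a random starting
chromatid and switching at each adjacent-marker interval with
probability r = Kosambi⁻¹(Δ cM). Crossovers are independent across
intervals; no interference is modelled beyond what the Kosambi function
encodes per interval, which suffices for the two-point statistics used
here. Residual heterozygosity halves per generation: (1/2)^(g−1), i.e.
6.25% at F5 — matching the 6.3% observed in the emulated study's mapped
population. Lines with heterozygosity strictly above 20% are excluded by
QC as putative outcrosses (a line at exactly 20% is kept).

Two-point linkage between markers uses the recombinant fraction R among
lines homozygous at both markers (heterozygous/missing calls skipped), a
binomial log10 likelihood ratio against r = 1/2 as the LOD, and the
linkage criteria LOD ≥ 10 and distance ≤ 50 cM. Because crossovers
accumulate over the selfing generations, R overstates the per-meiosis
r; `ril_two_point` inverts the *exact* expectation of R computed from
the two-locus selfing Markov chain at the lines' generation (the chain
reproduces the classical 2r/(1+2r) in the F∞ limit), then converts with
Kosambi, d = 25·ln((1+2r)/(1−2r)). The same chain doubles as an
independent oracle for the simulator in the tests. Full multipoint
marker ordering is deliberately not reproduced; marker order is taken
from the simulated truth and tested with two-point statistics.

## Scaffold anchoring

A scaffold with ≥ 1 mapped marker is anchored to that marker's linkage
group; it is oriented when its markers' genetic span is ≥ 1 cM
(inclusive). Orientation is the sign of the Spearman rank correlation
between physical and genetic marker positions — robust to one noisy
marker, unlike comparing only the extreme pair; with fewer than two
distinct positions on either axis the orientation stays unknown.
Markers mapping to different linkage groups mark the scaffold
"conflict" (possible misassembly) rather than being dropped. The
integration report counts statuses and the fraction of total scaffold
length anchored.

## Problem sizes and numerical choices

The test suite and the demo pipeline run on genomes of 3–50 kb, read
sets of a few thousand, and RIL populations up to 10,000 lines × 100
markers — sizes at which the brute-force oracles (exhaustive digestion
scans, O(L·33) alignment scans, all-window flank scans) remain exact and
cheap, while every statistical expectation (binomial SNP counts, Poisson
read counts, 1:2:1 F2 ratios, (1/2)^(g−1) heterozygosity, two-point
distance recovery at 444 lines) is testable at 3–5σ. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
reruns are byte-identical, including the pipeline's summary JSON.
Coordinates are 0-based half-open internally; all user-facing output
(VCF, TSV dumps) is 1-based.

## Known limitations

- The gel-banding surrogate, organelle-match threshold, mapping-score
  formula and consensus-quality formula are deterministic formalizations
  of procedures whose published descriptions are qualitative; each is
  documented above and kept behind a config knob where a different
  reading is plausible.
- End sampling leaves fragment interiors uncovered, so RRL recall is
  bounded by fragment-end coverage — by design, as in the emulated
  library type.
- The RIL simulator models ideal selfing; real populations also carry
  outcrossing and segregation distortion, which appear here only through
  the QC filter's contract.
- The aligner is exact but stores a Python dict index; it is sized for
  desk-scale genomes (≤ a few Mb), not production mammalian references.
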