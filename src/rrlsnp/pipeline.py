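"""End-to-end orchestration of the synthetic RRL SNP-discovery study.

``run_all`` executes the stages in order — reference simulation, in
silico digestion and size selection, divergent-accession mutation, read
sampling with contamination, 33-mer occurrence profiling and screening,
alignment, SNP calling under one or more filter modes, truth scoring,
and optionally RIL simulation plus scaffold anchoring — writing each
stage's artifacts plus a summary JSON into a run directory. The whole
run is deterministic under its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import align, anchor, caller, digest, kmers, rilmap, seqio, simulate

log = logging.getLogger("rrlsnp")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """One self-contained synthetic study."""

    out_dir: str = "rrlsnp_run"
    seed: int = 1
    genome_length: int = 50_000
    organelle_length: int = 10_000
    snp_rate: float = 1.0 / 425.0
    depth_target: float = 10.0
    error_rate: float = 0.002
    organelle_fraction: float = 0.05
    repeat_copies: int = 0
    repeat_length: int = 150
    enzymes: tuple[str, ...] = ("HaeIII", "PsiI", "SspI", "RsaI", "MslI")
    size_min: int = 100
    size_max: int = 150
    max_mismatch: int = 1
    modes: tuple[str, ...] = ("VMS", "VSS", "PRODUCTION")
    ril_lines: int = 470
    ril_generation: int = 5
    run_ril_stage: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _score_calls(passed, truth, selectable: set[int]) -> dict:
    """Recall/precision of a call set against the planted truth.

    Recall is reported both against all planted SNPs and against the
    discoverable subset (``selectable``: truth positions inside
    size-selected fragments, the only ones an RRL can see).
    """
    called = {(c.target_id, c.pos, c.consensus_base) for c in passed}
    truth_set = {(t.source_id, t.pos, t.alt_allele) for t in truth}
    tp = called & truth_set
    fp = called - truth_set
    disc = {t for t in truth_set if t[1] in selectable}
    return {
        "n_called": len(called),
        "true_positives": len(tp),
        "false_positives": len(fp),
        "precision": len(tp) / len(called) if called else 1.0,
        "recall_all": len(tp) / len(truth_set) if truth_set else 1.0,
        "n_discoverable": len(disc),
        "recall_discoverable": len(tp & disc) / len(disc) if disc else 1.0,
    }


def run_all(config: PipelineConfig) -> dict:
    """Run the whole pipeline; returns the summary dict (also written
    to ``<out_dir>/summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1)) for name in
             ("reference", "organelle", "repeats", "mutate", "reads", "ril")}

    log.info("stage 1/7: reference and organelle simulation")
    reference = simulate.random_genome(config.genome_length, seeds["reference"], id="chr1")
    if config.repeat_copies > 0:
        unit = simulate.random_genome(config.repeat_length, seeds["repeats"], id="repeat").seq
        reference, _sites = simulate.spike_repeats(
            reference, unit, config.repeat_copies, seeds["repeats"]
        )
    organelle = simulate.random_genome(
        config.organelle_length, seeds["organelle"], id="chloroplast"
    )
    seqio.write_fasta([reference], out / "reference.fasta")
    seqio.write_fasta([organelle], out / "organelle.fasta")

    log.info("stage 2/7: divergent accession (snp_rate=%.5f)", config.snp_rate)
    accession, truth = simulate.mutate_genome(reference, config.snp_rate, seeds["mutate"])
    seqio.write_fasta([accession], out / "accession.fasta")
    with open(out / "truth_snps.tsv", "w") as fh:
        fh.write("source\tpos_1based\tref\talt\n")
        for t in truth:
            fh.write(f"{t.source_id}\t{t.pos + 1}\t{t.ref_allele}\t{t.alt_allele}\n")

    log.info("stage 3/7: digest + size selection (%s)", ",".join(config.enzymes))
    enzymes = digest.get_enzymes(config.enzymes)
    fragments = digest.size_select(
        digest.digest(accession, enzymes), config.size_min, config.size_max
    )
    with open(out / "fragments.tsv", "w") as fh:
        fh.write("source\tstart\tend\tlength\n")
        for f in fragments:
            fh.write(f"{f.source_id}\t{f.start}\t{f.end}\t{len(f)}\n")

    log.info("stage 4/7: read sampling (%d fragments)", len(fragments))
    sim_cfg = simulate.SimConfig(
        snp_rate=config.snp_rate,
        depth_target=config.depth_target,
        error_rate=config.error_rate,
        organelle_fraction=config.organelle_fraction,
        seed=seeds["reads"],
    )
    reads, skipped = simulate.sample_reads(fragments, sim_cfg, organelle=[organelle])
    seqio.write_fastq(reads, out / "reads.fastq")

    log.info("stage 5/7: 33-mer profile + screening (%d reads)", len(reads))
    counts, _short = kmers.count_kmers(reads)
    table = kmers.build_occurrence_table(counts)
    with open(out / "occurrence_table.tsv", "w") as fh:
        fh.write("occurrences\tunique_33mers\treads\tbases\n")
        for b in table.bins:
            fh.write(f"{b.label}\t{b.unique_kmers}\t{b.reads}\t{b.bases}\n")
        fh.write(f"TOTAL\t{table.total_unique_kmers}\t{table.total_reads}\t{table.total_bases}\n")
    kept, excluded = kmers.filter_reads_by_occurrence(reads, counts)
    repetitive_ids = frozenset(r.id for r in excluded)
    kept, organelle_hits = kmers.screen_organelle(kept, [organelle])

    log.info("stage 6/7: alignment + SNP calling (%d kept reads)", len(kept))
    index = align.build_index([reference])
    placed = align.place_reads(kept, index, max_mismatch=config.max_mismatch)
    columns = align.pileup(placed, [reference])
    covered, fold = align.coverage_stats(placed)
    candidates = caller.candidate_snps(columns, placed)

    selectable = {pos for f in fragments for pos in range(f.start, f.end)}
    mode_results: dict[str, dict] = {}
    for mode in config.modes:
        cfg = caller.FilterConfig.for_mode(mode)
        if mode.upper() == "GMAP":
            passed = caller.gmap_cascade(
                candidates, placed, index, cfg, repetitive_read_ids=repetitive_ids
            )
        else:
            passed = caller.maq_cascade(candidates, placed, index, cfg)
        caller.write_snp_report(
            passed,
            out / f"snps_{mode.lower()}.vcf",
            out / f"snps_{mode.lower()}_ledger.tsv",
            reference_ids=[reference.id],
        )
        mode_results[mode] = _score_calls(passed, truth, selectable)

    summary = {
        "seed": config.seed,
        "genome_length": len(reference.seq),
        "n_truth_snps": len(truth),
        "n_fragments_selected": len(fragments),
        "n_reads": len(reads),
        "n_reads_skipped_short": skipped,
        "n_excluded_repetitive": len(excluded),
        "n_discarded_organelle": len(organelle_hits),
        "n_placed_unique": sum(1 for p in placed if p.placement == "unique"),
        "covered_bases": covered,
        "fold_coverage": round(fold, 3),
        "occurrence_total_reads": table.total_reads,
        "occurrence_total_bases": table.total_bases,
        "fraction_kmers_at_most_5": round(table.fraction_at_most(5), 4),
        "n_candidates": len(candidates),
        "modes": mode_results,
    }

    if config.run_ril_stage:
        log.info("stage 7/7: RIL simulation + anchoring")
        summary["ril"] = _ril_stage(config, seeds["ril"], out)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("run complete: %s", out / "summary.json")
    return summary


def _ril_stage(config: PipelineConfig, seed: int, out: Path) -> dict:
    """Map a simulated chromosome and anchor a shredded version of it."""
    n_markers = 20
    spacing_cm = 5.0
    cm = [i * spacing_cm for i in range(n_markers)]
    lines = rilmap.simulate_ril_population(
        cm, config.ril_lines, generation=config.ril_generation, seed=seed
    )
    kept, excluded = rilmap.qc_filter(lines)
    het = float(np.mean([rilmap.heterozygosity(l) for l in lines]))

    with open(out / "ril_genotypes.tsv", "w") as fh:
        fh.write("line\t" + "\t".join(f"M{j:02d}" for j in range(n_markers)) + "\n")
        for line in lines:
            fh.write(line.line_id + "\t" + "\t".join(line.genotypes) + "\n")

    # shred the mapped chromosome into scaffolds carrying 2 markers each
    scaffolds = []
    for s in range(n_markers // 2):
        mk = [
            rilmap.GeneticMarker(f"M{2 * s + j:02d}", f"scaf{s:02d}", 10_000 + j * 40_000, cm[2 * s + j])
            for j in range(2)
        ]
        scaffolds.append(anchor.Scaffold(f"scaf{s:02d}", 100_000, mk))
    results = anchor.anchor_scaffolds(scaffolds)
    report = anchor.integration_report(results, scaffolds)

    est_cm, lod, linked = rilmap.ril_two_point(kept, 0, 1)
    return {
        "n_lines": len(lines),
        "n_lines_kept": len(kept),
        "n_lines_excluded": len(excluded),
        "mean_heterozygosity_pct": round(100.0 * het, 3),
        "adjacent_interval_true_cm": spacing_cm,
        "adjacent_interval_est_cm": round(est_cm, 3),
        "adjacent_interval_lod": round(lod, 2),
        "adjacent_interval_linked": linked,
        "anchoring": report,
    }
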