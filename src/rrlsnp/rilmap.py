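"""Recombinant-inbred-line simulation and two-point genetic mapping.

An F5-derived RIL population is simulated by single-seed descent: each
line starts at F1 (heterozygous at every marker), and each of the four
selfing generations transmits two gametes produced with recombination
between adjacent markers at the frequency implied by the Kosambi map
distance. Expected residual heterozygosity after g-1 selfing meioses is
(1/2)^(g-1): 6.25% for F5-derived lines.

Two-point linkage uses the observed recombinant fraction among lines
homozygous at both markers, a binomial LOD against free recombination
(r = 1/2), and the Kosambi mapping function

    d(cM) = 25 * ln((1 + 2r) / (1 - 2r))

to convert recombination fractions into map distances. For RILs the raw
recombinant fraction R overstates the per-meiosis r because crossovers
accumulate over the selfing generations; :func:`ril_two_point` applies
the selfed-RIL correction r = R / (2 - 2R) before mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeneticMarker",
    "RilLine",
    "kosambi",
    "kosambi_inverse",
    "simulate_ril_population",
    "heterozygosity",
    "qc_filter",
    "recombination_fraction",
    "ril_two_point",
]

AA, BB, AB, MISSING = "AA", "BB", "AB", "NA"


@dataclass(frozen=True)
class GeneticMarker:
    marker_id: str
    scaffold_id: str
    phys_pos: int  # 0-based bp on its scaffold
    cm_pos: float
    linkage_group: str = "LG1"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cm_pos) or self.cm_pos < 0:
            raise ValueError(f"{self.marker_id}: cM position must be finite and >= 0")


@dataclass
class RilLine:
    line_id: str
    genotypes: list[str]  # per-marker, in {AA, BB, AB, NA}
    generation: int = 5

    def __post_init__(self) -> None:
        if self.generation < 2:
            raise ValueError("generation must be >= 2 (F2 at minimum)")


def kosambi(r: float) -> float:
    """Map distance in cM for recombination fraction r (Kosambi)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(cm: float) -> float:
    """Recombination fraction for a Kosambi map distance in cM."""
    if cm < 0:
        raise ValueError("map distance must be >= 0")
    x = math.exp(cm / 25.0)
    return 0.5 * (x - 1.0) / (x + 1.0)


def simulate_ril_population(
    marker_cm: Sequence[float],
    n_lines: int,
    generation: int = 5,
    seed: int = 0,
) -> list[RilLine]:
    """Simulate F_g-derived RILs by single-seed descent from an F1.

    ``marker_cm`` gives the true cM positions of the markers along one
    chromosome, in non-decreasing order; adjacent-interval recombination
    frequencies are ``kosambi_inverse`` of the cM gaps, with independent
    crossover draws per interval per transmitted gamete. Unlinked marker
    sets are modelled by gaps large enough that r ~= 0.5 (or by calling
    once per chromosome).
    """
    cm = np.asarray(marker_cm, dtype=float)
    if cm.ndim != 1 or cm.size == 0:
        raise ValueError("marker_cm must be a non-empty 1-D sequence")
    if np.any(np.diff(cm) < 0):
        raise ValueError("marker cM positions must be non-decreasing")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    m = cm.size
    r_adj = np.array([kosambi_inverse(d) for d in np.diff(cm)])
    n_meioses = generation - 1

    # haplotypes coded 0 (parent A) / 1 (parent B); shape (n_lines, 2, m)
    haps = np.zeros((n_lines, 2, m), dtype=np.int8)
    haps[:, 1, :] = 1  # F1: one A and one B chromosome

    for _ in range(n_meioses):
        new = np.empty_like(haps)
        for g in range(2):  # two independently produced gametes per selfing
            # random starting chromatid, then switch at each interval w.p. r
            cur = rng.integers(0, 2, size=n_lines)
            gam = np.empty((n_lines, m), dtype=np.int8)
            gam[:, 0] = haps[np.arange(n_lines), cur, 0]
            for j in range(1, m):
                flip = rng.random(n_lines) < r_adj[j - 1]
                cur = np.where(flip, 1 - cur, cur)
                gam[:, j] = haps[np.arange(n_lines), cur, j]
            new[:, g, :] = gam
        haps = new

    code = haps.sum(axis=1)  # 0 = AA, 2 = BB, 1 = AB
    geno_map = {0: AA, 1: AB, 2: BB}
    return [
        RilLine(f"RIL{i + 1:04d}", [geno_map[int(v)] for v in code[i]], generation)
        for i in range(n_lines)
    ]


def heterozygosity(line: RilLine) -> float:
    """Fraction of heterozygous calls among non-missing calls."""
    calls = [g for g in line.genotypes if g != MISSING]
    if not calls:
        raise ValueError(f"{line.line_id}: no non-missing genotypes")
    return sum(1 for g in calls if g == AB) / len(calls)


def qc_filter(
    lines: Sequence[RilLine], max_het: float = 0.20
) -> tuple[list[RilLine], list[tuple[RilLine, str]]]:
    """Exclude lines with heterozygosity strictly above ``max_het``.

    High heterozygosity indicates an outcross during generation advance
    rather than a true inbred line. All-missing lines are excluded with
    reason "no_data".
    """
    kept: list[RilLine] = []
    excluded: list[tuple[RilLine, str]] = []
    for line in lines:
        if all(g == MISSING for g in line.genotypes):
            excluded.append((line, "no_data"))
            continue
        if heterozygosity(line) > max_het:
            excluded.append((line, "heterozygosity"))
        else:
            kept.append(line)
    return kept, excluded


def recombination_fraction(
    lines: Sequence[RilLine], idx_a: int, idx_b: int
) -> tuple[float, float, int]:
    """Two-point recombinant fraction and LOD between two markers.

    Informative lines are those homozygous (AA or BB) at both markers;
    heterozygous or missing calls are skipped. Returns
    (r_hat, lod, n_informative) where r_hat is the raw recombinant
    fraction and lod the log10 likelihood ratio of linkage at r_hat
    against r = 1/2 under a binomial model.
    """
    n = k = 0
    for line in lines:
        a, b = line.genotypes[idx_a], line.genotypes[idx_b]
        if a in (AA, BB) and b in (AA, BB):
            n += 1
            if a != b:
                k += 1
    if n == 0:
        raise ValueError("no informative lines")
    r_hat = k / n
    if 0.0 < r_hat < 1.0:
        lod = k * math.log10(r_hat / 0.5) + (n - k) * math.log10((1.0 - r_hat) / 0.5)
    elif r_hat == 0.0:
        lod = n * math.log10(2.0)
    else:
        lod = k * math.log10(2.0)
    return r_hat, lod, n


def two_locus_selfing_distribution(r: float, generation: int) -> np.ndarray:
    """Exact two-locus genotype distribution of F_g selfed lines.

    States are ordered pairs of two-locus gametes; a gamete is 0..3
    encoding (allele at locus 1, allele at locus 2) as two bits with
    0 = parent A. Starting from the F1 (gametes 0b00 and 0b11), each
    selfing generation draws two independent gametes from the current
    plant, each parental with probability (1-r)/2 per haplotype and
    recombinant with probability r/2 per recombinant type. Returns the
    16-vector of ordered-pair probabilities after generation-1 meioses.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("r outside [0, 0.5]")
    if generation < 2:
        raise ValueError("generation must be >= 2")
    # gamete distribution produced by each ordered genotype (h1, h2)
    gamete = np.zeros((4, 4, 4))
    for h1 in range(4):
        for h2 in range(4):
            rec1 = (h1 & 0b10) | (h2 & 0b01)
            rec2 = (h2 & 0b10) | (h1 & 0b01)
            gamete[h1, h2, h1] += (1.0 - r) / 2.0
            gamete[h1, h2, h2] += (1.0 - r) / 2.0
            gamete[h1, h2, rec1] += r / 2.0
            gamete[h1, h2, rec2] += r / 2.0
    dist = np.zeros((4, 4))
    dist[0b00, 0b11] = 1.0  # F1
    for _ in range(generation - 1):
        new = np.zeros((4, 4))
        for h1 in range(4):
            for h2 in range(4):
                p = dist[h1, h2]
                if p > 0.0:
                    g = gamete[h1, h2]
                    new += p * np.outer(g, g)
        dist = new
    return dist


def expected_ril_recombinant_fraction(r: float, generation: int) -> float:
    """Expected recombinant fraction among double-homozygous F_g lines.

    Crossovers accumulate over the selfing generations, so this exceeds
    the per-meiosis r (approaching 2r/(1+2r) as generation grows).
    """
    dist = two_locus_selfing_distribution(r, generation)
    parental = dist[0b00, 0b00] + dist[0b11, 0b11]
    recomb = dist[0b01, 0b01] + dist[0b10, 0b10]
    total = parental + recomb
    return recomb / total if total > 0 else 0.0


def ril_two_point(
    lines: Sequence[RilLine],
    idx_a: int,
    idx_b: int,
    min_lod: float = 10.0,
    max_cm: float = 50.0,
) -> tuple[float, float, bool]:
    """Map distance between two markers from RIL genotypes.

    The observed recombinant fraction R among double-homozygous lines
    overstates the per-meiosis r because crossovers accumulate over the
    selfing generations; the exact generation-specific expectation from
    the two-locus selfing chain is inverted numerically to recover r,
    which the Kosambi function converts to cM. The two-point linkage
    criteria (LOD >= min_lod and distance <= max_cm) are then applied.
    Returns (cm, lod, linked).
    """
    from scipy.optimize import brentq

    r_obs, lod, _n = recombination_fraction(lines, idx_a, idx_b)
    generation = lines[0].generation
    r_cap = 0.4999
    if r_obs <= 0.0:
        r_meiotic = 0.0
    elif r_obs >= expected_ril_recombinant_fraction(r_cap, generation):
        r_meiotic = r_cap
    else:
        r_meiotic = brentq(
            lambda r: expected_ril_recombinant_fraction(r, generation) - r_obs,
            0.0,
            r_cap,
            xtol=1e-10,
        )
    cm = kosambi(r_meiotic)
    return cm, lod, bool(lod >= min_lod and cm <= max_cm)
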