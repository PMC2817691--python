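"""Kosambi function, RIL simulator against the exact selfing chain,
heterozygosity QC and two-point linkage."""

import math

import numpy as np
import pytest

from rrlsnp.rilmap import (
    AB,
    MISSING,
    GeneticMarker,
    RilLine,
    expected_ril_recombinant_fraction,
    heterozygosity,
    kosambi,
    kosambi_inverse,
    qc_filter,
    recombination_fraction,
    ril_two_point,
    simulate_ril_population,
    two_locus_selfing_distribution,
)


class TestKosambi:
    @pytest.mark.parametrize(
        "r,cm",
        [
            (0.0, 0.0),
            (0.1, 25 * math.log(1.2 / 0.8)),  # 10.1366
            (0.25, 25 * math.log(3.0)),  # 27.4653
        ],
    )
    def test_closed_form(self, r, cm):
        assert kosambi(r) == pytest.approx(cm, abs=1e-9)
        assert kosambi(0.1) == pytest.approx(10.1366, abs=1e-4)
        assert kosambi(0.25) == pytest.approx(27.4653, abs=1e-4)

    def test_inverse_roundtrip(self):
        for cm in np.linspace(0.0, 200.0, 41):
            assert kosambi(kosambi_inverse(cm)) == pytest.approx(cm, abs=1e-9)

    def test_monotone_and_above_100r(self):
        grid = np.linspace(0.0, 0.499, 200)
        vals = [kosambi(r) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v >= 100 * r for r, v in zip(grid, vals))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi(-0.01)


class TestSimulator:
    def test_f2_single_marker_1_2_1(self):
        lines = simulate_ril_population([0.0], 10_000, generation=2, seed=101)
        counts = {g: 0 for g in ("AA", "AB", "BB")}
        for l in lines:
            counts[l.genotypes[0]] += 1
        for geno, p in (("AA", 0.25), ("AB", 0.5), ("BB", 0.25)):
            sigma = math.sqrt(p * (1 - p) / 10_000)
            assert abs(counts[geno] / 10_000 - p) <= 4 * sigma

    def test_f5_heterozygosity_expectation(self):
        # unlinked markers via huge cM gaps; E[het] = (1/2)^4 = 6.25%
        cm = [i * 10_000.0 for i in range(50)]
        lines = simulate_ril_population(cm, 2_000, generation=5, seed=102)
        het = np.mean([heterozygosity(l) for l in lines])
        sigma = math.sqrt(0.0625 * 0.9375 / (2_000 * 50))
        assert abs(het - 0.0625) <= 4 * sigma

    @pytest.mark.parametrize("generation", [2, 3, 5, 7])
    def test_heterozygosity_halves_each_generation(self, generation):
        lines = simulate_ril_population([0.0], 8_000, generation=generation, seed=103)
        het = np.mean([heterozygosity(l) for l in lines])
        expected = 0.5 ** (generation - 1)
        sigma = math.sqrt(expected * (1 - expected) / 8_000)
        assert abs(het - expected) <= 4 * sigma

    def test_zero_distance_no_recombinants(self):
        lines = simulate_ril_population([10.0, 10.0], 2_000, generation=5, seed=104)
        assert all(l.genotypes[0] == l.genotypes[1] for l in lines)

    def test_genotype_distribution_matches_exact_chain(self):
        """Two linked markers: simulated genotype-pair frequencies agree
        with the exact two-locus selfing distribution."""
        true_cm = 20.0
        r = kosambi_inverse(true_cm)
        dist = two_locus_selfing_distribution(r, generation=5)
        # collapse ordered gamete pairs to unordered genotype-pair labels
        def label(h1, h2):
            a = {0: "AA", 1: "AB", 2: "BB"}[(h1 >> 1) + (h2 >> 1)]
            b = {0: "AA", 1: "AB", 2: "BB"}[(h1 & 1) + (h2 & 1)]
            return a, b
        expected: dict = {}
        for h1 in range(4):
            for h2 in range(4):
                expected[label(h1, h2)] = expected.get(label(h1, h2), 0.0) + dist[h1, h2]
        n = 30_000
        lines = simulate_ril_population([0.0, true_cm], n, generation=5, seed=105)
        observed: dict = {}
        for l in lines:
            key = (l.genotypes[0], l.genotypes[1])
            observed[key] = observed.get(key, 0) + 1
        for key, p in expected.items():
            if p < 1e-6:
                continue
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(observed.get(key, 0) / n - p) <= 5 * sigma, key

    def test_determinism_and_validation(self):
        a = simulate_ril_population([0.0, 10.0], 50, seed=1)
        b = simulate_ril_population([0.0, 10.0], 50, seed=1)
        assert [l.genotypes for l in a] == [l.genotypes for l in b]
        with pytest.raises(ValueError):
            simulate_ril_population([10.0, 0.0], 10, seed=1)  # unordered map
        with pytest.raises(ValueError):
            simulate_ril_population([0.0], 0, seed=1)


class TestQc:
    def test_all_het_excluded_all_hom_kept(self):
        hi = RilLine("hi", [AB] * 10)
        lo = RilLine("lo", ["AA"] * 10)
        kept, excluded = qc_filter([hi, lo])
        assert kept == [lo] and excluded[0][0] is hi

    def test_boundary_exactly_20_percent_kept(self):
        line = RilLine("edge", [AB] * 2 + ["AA"] * 8)  # exactly 0.20
        kept, excluded = qc_filter([line])
        assert kept == [line] and excluded == []

    def test_all_missing_flagged(self):
        line = RilLine("none", [MISSING] * 5)
        kept, excluded = qc_filter([line])
        assert kept == [] and excluded == [(line, "no_data")]


class TestTwoPoint:
    def test_identical_vectors_r_zero(self):
        lines = [RilLine(f"l{i}", ["AA", "AA"]) for i in range(20)]
        r, lod, n = recombination_fraction(lines, 0, 1)
        assert r == 0.0 and n == 20
        assert lod == pytest.approx(20 * math.log10(2))

    def test_het_and_missing_skipped(self):
        lines = [
            RilLine("a", ["AA", "BB"]),
            RilLine("b", [AB, "AA"]),
            RilLine("c", ["AA", MISSING]),
        ]
        r, _, n = recombination_fraction(lines, 0, 1)
        assert n == 1 and r == 1.0

    def test_independent_markers_r_half_lod_zero(self):
        cm = [0.0, 10_000.0]
        lines = simulate_ril_population(cm, 1_000, generation=5, seed=106)
        r, lod, _ = recombination_fraction(lines, 0, 1)
        assert abs(r - 0.5) < 0.05
        assert lod < 1.0
        _, _, linked = ril_two_point(lines, 0, 1)
        assert not linked

    def test_true_distance_recovered_at_study_size(self):
        """20-marker chromosome at 444 lines: adjacent true distances
        recovered within 3 sigma of simulation error."""
        spacing = 10.0
        cm = [i * spacing for i in range(20)]
        lines = simulate_ril_population(cm, 444, generation=5, seed=107)
        r_true = kosambi_inverse(spacing)
        R = expected_ril_recombinant_fraction(r_true, 5)
        # delta method: sd of estimated cM from binomial sd of observed R
        dR = math.sqrt(R * (1 - R) / 444)
        eps = 1e-4
        dcm_dR = (
            _cm_from_R(R + eps) - _cm_from_R(R - eps)
        ) / (2 * eps)
        tol = 3 * dR * abs(dcm_dR)
        for j in range(19):
            est, lod, linked = ril_two_point(lines, j, j + 1)
            assert linked
            assert abs(est - spacing) <= tol, (j, est)

    def test_no_informative_lines_reported(self):
        lines = [RilLine("a", [AB, AB])]
        with pytest.raises(ValueError, match="informative"):
            recombination_fraction(lines, 0, 1)


def _cm_from_R(R: float) -> float:
    from scipy.optimize import brentq

    r = brentq(
        lambda r: expected_ril_recombinant_fraction(r, 5) - R, 0.0, 0.4999, xtol=1e-12
    )
    return kosambi(r)


def test_f_infinity_limit_matches_haldane_waddington():
    """The selfing chain converges to R = 2r/(1+2r) as generations grow."""
    for r in (0.05, 0.1, 0.2, 0.3):
        assert expected_ril_recombinant_fraction(r, 60) == pytest.approx(
            2 * r / (1 + 2 * r), abs=1e-9
        )


def test_marker_validation():
    with pytest.raises(ValueError):
        GeneticMarker("m", "s", 0, float("nan"))
    with pytest.raises(ValueError):
        RilLine("l", ["AA"], generation=1)
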