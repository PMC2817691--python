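"""Published summary numbers used as inputs and cross-checks.

``SOY_RRL_OCCURRENCE_PROFILE`` is the per-band 33-mer occurrence profile
of the deep-sequenced soybean (G. soja PI 468916) reduced-representation
library: for each occurrence band, the number of distinct 33-mers and
the number of 33 bp reads they account for. Feeding it through
:func:`rrlsnp.kmers.occurrence_table_from_profile` recomputes the base
counts and totals from scratch, so the table's internal arithmetic
(bases = 33 x reads per band, totals = column sums) is verified rather
than transcribed.

The validation-rate helpers express SNP-validation arithmetic:
a validation rate is confirmed/tested as a percentage, and a GoldenGate
assay conversion rate can be deflated by the expected conversion rate of
a true SNP (89%) to give an effective validation rate.
"""

from __future__ import annotations

__all__ = [
    "SOY_RRL_OCCURRENCE_PROFILE",
    "GOLDENGATE_CONVERSION_OF_TRUE_SNP",
    "validation_rate",
    "effective_validation_rate",
]

# (band label, representative occurrence, unique 33-mers, 33 bp reads)
SOY_RRL_OCCURRENCE_PROFILE: tuple[tuple[str, int, int, int], ...] = (
    ("500 plus", 600, 1_293, 2_142_203),
    ("300-500", 400, 1_414, 536_701),
    ("100-299", 150, 6_561, 1_097_771),
    ("35-99", 50, 15_119, 871_270),
    ("20-34", 25, 14_510, 374_818),
    ("15-20", 17, 12_040, 206_542),
    ("11-14", 12, 15_645, 192_046),
    ("9-10", 9, 15_234, 143_581),
    ("7-8", 7, 29_215, 216_367),
    ("6", 6, 26_648, 159_888),
    ("5", 5, 43_105, 215_525),
    ("4", 4, 72_955, 291_820),
    ("3", 3, 130_555, 391_665),
    ("2", 2, 259_225, 518_450),
    ("1", 1, 1_312_518, 1_312_518),
)

# Fraction of validated (true) SNPs that convert into a working
# GoldenGate assay, from prior soybean assay-design experience.
GOLDENGATE_CONVERSION_OF_TRUE_SNP = 89.0  # percent


def validation_rate(confirmed: int, tested: int) -> float:
    """Percent of tested SNP predictions confirmed by resequencing."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    if not 0 <= confirmed <= tested:
        raise ValueError("confirmed must be in [0, tested]")
    return 100.0 * confirmed / tested


def effective_validation_rate(
    conversion_pct: float,
    assay_conversion_pct: float = GOLDENGATE_CONVERSION_OF_TRUE_SNP,
) -> float:
    """SNP validation rate implied by an assay conversion rate.

    If a true SNP converts into a working assay with probability c, an
    observed conversion rate v of predicted SNPs implies a validation
    rate of v / c.
    """
    if assay_conversion_pct <= 0:
        raise ValueError("assay conversion rate must be positive")
    return 100.0 * conversion_pct / assay_conversion_pct
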