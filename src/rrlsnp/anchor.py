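"""Scaffold anchoring and orientation from mapped markers.

A scaffold with at least one genetically mapped marker can be anchored
to a linkage group; orienting it additionally requires markers whose
genetic positions are spread by at least 1 cM (below that, recombination
gives no information about direction). Orientation is decided by the
sign of the rank correlation between physical (bp) and genetic (cM)
marker positions, which tolerates a single noisy marker better than
comparing only the two extreme markers.

Markers on one scaffold that map to different linkage groups are a
red flag for misassembly; such scaffolds are reported with status
"conflict" rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import spearmanr

from .rilmap import GeneticMarker

__all__ = ["Scaffold", "AnchorResult", "anchor_scaffolds", "integration_report"]

ORIENT_SPAN_CM = 1.0  # minimum cM spread to call an orientation


@dataclass
class Scaffold:
    scaffold_id: str
    length: int
    markers: list[GeneticMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.markers:
            if m.phys_pos >= self.length:
                raise ValueError(
                    f"{self.scaffold_id}: marker {m.marker_id} beyond scaffold end"
                )


@dataclass(frozen=True)
class AnchorResult:
    scaffold_id: str
    status: str  # unanchored | anchored | oriented | conflict
    linkage_group: str | None
    orientation: str  # forward | reverse | unknown
    cm_span: float
    n_markers: int


def _orientation(markers: Sequence[GeneticMarker]) -> str:
    xs = [m.phys_pos for m in markers]
    ys = [m.cm_pos for m in markers]
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        return "unknown"
    rho = spearmanr(xs, ys).statistic
    if rho > 0:
        return "forward"
    if rho < 0:
        return "reverse"
    return "unknown"


def anchor_scaffolds(scaffolds: Sequence[Scaffold]) -> list[AnchorResult]:
    """Anchor/orient each scaffold from its mapped markers.

    status: "unanchored" (no markers), "anchored" (markers but cM span
    below 1), "oriented" (span >= 1 cM), "conflict" (markers on more
    than one linkage group).
    """
    results: list[AnchorResult] = []
    for scaf in scaffolds:
        markers = scaf.markers
        if not markers:
            results.append(
                AnchorResult(scaf.scaffold_id, "unanchored", None, "unknown", 0.0, 0)
            )
            continue
        groups = {m.linkage_group for m in markers}
        if len(groups) > 1:
            results.append(
                AnchorResult(scaf.scaffold_id, "conflict", None, "unknown", 0.0, len(markers))
            )
            continue
        lg = markers[0].linkage_group
        cms = [m.cm_pos for m in markers]
        span = max(cms) - min(cms)
        if len(markers) >= 2 and span >= ORIENT_SPAN_CM:
            results.append(
                AnchorResult(
                    scaf.scaffold_id, "oriented", lg, _orientation(markers), span, len(markers)
                )
            )
        else:
            results.append(
                AnchorResult(scaf.scaffold_id, "anchored", lg, "unknown", span, len(markers))
            )
    return results


def integration_report(
    results: Sequence[AnchorResult], scaffolds: Sequence[Scaffold]
) -> dict:
    """Status counts plus the fraction of total scaffold length anchored."""
    lengths = {s.scaffold_id: s.length for s in scaffolds}
    counts: dict[str, int] = {"unanchored": 0, "anchored": 0, "oriented": 0, "conflict": 0}
    anchored_len = 0
    total_len = sum(lengths.values())
    for res in results:
        counts[res.status] = counts.get(res.status, 0) + 1
        if res.status in ("anchored", "oriented"):
            anchored_len += lengths.get(res.scaffold_id, 0)
    return {
        "counts": counts,
        "total_scaffolds": len(results),
        "total_length": total_len,
        "anchored_length": anchored_len,
        "anchored_fraction": (anchored_len / total_len) if total_len else 0.0,
    }
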