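"""Completeness/contamination estimation and three-tier quality calls for
giant-virus bins.

NCLDVs have no universal single-copy marker set, so quality is judged
against the *superclade* a bin belongs to: for each superclade, the average
number of the twenty conserved NCVOGs present — and present as multiple
copies — is computed over member genomes.  A bin's completeness is the
number of quality-set markers it carries relative to that mean; its
contamination is the deviation of its multicopy-marker count from the
superclade mean.  Tier boundaries follow the bin-quality convention for
uncultivated viruses: completeness high ≥ 90 %, medium ≥ 50 %; contamination
low ≤ 1.2×, medium ≤ 2×.  The final call combines the two tiers and is
demoted when assembly criteria (contig count, assembly size, longest contig)
are not met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .registry import QUALITY20

__all__ = [
    "SupercladeBaseline",
    "AssemblyStats",
    "QualityCall",
    "build_baseline",
    "contamination_tier",
    "completeness_tier",
    "final_quality",
]


@dataclass(frozen=True)
class SupercladeBaseline:
    """Mean quality-set marker counts over one superclade's genomes."""

    superclade_id: str
    mean_present: float
    mean_single: float
    mean_multi: float
    n_genomes: int = 0


def _marker_counts(
    markers: Mapping[str, int], marker_set: frozenset[str]
) -> tuple[int, int, int]:
    present = sum(1 for m in marker_set if markers.get(m, 0) >= 1)
    single = sum(1 for m in marker_set if markers.get(m, 0) == 1)
    multi = sum(1 for m in marker_set if markers.get(m, 0) >= 2)
    return present, single, multi


def build_baseline(
    tables: Mapping[str, Mapping[str, int]],
    superclade_id: str,
    marker_set: frozenset[str] = QUALITY20,
    *,
    exclude: str | None = None,
) -> SupercladeBaseline:
    """Average quality-set marker presence over one superclade's genomes.

    ``tables`` maps genome id → (NCVOG id → copy count).  ``exclude`` drops
    one genome (leave-one-out) so a bin under evaluation does not bias its
    own baseline in small superclades.
    """
    ids = [g for g in tables if g != exclude]
    if not ids:
        raise ValueError(f"superclade {superclade_id!r} has no baseline genomes")
    present = single = multi = 0
    for g in ids:
        p, s, m = _marker_counts(tables[g], marker_set)
        present += p
        single += s
        multi += m
    n = len(ids)
    return SupercladeBaseline(
        superclade_id=superclade_id,
        mean_present=present / n,
        mean_single=single / n,
        mean_multi=multi / n,
        n_genomes=n,
    )


LOW_CONTAMINATION_FACTOR = 1.2
MEDIUM_CONTAMINATION_FACTOR = 2.0
HIGH_COMPLETENESS_FRACTION = 0.9
MEDIUM_COMPLETENESS_FRACTION = 0.5


def contamination_tier(
    markers: Mapping[str, int],
    baseline: SupercladeBaseline,
    marker_set: frozenset[str] = QUALITY20,
) -> tuple[str, float]:
    """Contamination tier from the multicopy-marker deviation.

    The deviation factor is the bin's multicopy quality-set marker count over
    the superclade mean (floored at 1: superclades whose members are
    essentially single-copy would otherwise make any duplication an infinite
    deviation).  Deviation ≤ 1.2 is low, ≤ 2 medium, above that high.
    """
    _, _, multi = _marker_counts(markers, marker_set)
    deviation = multi / max(baseline.mean_multi, 1.0)
    if deviation <= LOW_CONTAMINATION_FACTOR:
        tier = "low"
    elif deviation <= MEDIUM_CONTAMINATION_FACTOR:
        tier = "medium"
    else:
        tier = "high"
    return tier, deviation


def completeness_tier(
    markers: Mapping[str, int],
    baseline: SupercladeBaseline,
    marker_set: frozenset[str] = QUALITY20,
) -> tuple[str, float]:
    """Completeness tier from quality-set marker presence vs the superclade
    mean: ≥ 90 % high, ≥ 50 % medium, below that low.  The fraction may
    exceed 1 for bins richer than the mean and is reported uncapped."""
    if baseline.mean_present <= 0:
        raise ValueError("baseline mean_present must be positive")
    present, _, _ = _marker_counts(markers, marker_set)
    fraction = present / baseline.mean_present
    if fraction >= HIGH_COMPLETENESS_FRACTION:
        tier = "high"
    elif fraction >= MEDIUM_COMPLETENESS_FRACTION:
        tier = "medium"
    else:
        tier = "low"
    return tier, fraction


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    assembly_size: int  # bp
    longest_contig: int  # bp


@dataclass(frozen=True)
class QualityCall:
    contamination_tier: str
    completeness_tier: str
    final: str
    stats: AssemblyStats
    deviation: float = math.nan
    completeness_fraction: float = math.nan


_TIER_RANK = {"low": 0, "medium": 1, "high": 2}

#: Combination matrix mapping (completeness, contamination) to a candidate
#: final tier.  High demands high completeness with low contamination; medium
#: demands at-least-medium completeness with at-most-medium contamination.
#: The published matrix is supplementary material; this default is
#: overridable via ``final_quality``'s ``matrix`` argument.
DEFAULT_COMBINATION_MATRIX: dict[tuple[str, str], str] = {
    (compl, contam): (
        "high"
        if compl == "high" and contam == "low"
        else "medium"
        if _TIER_RANK[compl] >= 1 and _TIER_RANK[contam] <= 1
        else "low"
    )
    for compl in _TIER_RANK
    for contam in _TIER_RANK
}

HIGH_ASSEMBLY = AssemblyStats(n_contigs=30, assembly_size=100_000, longest_contig=30_000)
MEDIUM_ASSEMBLY = AssemblyStats(n_contigs=50, assembly_size=100_000, longest_contig=15_000)


def _meets(stats: AssemblyStats, crit: AssemblyStats) -> bool:
    return (
        stats.n_contigs <= crit.n_contigs
        and stats.assembly_size >= crit.assembly_size
        and stats.longest_contig > crit.longest_contig
    )


def final_quality(
    contamination: str,
    completeness: str,
    stats: AssemblyStats,
    *,
    matrix: Mapping[tuple[str, str], str] = None,
    deviation: float = math.nan,
    completeness_fraction: float = math.nan,
) -> QualityCall:
    """Combine tiers into the final quality call, then demote until assembly
    criteria are met.

    High quality additionally requires no more than 30 contigs, at least
    100 kb of assembly and one contig longer than 30 kb; medium requires no
    more than 50 contigs, at least 100 kb and one contig longer than 15 kb.
    A candidate failing its tier's criteria is demoted (high → medium → low).
    """
    matrix = DEFAULT_COMBINATION_MATRIX if matrix is None else matrix
    candidate = matrix[(completeness, contamination)]
    final = candidate
    if final == "high" and not _meets(stats, HIGH_ASSEMBLY):
        final = "medium"
    if final == "medium" and not _meets(stats, MEDIUM_ASSEMBLY):
        final = "low"
    return QualityCall(
        contamination_tier=contamination,
        completeness_tier=completeness,
        final=final,
        stats=stats,
        deviation=deviation,
        completeness_fraction=completeness_fraction,
    )
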