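"""Virus–host linkage through horizontal gene transfer (HGT).

Every protein of a viral lineage's pan-proteome is searched against two
databases: a cellular protein database (archaea, bacteria, eukaryotes) and
an NCLDV database.  Cellular hits are gated at E ≤ 1e-50, identity ≥ 50 %
and alignment fraction ≥ 50 % (alignment length over query length); hits to
the query's own lineage in the NCLDV database are discarded.  A protein is
an HGT candidate when its best surviving cellular hit has a strictly lower
E-value than its best surviving NCLDV hit — the gene looks more cellular
than viral, indicating a transfer with the host group of that best cellular
hit.  Candidate counts per (lineage, host group) become the edge weights of
an undirected virus–host network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "HitRecord",
    "HgtCandidate",
    "detect_hgt",
    "build_network",
    "host_fraction_summary",
    "EUKARYOTIC_SUPERGROUPS",
]

EVALUE_CUTOFF = 1e-50
MIN_IDENTITY = 50.0
MIN_ALIGNMENT_FRACTION = 50.0


@dataclass(frozen=True)
class HitRecord:
    """One tabular similarity-search hit, tagged with its database and the
    taxon group of the subject."""

    query_protein: str
    query_lineage: str
    subject_id: str
    database: str  # {"cellular_nr", "ncldv"}
    subject_taxon_group: str
    evalue: float
    pct_identity: float
    alignment_fraction: float  # alignment length / query length, %

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if not (0 <= self.pct_identity <= 100 and 0 <= self.alignment_fraction <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if self.database not in {"cellular_nr", "ncldv"}:
            raise ValueError(f"unknown database {self.database!r}")


@dataclass(frozen=True)
class HgtCandidate:
    query_protein: str
    query_lineage: str
    host_group: str
    cellular_evalue: float
    ncldv_evalue: float | None


def _passes_gates(hit: HitRecord) -> bool:
    return (
        hit.evalue <= EVALUE_CUTOFF
        and hit.pct_identity >= MIN_IDENTITY
        and hit.alignment_fraction >= MIN_ALIGNMENT_FRACTION
    )


def detect_hgt(
    records: Iterable[HitRecord],
    *,
    subject_blocklist: frozenset[str] = frozenset(),
) -> list[HgtCandidate]:
    """Detect HGT-candidate proteins by dual-database best-hit comparison.

    Cellular hits are (re-)gated at the E-value/identity/alignment-fraction
    cut-offs and hits to blocklisted subjects (e.g. known misclassified
    reference bins) are dropped; NCLDV hits to the query's own lineage are
    removed before comparison.  A protein is a candidate iff its best
    cellular hit has strictly lower E-value than its best NCLDV hit (a tie is
    not a candidate; a protein with no surviving NCLDV hit is).  Proteins
    with no surviving hits in either database are skipped.  Candidates are
    returned sorted by protein id with the best cellular hit's taxon group as
    the putative host.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_protein, []).append(r)
    candidates = []
    for query in sorted(by_query):
        hits = by_query[query]
        cellular = [
            h
            for h in hits
            if h.database == "cellular_nr"
            and _passes_gates(h)
            and h.subject_id not in subject_blocklist
        ]
        viral = [
            h
            for h in hits
            if h.database == "ncldv" and h.subject_taxon_group != h.query_lineage
        ]
        if not cellular:
            continue
        best_cell = min(cellular, key=lambda h: (h.evalue, h.subject_id))
        best_viral_e = min((h.evalue for h in viral), default=None)
        if best_viral_e is None or best_cell.evalue < best_viral_e:
            candidates.append(
                HgtCandidate(
                    query_protein=query,
                    query_lineage=best_cell.query_lineage,
                    host_group=best_cell.subject_taxon_group,
                    cellular_evalue=best_cell.evalue,
                    ncldv_evalue=best_viral_e,
                )
            )
    return candidates


DEFAULT_MIN_WEIGHT = 2  # network filter; the figure view uses 4


def build_network(
    candidates: Sequence[HgtCandidate], min_weight: int = DEFAULT_MIN_WEIGHT
) -> nx.Graph:
    """Build the weighted undirected virus–host network.

    Edge weight between a viral lineage and a host group is the number of
    candidate proteins in that lineage's pan-proteome whose best cellular hit
    falls in the group; edges below ``min_weight`` are dropped.  Nodes carry
    a ``kind`` attribute ("lineage" or "host").
    """
    weights: dict[tuple[str, str], int] = {}
    for c in candidates:
        key = (c.query_lineage, c.host_group)
        weights[key] = weights.get(key, 0) + 1
    G = nx.Graph()
    for (lineage, host), w in sorted(weights.items()):
        if w >= min_weight:
            G.add_node(lineage, kind="lineage")
            G.add_node(host, kind="host")
            G.add_edge(lineage, host, weight=w)
    return G


#: Major eukaryotic supergroups used to summarise host assignments.
EUKARYOTIC_SUPERGROUPS: tuple[str, ...] = (
    "Opisthokonta",
    "Amoebozoa",
    "Excavata",
    "Archaeoplastida",
    "Cryptista",
    "SAR",
)

UNASSIGNED = "unassigned"


def host_fraction_summary(
    candidates: Sequence[HgtCandidate],
    supergroup_of: Mapping[str, str],
) -> dict[str, float]:
    """Proportion of HGT candidates per major eukaryotic supergroup.

    ``supergroup_of`` maps host groups to supergroups; unmapped host groups
    fall into an "unassigned" bucket.  Proportions sum to 1 over all
    candidates; an empty candidate list yields an empty summary.
    """
    if not candidates:
        return {}
    counts: dict[str, int] = {}
    for c in candidates:
        sg = supergroup_of.get(c.host_group, UNASSIGNED)
        counts[sg] = counts.get(sg, 0) + 1
    total = sum(counts.values())
    return {sg: n / total for sg, n in sorted(counts.items())}
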