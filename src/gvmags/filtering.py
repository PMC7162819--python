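"""Bin-level and contig-level filters and dereplication for candidate GVMAGs.

Candidate giant-virus bins recovered from metagenomes are screened in several
passes before they count as genomes:

1. hard copy-number caps on five conserved NCVOGs (bins exceeding any cap are
   dropped);
2. a duplication ratio over sixteen usually-low-copy NCVOGs (total copies /
   distinct markers observed); ratios above 3 indicate non-clonal bins;
3. contig-local removal by the taxonomic affiliation profile of best protein
   hits (rules are configuration; a documented default ships with the
   package);
4. species-level dereplication: single-linkage clusters over ANI > 95 % with
   alignment fraction ≥ 50 %, then removal of within-cluster duplicates that
   share a full-length 100 %-identity marker protein, dropping
   conventionally-binned members first and keeping the largest assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .registry import COPY_NUMBER_CAPS, DEREP6, DUP16, MAX_DUPLICATION_RATIO

__all__ = [
    "copy_number_filter",
    "duplication_ratio",
    "TaxRule",
    "DEFAULT_TAX_RULES",
    "filter_contigs_by_taxonomy",
    "AniEdge",
    "MarkerIdentityHit",
    "GenomeMeta",
    "DereplicationResult",
    "dereplicate",
]


def copy_number_filter(
    markers: Mapping[str, int],
    caps: Mapping[str, int] = COPY_NUMBER_CAPS,
) -> tuple[bool, list[str]]:
    """Check one genome's marker copy numbers against the hard caps.

    A genome fails iff it encodes *strictly more* copies than the cap for any
    capped NCVOG (defaults: NCVOG0023 > 20, NCVOG0038 > 4, NCVOG0076 > 12,
    NCVOG0249 > 7, NCVOG0262 > 4).  Returns ``(passed, reasons)`` where
    ``reasons`` names every violated cap.
    """
    reasons = [
        f"{ncvog}: {markers.get(ncvog, 0)} copies > cap {cap}"
        for ncvog, cap in sorted(caps.items())
        if markers.get(ncvog, 0) > cap
    ]
    return (not reasons, reasons)


def duplication_ratio(
    markers: Mapping[str, int],
    marker_set: frozenset[str] = DUP16,
) -> float | None:
    """Total copies of the duplication-set NCVOGs divided by the number of
    distinct ones observed; ``None`` when none are observed.

    Genomes with a ratio strictly above :data:`~gvmags.registry.MAX_DUPLICATION_RATIO`
    (3) are excluded by callers; a genome with no duplication-set markers at
    all passes this filter but should be flagged — completeness screening
    handles it downstream.
    """
    counts = [markers[m] for m in marker_set if markers.get(m, 0) >= 1]
    if not counts:
        return None
    return sum(counts) / len(counts)


@dataclass(frozen=True)
class TaxRule:
    """One contig-removal rule on the best-hit affiliation profile.

    A contig matches when every ``greater`` fraction is strictly exceeded and
    every ``less`` fraction is strictly undercut; a matching contig is
    removed.  Fractions are of the contig's protein count.
    """

    name: str
    greater: Mapping[str, float] = field(default_factory=dict)
    less: Mapping[str, float] = field(default_factory=dict)


#: Default contig-cleanup rules: drop contigs dominated by cellular best hits
#: with next to no NCLDV signal.  The published thresholds are supplementary
#: material; these defaults are deliberately conservative and overridable.
DEFAULT_TAX_RULES: tuple[TaxRule, ...] = (
    TaxRule("bacterial_dominated", greater={"Bacteria": 0.8}, less={"virus_NCLDV": 0.1}),
    TaxRule("archaeal_dominated", greater={"Archaea": 0.8}, less={"virus_NCLDV": 0.1}),
    TaxRule("eukaryotic_dominated", greater={"Eukaryota": 0.8}, less={"virus_NCLDV": 0.1}),
    TaxRule("phage_dominated", greater={"phage": 0.8}, less={"virus_NCLDV": 0.1}),
)

TAX_COLUMNS = ("Archaea", "Bacteria", "Eukaryota", "phage", "virus_NCLDV", "Unknown")


def filter_contigs_by_taxonomy(
    profile: pd.DataFrame,
    rules: Sequence[TaxRule] = DEFAULT_TAX_RULES,
) -> tuple[list[str], pd.DataFrame]:
    """Apply contig-removal rules to a per-contig affiliation-count table.

    ``profile`` is indexed by contig id with one count column per affiliation
    (Archaea, Bacteria, Eukaryota, phage, virus_NCLDV, Unknown).  Counts are
    converted to fractions of the contig's protein count before rule
    evaluation.  Removal is contig-local: each contig is judged on its own
    profile only.  Returns ``(kept_contig_ids, removal_log)``.
    """
    for rule in rules:
        for col in list(rule.greater) + list(rule.less):
            if col not in profile.columns:
                raise KeyError(f"rule {rule.name!r} references unknown column {col!r}")
    totals = profile.sum(axis=1)
    kept: list[str] = []
    log_rows = []
    for contig, row in profile.iterrows():
        total = totals.loc[contig]
        fracs = (row / total) if total > 0 else row * 0.0
        hit = None
        for rule in rules:
            over = all(fracs[c] > t for c, t in rule.greater.items())
            under = all(fracs[c] < t for c, t in rule.less.items())
            if over and under:
                hit = rule.name
                break
        if hit is None:
            kept.append(str(contig))
        else:
            log_rows.append({"contig_id": contig, "rule": hit})
    return kept, pd.DataFrame(log_rows, columns=["contig_id", "rule"])


@dataclass(frozen=True)
class AniEdge:
    genome_a: str
    genome_b: str
    ani: float  # %
    af_a: float  # alignment fraction of a against b, %
    af_b: float  # alignment fraction of b against a, %


@dataclass(frozen=True)
class MarkerIdentityHit:
    """An all-versus-all marker-protein hit within an ANI cluster."""

    genome_a: str
    genome_b: str
    ncvog: str
    pct_identity: float
    full_length: bool


@dataclass(frozen=True)
class GenomeMeta:
    genome_id: str
    assembly_size: int
    provenance: str = "targeted"  # {targeted, conventional}


@dataclass
class DereplicationResult:
    representatives: list[str]
    cluster_of: dict[str, int]
    removed: list[tuple[str, str]]  # (genome_id, reason)


ANI_THRESHOLD = 95.0
AF_THRESHOLD = 50.0


def dereplicate(
    genomes: Sequence[GenomeMeta],
    ani_edges: Iterable[AniEdge],
    marker_hits: Iterable[MarkerIdentityHit] = (),
    *,
    ani_threshold: float = ANI_THRESHOLD,
    af_threshold: float = AF_THRESHOLD,
    derep_markers: frozenset[str] = DEREP6,
) -> DereplicationResult:
    """Cluster genomes at species level and drop within-cluster duplicates.

    Clusters are connected components (single linkage) of the graph whose
    edges require ANI strictly above 95 % and alignment fraction of at least
    50 % in either direction.  Within each cluster, genomes connected by a
    full-length 100 %-identity hit on any of the six long marker NCVOGs form
    duplicate groups; each group keeps one member, preferring targeted over
    conventional binning provenance, then the largest assembly, then the
    lexicographically smallest genome id.
    """
    meta = {g.genome_id: g for g in genomes}
    G = nx.Graph()
    G.add_nodes_from(meta)
    for e in ani_edges:
        if e.genome_a not in meta or e.genome_b not in meta:
            continue
        if e.ani > ani_threshold and max(e.af_a, e.af_b) >= af_threshold:
            G.add_edge(e.genome_a, e.genome_b)
    cluster_of: dict[str, int] = {}
    # deterministic cluster ids: order components by smallest member id
    comps = sorted(nx.connected_components(G), key=lambda c: min(c))
    for cid, comp in enumerate(comps):
        for g in comp:
            cluster_of[g] = cid

    # duplicate groups: marker-identity links restricted to same cluster
    D = nx.Graph()
    D.add_nodes_from(meta)
    for h in marker_hits:
        if h.genome_a not in meta or h.genome_b not in meta:
            continue
        if h.ncvog not in derep_markers:
            continue
        if not (h.full_length and h.pct_identity >= 100.0):
            continue
        if cluster_of[h.genome_a] != cluster_of[h.genome_b]:
            continue
        D.add_edge(h.genome_a, h.genome_b)

    removed: list[tuple[str, str]] = []
    keep = set(meta)
    for group in nx.connected_components(D):
        if len(group) < 2:
            continue
        ranked = sorted(
            group,
            key=lambda g: (
                meta[g].provenance != "targeted",  # conventional removed first
                -meta[g].assembly_size,
                g,
            ),
        )
        for g in ranked[1:]:
            keep.discard(g)
            removed.append((g, f"duplicate of {ranked[0]}"))
    return DereplicationResult(
        representatives=sorted(keep),
        cluster_of=cluster_of,
        removed=sorted(removed),
    )
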