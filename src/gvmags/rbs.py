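"""Ribosome-binding-site (RBS) motif categorization and genome feature vectors.

Gene callers that perform a full upstream-motif scan report, for each gene, a
short motif string (or no motif) found upstream of the start codon.  The class
profile of these motifs separates giant viruses (NCLDVs) — which carry a
characteristic short alternating A/T ("TATATA") motif — from bacteria,
archaea, eukaryotes and other viruses.  This module

* maps a raw motif string onto one of eleven ordered categories,
* computes the fourteen per-genome (or per-contig) features consumed by the
  NCLDV classifier: the eleven category frequencies plus gene density, coding
  density and mean RBS spacer length, and
* groups genomes by hierarchical clustering of their motif-frequency profile.

Category evaluation is strictly ordered: a motif belongs to the first class
whose rule it satisfies, mirroring the "not already included in a previous
group" construction of the category definitions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "MotifCategory",
    "GeneRecord",
    "FeatureVector",
    "categorize_motif",
    "compute_features",
    "group_genomes",
    "SD_CANONICAL_PATTERNS",
    "FEATURE_NAMES",
    "MOTIF_ALPHABET",
]

MOTIF_ALPHABET = frozenset("ACGTx")

#: 5-bp cores of the canonical Shine–Dalgarno AGGAGG and its printed variants.
#: A motif is SD_Canonical iff it contains a window matching one of these,
#: with literal ``x`` in the motif acting as a single-base wildcard.
SD_CANONICAL_PATTERNS: tuple[str, ...] = ("AGGAG", "GGAGG", "GAGGA")


class MotifCategory(enum.IntEnum):
    """The eleven RBS motif classes, in listing (= precedence) order."""

    NONE = 1
    SD_CANONICAL = 2
    SD_BACTEROIDETES = 3
    OTHER_GA = 4
    TATATA_3_6 = 5
    ONLY_A = 6
    ONLY_T = 7
    DOUBLE_A = 8
    DOUBLE_T = 9
    NO_A = 10
    OTHER = 11

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]


_CATEGORY_LABELS: dict[MotifCategory, str] = {
    MotifCategory.NONE: "None",
    MotifCategory.SD_CANONICAL: "SD_Canonical",
    MotifCategory.SD_BACTEROIDETES: "SD_Bacteroidetes",
    MotifCategory.OTHER_GA: "Other_GA",
    MotifCategory.TATATA_3_6: "TATATA_3.6",
    MotifCategory.ONLY_A: "OnlyA",
    MotifCategory.ONLY_T: "OnlyT",
    MotifCategory.DOUBLE_A: "DoubleA",
    MotifCategory.DOUBLE_T: "DoubleT",
    MotifCategory.NO_A: "NoA",
    MotifCategory.OTHER: "Other",
}

CATEGORY_ORDER: tuple[MotifCategory, ...] = tuple(MotifCategory)

#: Names of the 14 classifier features, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"freq_{c.label}" for c in CATEGORY_ORDER
) + ("gene_density", "coding_density", "mean_spacer")


def _window_matches(window: str, pattern: str) -> bool:
    # motif-side 'x' is a wildcard; pattern side is concrete
    return all(m == "x" or m == p for m, p in zip(window, pattern))


def _contains_canonical_core(motif: str, patterns: Sequence[str]) -> bool:
    for pat in patterns:
        k = len(pat)
        for i in range(len(motif) - k + 1):
            if _window_matches(motif[i : i + k], pat):
                return True
    return False


def _is_bacteroidetes(motif: str) -> bool:
    # full-string match of TA{2,5}T{0,1}
    if not (3 <= len(motif) <= 7) or motif[0] != "T":
        return False
    body = motif[1:]
    if body.endswith("T"):
        body = body[:-1]
    return 2 <= len(body) <= 5 and set(body) == {"A"}


def _is_tatata(motif: str) -> bool:
    # full-string alternating T/A, 3-6 bp, either starting base
    if not (3 <= len(motif) <= 6) or motif[0] not in "AT":
        return False
    return all(
        b in "AT" and b != motif[i - 1] for i, b in enumerate(motif) if i > 0
    ) and all(b in "AT" for b in motif)


def _categorize_concrete(motif: str, patterns: Sequence[str]) -> MotifCategory:
    """Categorize a motif over {A,C,G,T} by the ordered rules."""
    if _contains_canonical_core(motif, patterns):
        return MotifCategory.SD_CANONICAL
    if _is_bacteroidetes(motif):
        return MotifCategory.SD_BACTEROIDETES
    if "GA" in motif:
        return MotifCategory.OTHER_GA
    if _is_tatata(motif):
        return MotifCategory.TATATA_3_6
    if set(motif) == {"A"}:
        return MotifCategory.ONLY_A
    if set(motif) == {"T"}:
        return MotifCategory.ONLY_T
    if "AA" in motif:
        return MotifCategory.DOUBLE_A
    if "TT" in motif:
        return MotifCategory.DOUBLE_T
    if "A" not in motif:
        return MotifCategory.NO_A
    return MotifCategory.OTHER


def categorize_motif(
    motif: str | None,
    *,
    canonical_patterns: Sequence[str] = SD_CANONICAL_PATTERNS,
) -> MotifCategory:
    """Assign an RBS motif string to its category.

    Parameters
    ----------
    motif
        Upstream motif over ``{A,C,G,T}``, possibly containing the wildcard
        character ``x`` (matching any single base), or ``None`` / empty when
        the gene caller predicted no RBS.
    canonical_patterns
        5-bp cores defining the canonical Shine–Dalgarno class; overridable
        to widen or narrow what counts as canonical.

    Returns
    -------
    MotifCategory
        The first category, in listing order, whose rule the motif satisfies.
        A wildcard-containing motif receives the highest-precedence category
        reachable by any concretization of its wildcards.

    Raises
    ------
    ValueError
        If the motif contains characters outside ``{A,C,G,T,x}``.
    """
    if motif is None or motif == "" or motif == "None":
        return MotifCategory.NONE
    bad = set(motif) - MOTIF_ALPHABET
    if bad:
        raise ValueError(f"motif {motif!r} contains invalid characters {sorted(bad)}")
    if "x" not in motif:
        return _categorize_concrete(motif, canonical_patterns)
    # existential wildcard semantics: best (lowest-order) category over all
    # concretizations; motifs are short so the expansion is tiny
    positions = [i for i, b in enumerate(motif) if b == "x"]
    chars = list(motif)
    best = MotifCategory.OTHER
    stack = [0]

    def _expand(idx: int) -> None:
        nonlocal best
        if idx == len(positions):
            cat = _categorize_concrete("".join(chars), canonical_patterns)
            if cat < best:
                best = cat
            return
        for base in "ACGT":
            chars[positions[idx]] = base
            _expand(idx + 1)
        chars[positions[idx]] = "x"

    _expand(0)
    return best


@dataclass(frozen=True)
class GeneRecord:
    """One predicted gene with its upstream-motif annotation.

    Coordinates are 0-based half-open; ``rbs_motif`` is ``None`` when no RBS
    was predicted, in which case ``rbs_spacer_bp`` is ignored.
    """

    contig_id: str
    start: int
    end: int
    strand: str = "+"
    rbs_motif: str | None = None
    rbs_spacer_bp: int = 0
    confidence: float = 100.0
    score: float = 100.0
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id or self.contig_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


#: Sentinel for the mean spacer when no gene carries a predicted RBS.
NO_SPACER = float("nan")


@dataclass(frozen=True)
class FeatureVector:
    """The 14 features of one genome/contig: 11 motif-class frequencies,
    gene density and coding density (both per 10 kb), and mean RBS spacer."""

    motif_freqs: Mapping[str, float]
    gene_density: float
    coding_density: float
    mean_spacer: float
    n_genes: int = 0
    empty: bool = field(default=False, compare=False)

    def as_array(self, motif_only: bool = False) -> np.ndarray:
        freqs = [self.motif_freqs[c.label] for c in CATEGORY_ORDER]
        if motif_only:
            return np.asarray(freqs, dtype=float)
        spacer = 0.0 if math.isnan(self.mean_spacer) else self.mean_spacer
        return np.asarray(
            freqs + [self.gene_density, self.coding_density, spacer], dtype=float
        )


DEFAULT_MIN_CONFIDENCE = 90.0
DEFAULT_MIN_SCORE = 50.0


def compute_features(
    genes: Iterable[GeneRecord],
    sequence_length: int,
    apply_gene_gates: bool = True,
    *,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    min_score: float = DEFAULT_MIN_SCORE,
) -> FeatureVector:
    """Compute the 14-feature vector from predicted genes.

    With ``apply_gene_gates`` (the default) only genes predicted with
    confidence ≥ 90 and score ≥ 50 are counted.  Densities are per 10 kb of
    sequence; the mean spacer averages only over genes with a predicted RBS
    (NaN sentinel when there are none).  Zero counted genes yields an
    all-zero vector flagged ``empty`` rather than an error.
    """
    if sequence_length <= 0:
        raise ValueError("sequence_length must be positive")
    counted = [
        g
        for g in genes
        if not apply_gene_gates
        or (g.confidence >= min_confidence and g.score >= min_score)
    ]
    freqs = {c.label: 0.0 for c in CATEGORY_ORDER}
    if not counted:
        return FeatureVector(
            motif_freqs=freqs,
            gene_density=0.0,
            coding_density=0.0,
            mean_spacer=NO_SPACER,
            n_genes=0,
            empty=True,
        )
    for g in counted:
        freqs[categorize_motif(g.rbs_motif).label] += 1
    n = len(counted)
    for k in freqs:
        freqs[k] /= n
    spacers = [g.rbs_spacer_bp for g in counted if g.rbs_motif]
    return FeatureVector(
        motif_freqs=freqs,
        gene_density=10_000.0 * n / sequence_length,
        coding_density=10_000.0 * sum(g.length for g in counted) / sequence_length,
        mean_spacer=float(np.mean(spacers)) if spacers else NO_SPACER,
        n_genes=n,
    )


def group_genomes(vectors: Sequence[FeatureVector], n_groups: int) -> np.ndarray:
    """Group genomes by hierarchical clustering of motif-frequency profiles.

    Complete-linkage agglomerative clustering on Euclidean distance between
    the 11 motif-class frequency vectors, cut at ``n_groups`` clusters.
    Returns integer labels in ``0..n_groups-1`` in input order.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if len(vectors) < n_groups:
        raise ValueError("need at least n_groups vectors")
    X = np.vstack([v.as_array(motif_only=True) for v in vectors])
    if len(vectors) == n_groups:
        return np.arange(n_groups)
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return np.asarray(labels) - 1
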