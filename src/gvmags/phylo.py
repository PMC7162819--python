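"""Species-tree genome selection and phylogenetic-diversity accounting.

Genomes enter the NCLDV species tree when they carry at least three of the
five core NCVOGs (DNA polymerase B, D5 helicase-primase, packaging ATPase,
superfamily-II helicase, VLTF3-like factor).  Phylogenetic diversity (PD) is
the sum of branch lengths of a tree; the expansion contributed by
metagenome-derived genomes is expressed as the PD ratio of the combined tree
(references + bins) over the reference-only tree, alongside the absolute
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy

from .registry import CORE5

__all__ = [
    "select_for_tree",
    "load_tree",
    "phylogenetic_diversity",
    "pd_fold_increase",
    "PdComparison",
]

MIN_CORE_MARKERS = 3


def select_for_tree(
    tables: Mapping[str, Mapping[str, int]],
    core_set: frozenset[str] = CORE5,
    min_markers: int = MIN_CORE_MARKERS,
) -> list[str]:
    """Genomes with at least three of the five core NCVOGs present.

    Presence (count ≥ 1), not copy number, is what is tested.  Returns the
    selected genome ids sorted.
    """
    return sorted(
        g
        for g, markers in tables.items()
        if sum(1 for m in core_set if markers.get(m, 0) >= 1) >= min_markers
    )


def load_tree(source: str, *, is_path: bool = True) -> dendropy.Tree:
    """Parse a Newick tree with branch lengths (polytomies allowed,
    internal labels ignored)."""
    kwargs = {"path": source} if is_path else {"data": source}
    return dendropy.Tree.get(schema="newick", **kwargs)


def phylogenetic_diversity(tree: dendropy.Tree) -> float:
    """Sum of branch lengths over all edges of the tree.

    Edges without a length (typically the root edge) contribute 0; negative
    lengths raise, as they are not meaningful path distances.  The sum is
    independent of rooting for a fixed unrooted topology.
    """
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if edge.length < 0:
            raise ValueError("tree contains a negative branch length")
        total += edge.length
    return total


@dataclass(frozen=True)
class PdComparison:
    pd_combined: float
    pd_reference: float
    fold: float
    difference: float
    percent_increase: float


def pd_fold_increase(
    tree_combined: dendropy.Tree, tree_reference: dendropy.Tree
) -> PdComparison:
    """Phylogenetic-diversity expansion of the combined tree over the
    reference tree, as a fold ratio and as percentage increase.

    The fold is PD(combined)/PD(reference); the absolute PD difference is
    reported too.  Requires both PDs positive.
    """
    pd_c = phylogenetic_diversity(tree_combined)
    pd_r = phylogenetic_diversity(tree_reference)
    if pd_r <= 0 or pd_c <= 0:
        raise ValueError("both trees must have positive total branch length")
    return PdComparison(
        pd_combined=pd_c,
        pd_reference=pd_r,
        fold=pd_c / pd_r,
        difference=pd_c - pd_r,
        percent_increase=100.0 * (pd_c - pd_r) / pd_r,
    )
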