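"""Parameter-recovery benchmarks on planted synthetic data.

Each function here runs one pipeline stage end to end on inputs from
:mod:`gvmags.synth` and measures how well the stage recovers the planted
ground truth.  They are the package's own calibration experiments — run them
after changing a rule or a generator to confirm the stage still recovers
what was planted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import NCLDV_BINARY_LABEL, cross_validate
from .hgt import build_network, detect_hgt
from .io import genes_from_table
from .mcp import NOVEL, assign, train_lineage_classifier
from .quality import build_baseline, completeness_tier, contamination_tier
from .rbs import compute_features
from .synth import (
    DEFAULT_GROUP_PROFILES,
    generate_gene_table,
    generate_hgt_scenario,
    generate_marker_table,
    generate_mcp_scores,
)

__all__ = [
    "simulate_feature_vectors",
    "classifier_cv_benchmark",
    "quality_tier_recovery",
    "mcp_assignment_benchmark",
    "hgt_recovery_benchmark",
]


def simulate_feature_vectors(per_group=200, genome_length=100_000, seed=0):
    """Feature vectors for ``per_group`` genomes of each default group."""
    vectors, groups = [], []
    for gi, name in enumerate(sorted(DEFAULT_GROUP_PROFILES)):
        profile = DEFAULT_GROUP_PROFILES[name]
        for j in range(per_group):
            table, _ = generate_gene_table(
                profile, genome_length, seed=seed + 100_000 * gi + j
            )
            vectors.append(compute_features(genes_from_table(table), genome_length))
            groups.append(name)
    return vectors, groups


def classifier_cv_benchmark(
    per_group=200, genome_length=100_000, folds=10, n_trees=200, seed=0
) -> dict[str, pd.DataFrame]:
    """10-fold CV of the binary and group classifiers on well-separated
    synthetic genome groups; returns both per-group accuracy tables."""
    vectors, groups = simulate_feature_vectors(per_group, genome_length, seed)
    binary = [
        NCLDV_BINARY_LABEL if g == "NCLDV (non-pandoraviruses)" else "Other"
        for g in groups
    ]
    return {
        "binary": cross_validate(
            vectors, binary, folds=folds, mode="binary", seed=seed, n_trees=n_trees
        ),
        "group": cross_validate(
            vectors, groups, folds=folds, mode="group", seed=seed, n_trees=n_trees
        ),
    }


_COMPLETENESS_SETPOINTS = (0.35, 0.65, 0.75, 1.0)
# target multicopy counts giving contamination deviations 0.6 / 1.6 / 2.6
# against a superclade baseline with five multicopy markers on average
_CONTAMINATION_TARGETS = {"low": 3, "medium": 8, "high": 13}
_COMPLETENESS_TIER = {0.35: "low", 0.65: "medium", 0.75: "medium", 1.0: "high"}


def quality_tier_recovery(n_trials=500, seed=0) -> dict[str, float]:
    """Fraction of synthetic bins whose planted tiers are recovered.

    Bins are generated from a 20-marker single-copy archetype at
    completeness and contamination set-points at least 10 % away from every
    tier boundary; the superclade baseline comes from reference genomes with
    five multicopy markers each (mean_present 20, mean_multi 5).
    """
    rng = np.random.default_rng(seed)
    markers = [f"NCVOG{i:04d}" for i in (
        22, 23, 35, 36, 38, 52, 59, 76, 211, 249, 256, 262, 271,
        1060, 1088, 1115, 1117, 1122, 1127, 1192)]
    marker_set = frozenset(markers)
    archetype = {m: 1 for m in markers}
    references = {}
    for i in range(8):
        table = {m: 1 for m in markers}
        for m in markers[i : i + 5]:
            table[m] = 2
        references[f"ref{i}"] = table
    baseline = build_baseline(references, "SC1", marker_set)
    assert baseline.mean_multi == 5.0 and baseline.mean_present == 20.0

    ok_contam = ok_compl = 0
    for trial in range(n_trials):
        c = float(rng.choice(_COMPLETENESS_SETPOINTS))
        n_keep = round(20 * c)
        feasible = [t for t, m in _CONTAMINATION_TARGETS.items() if m <= n_keep]
        target_contam = str(rng.choice(feasible))
        m_target = _CONTAMINATION_TARGETS[target_contam]
        factor = 1.0 + m_target / n_keep
        bin_table, _ = generate_marker_table(
            archetype, c, factor, seed=int(rng.integers(2**31))
        )
        got_contam, _ = contamination_tier(bin_table, baseline, marker_set)
        got_compl, _ = completeness_tier(bin_table, baseline, marker_set)
        ok_contam += got_contam == target_contam
        ok_compl += got_compl == _COMPLETENESS_TIER[c]
    return {
        "contamination_recovery": ok_contam / n_trials,
        "completeness_recovery": ok_compl / n_trials,
        "n_trials": n_trials,
    }


def mcp_assignment_benchmark(
    n_lineages=5, n_train=500, n_eval=400, separation=8.0,
    novel_fraction=0.25, seed=0,
) -> dict[str, float]:
    """Train the lineage classifier on one planted score matrix and measure
    assignment accuracy and novel recall on an independently drawn one."""
    train_scores, train_truth = generate_mcp_scores(
        n_lineages, n_train, separation, novel_fraction=0.0, seed=seed
    )
    labels = [train_truth.labels[p] for p in train_scores.index]
    model = train_lineage_classifier(train_scores, labels, seed=seed)
    eval_scores, eval_truth = generate_mcp_scores(
        n_lineages, n_eval, separation, novel_fraction=novel_fraction, seed=seed + 1
    )
    assigns = assign(model, eval_scores)
    member = [a for a in assigns if eval_truth.labels[a.protein_id] != NOVEL]
    novel = [a for a in assigns if eval_truth.labels[a.protein_id] == NOVEL]
    return {
        "assignment_accuracy": float(
            np.mean([a.lineage == eval_truth.labels[a.protein_id] for a in member])
        ),
        "novel_recall": float(np.mean([a.lineage == NOVEL for a in novel])),
        "n_member": len(member),
        "n_novel": len(novel),
    }


def hgt_recovery_benchmark(seed=0) -> dict[str, float]:
    """Detect planted transfers among gate-failing background and check the
    network edge weights equal the planted counts."""
    edges = [("L1", "H1", 5), ("L2", "H3", 9), ("L4", "H2", 2)]
    records, truth = generate_hgt_scenario(
        4, 4, edges, background_hits=120, seed=seed
    )
    candidates = detect_hgt(records)
    got = {c.query_protein: c.host_group for c in candidates}
    tp = sum(1 for p, h in got.items() if truth.labels.get(p) == h)
    precision = tp / len(got) if got else 1.0
    recall = tp / len(truth.labels) if truth.labels else 1.0
    G = build_network(candidates, min_weight=1)
    weights_match = all(
        G.has_edge(l, h) and G[l][h]["weight"] == n for l, h, n in edges
    )
    return {
        "precision": precision,
        "recall": recall,
        "edge_weights_match": float(weights_match),
        "n_candidates": len(candidates),
    }
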