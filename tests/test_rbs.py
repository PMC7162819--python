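"""Motif categorization and genome feature extraction."""

import itertools
import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gvmags.rbs import (
    CATEGORY_ORDER,
    FeatureVector,
    GeneRecord,
    MotifCategory,
    categorize_motif,
    compute_features,
    group_genomes,
)


def oracle_categorize(motif):
    """Independent rule oracle: regex/set re-statement of the 11 ordered rules."""
    if motif is None or motif == "":
        return "None"
    if re.search(r"AGGAG|GGAGG|GAGGA", motif):
        return "SD_Canonical"
    if re.fullmatch(r"TA{2,5}T?", motif):
        return "SD_Bacteroidetes"
    if "GA" in motif:
        return "Other_GA"
    if (
        3 <= len(motif) <= 6
        and set(motif) <= {"A", "T"}
        and all(motif[i] != motif[i + 1] for i in range(len(motif) - 1))
    ):
        return "TATATA_3.6"
    if re.fullmatch(r"A+", motif):
        return "OnlyA"
    if re.fullmatch(r"T+", motif):
        return "OnlyT"
    if "AA" in motif:
        return "DoubleA"
    if "TT" in motif:
        return "DoubleT"
    if "A" not in motif:
        return "NoA"
    return "Other"


@pytest.mark.parametrize(
    "motif,expected",
    [
        ("AGGAG", "SD_Canonical"),
        ("AGxAG", "SD_Canonical"),
        ("GAGGA", "SD_Canonical"),
        ("TAAAT", "SD_Bacteroidetes"),
        ("TAA", "SD_Bacteroidetes"),
        ("TAAAAAT", "SD_Bacteroidetes"),
        ("GAGGGA", "Other_GA"),
        ("TAT", "TATATA_3.6"),
        ("ATAT", "TATATA_3.6"),
        ("TATAT", "TATATA_3.6"),
        ("TATATA", "TATATA_3.6"),
        (None, "None"),
        ("", "None"),
        ("AAAAA", "OnlyA"),
        ("TTTTT", "OnlyT"),
        ("AAAAC", "DoubleA"),
        ("TACTT", "DoubleT"),
        ("TCTCG", "NoA"),
        ("CACGC", "Other"),
    ],
)
def test_worked_exemplars(motif, expected):
    assert categorize_motif(motif).label == expected


def test_invalid_characters_rejected():
    with pytest.raises(ValueError):
        categorize_motif("AGGAN")


def test_category_listing_order_is_total():
    assert len(CATEGORY_ORDER) == 11
    assert [c.value for c in CATEGORY_ORDER] == list(range(1, 12))


def test_oracle_agreement_short_motifs():
    """Exhaustive agreement with the independent oracle up to length 4."""
    for L in (1, 2, 3, 4):
        for combo in itertools.product("ACGT", repeat=L):
            m = "".join(combo)
            assert categorize_motif(m).label == oracle_categorize(m), m


def test_wildcard_takes_best_reachable_category():
    # AGxAG can concretize to AGGAG (canonical); TxT can reach TAT
    assert categorize_motif("AGxAG") is MotifCategory.SD_CANONICAL
    assert categorize_motif("TxT") is MotifCategory.TATATA_3_6
    # xxxxx can reach OnlyA via concretization but canonical needs 5 matching
    assert categorize_motif("xxxxx") is MotifCategory.SD_CANONICAL


def _gene(start, end, motif, spacer=5, conf=95.0, score=80.0):
    return GeneRecord(
        contig_id="c1",
        start=start,
        end=end,
        rbs_motif=motif,
        rbs_spacer_bp=spacer,
        confidence=conf,
        score=score,
    )


def test_density_arithmetic():
    genes = [_gene(i * 1000, i * 1000 + 944, "TATAT") for i in range(9)]
    # 9 genes, 8,496 coding bp on 10 kb
    fv = compute_features(genes, 10_000)
    assert fv.gene_density == pytest.approx(9.0)
    assert fv.coding_density == pytest.approx(9 * 944)


def test_hand_counted_motif_frequencies():
    genes = [_gene(i * 200, i * 200 + 100, "TATAT") for i in range(6)] + [
        _gene(2000 + i * 200, 2000 + i * 200 + 100, "AGGAG") for i in range(4)
    ]
    fv = compute_features(genes, 10_000)
    assert fv.motif_freqs["TATATA_3.6"] == pytest.approx(0.6)
    assert fv.motif_freqs["SD_Canonical"] == pytest.approx(0.4)


def test_all_motif_absent():
    genes = [_gene(i * 200, i * 200 + 100, None) for i in range(5)]
    fv = compute_features(genes, 10_000)
    assert fv.motif_freqs["None"] == pytest.approx(1.0)
    assert math.isnan(fv.mean_spacer)


def test_gene_gates_exclude_low_confidence_and_score():
    genes = [
        _gene(0, 100, "TATAT", conf=95, score=80),
        _gene(200, 300, "AGGAG", conf=80, score=80),  # fails confidence
        _gene(400, 500, "AGGAG", conf=95, score=40),  # fails score
    ]
    fv = compute_features(genes, 10_000)
    assert fv.n_genes == 1
    assert fv.motif_freqs["TATATA_3.6"] == 1.0
    assert compute_features(genes, 10_000, apply_gene_gates=False).n_genes == 3


def test_empty_gene_set_flagged_not_raised():
    fv = compute_features([], 10_000)
    assert fv.empty and fv.n_genes == 0
    assert sum(fv.motif_freqs.values()) == 0.0


def test_mean_spacer_averages_only_rbs_genes():
    genes = [_gene(0, 100, "TATAT", spacer=4), _gene(200, 300, None, spacer=99)]
    fv = compute_features(genes, 10_000)
    assert fv.mean_spacer == pytest.approx(4.0)


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["TATAT", "AGGAG", "AAAAC", None]),
            st.integers(min_value=0, max_value=20),
        ),
        min_size=1,
        max_size=30,
    )
)
@settings(max_examples=50, deadline=None)
def test_frequencies_sum_to_one_and_order_invariant(entries):
    genes = [
        _gene(i * 100, i * 100 + 50, m, spacer=s) for i, (m, s) in enumerate(entries)
    ]
    fv = compute_features(genes, 100_000)
    assert sum(fv.motif_freqs.values()) == pytest.approx(1.0)
    fv_rev = compute_features(list(reversed(genes)), 100_000)
    assert fv.motif_freqs == pytest.approx(fv_rev.motif_freqs)
    assert fv.gene_density == pytest.approx(fv_rev.gene_density)


def test_doubling_genes_and_length_preserves_densities():
    genes = [_gene(i * 500, i * 500 + 300, "TATAT") for i in range(10)]
    fv1 = compute_features(genes, 20_000)
    doubled = genes + [
        _gene(g.start + 20_000, g.end + 20_000, g.rbs_motif) for g in genes
    ]
    fv2 = compute_features(doubled, 40_000)
    assert fv2.gene_density == pytest.approx(fv1.gene_density)
    assert fv2.coding_density == pytest.approx(fv1.coding_density)


def _vec(freqs):
    full = {c.label: 0.0 for c in CATEGORY_ORDER}
    full.update(freqs)
    return FeatureVector(full, 9.0, 8500.0, 7.0)


def test_grouping_separates_tight_clusters():
    a = [_vec({"TATATA_3.6": 0.9, "None": 0.1}) for _ in range(5)]
    b = [_vec({"SD_Canonical": 0.9, "None": 0.1}) for _ in range(5)]
    labels = group_genomes(a + b, 2)
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
    assert labels[0] != labels[5]


def test_grouping_degenerate_and_singleton_cases():
    same = [_vec({"None": 1.0}) for _ in range(4)]
    labels = np.asarray(group_genomes(same, 2))
    assert set(labels) <= {0, 1}  # deterministic arbitrary split
    assert list(group_genomes(same, 4)) == [0, 1, 2, 3]
    with pytest.raises(ValueError):
        group_genomes(same, 1)
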