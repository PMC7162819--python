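"""NCLDV classifier training, cross-validation and the contig score rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gvmags.classify import (
    NCLDV_BINARY_LABEL,
    cross_validate,
    score_contig,
    select_for_binning,
    train,
)
from gvmags.io import genes_from_table
from gvmags.rbs import compute_features
from gvmags.synth import DEFAULT_GROUP_PROFILES, generate_gene_table

N_TREES = 60  # plenty for the separable fixtures used here


def _vectors(profile_names, per_group, length=50_000, seed0=0):
    vectors, labels = [], []
    for gi, name in enumerate(profile_names):
        for j in range(per_group):
            tbl, _ = generate_gene_table(
                DEFAULT_GROUP_PROFILES[name], length, seed=seed0 + 1000 * gi + j
            )
            vectors.append(compute_features(genes_from_table(tbl), length))
            labels.append(name)
    return vectors, labels


@pytest.fixture(scope="module")
def separable_binary():
    vectors, groups = _vectors(
        ["NCLDV (non-pandoraviruses)", "canonical bacteria and archaea"], 30
    )
    labels = [
        NCLDV_BINARY_LABEL if g.startswith("NCLDV") else "Other" for g in groups
    ]
    return vectors, labels


def test_training_accuracy_on_separable_fixture(separable_binary):
    vectors, labels = separable_binary
    model = train(vectors, labels, seed=0, n_trees=N_TREES)
    preds = model.predict(vectors)
    assert all(p.label == t for p, t in zip(preds, labels))
    assert all(0.0 <= p.ncldv_prob <= 1.0 for p in preds)


def test_training_is_deterministic(separable_binary):
    vectors, labels = separable_binary
    p1 = train(vectors, labels, seed=7, n_trees=N_TREES).predict(vectors)
    p2 = train(vectors, labels, seed=7, n_trees=N_TREES).predict(vectors)
    assert p1 == p2


def test_single_class_and_length_mismatch_rejected(separable_binary):
    vectors, labels = separable_binary
    with pytest.raises(ValueError):
        train(vectors, ["Other"] * len(vectors))
    with pytest.raises(ValueError):
        train(vectors, labels[:-1])


def test_permuted_labels_give_chance_accuracy(separable_binary):
    vectors, labels = separable_binary
    rng = np.random.default_rng(5)
    shuffled = list(rng.permutation(labels))
    table = cross_validate(vectors, shuffled, folds=5, seed=0, n_trees=N_TREES)
    # balanced binary null: per-class sensitivity within a generous binomial
    # band around 0.5 (n = 30 per class)
    assert (table.sensitivity.between(0.2, 0.8)).all()


def test_cross_validation_perfect_on_separable_fixture(separable_binary):
    vectors, labels = separable_binary
    table = cross_validate(vectors, labels, folds=5, seed=0, n_trees=N_TREES)
    assert (table.sensitivity == 1.0).all()
    assert (table.specificity == 1.0).all()


def test_contaminated_group_degrades_only_its_own_sensitivity():
    vectors, groups = _vectors(
        ["NCLDV (non-pandoraviruses)", "canonical bacteria and archaea",
         "bacteroidetes-like"], 20
    )
    # relabel some canonical-bacteria vectors as bacteroidetes: the
    # bacteroidetes class now contains off-distribution members
    poisoned = list(groups)
    swap = [i for i, g in enumerate(groups) if g == "canonical bacteria and archaea"][:8]
    for i in swap:
        poisoned[i] = "bacteroidetes-like"
    table = cross_validate(vectors, poisoned, folds=5, seed=0, n_trees=N_TREES)
    by = table.set_index("group")
    assert by.loc["bacteroidetes-like", "sensitivity"] < 1.0
    assert by.loc["NCLDV (non-pandoraviruses)", "sensitivity"] == 1.0


def test_leave_one_out_matches_brute_force_oracle():
    vectors, groups = _vectors(
        ["NCLDV (non-pandoraviruses)", "protists & fungi"], 6
    )
    labels = [NCLDV_BINARY_LABEL if g.startswith("NCLDV") else "Other" for g in groups]
    table = cross_validate(vectors, labels, folds=len(labels), seed=3, n_trees=N_TREES)

    # brute-force leave-one-out with a freshly seeded forest per split
    from sklearn.ensemble import RandomForestClassifier

    X = np.vstack([v.as_array() for v in vectors])
    y = np.asarray(labels)
    preds = []
    for i in range(len(y)):
        mask = np.ones(len(y), bool)
        mask[i] = False
        est = RandomForestClassifier(n_estimators=N_TREES, random_state=3)
        est.fit(X[mask], y[mask])
        preds.append(est.predict(X[~mask])[0])
    preds = np.asarray(preds)
    for cls in sorted(set(labels)):
        tp = np.sum((y == cls) & (preds == cls))
        fn = np.sum((y == cls) & (preds != cls))
        expected = tp / (tp + fn)
        got = table.set_index("group").loc[cls, "sensitivity"]
        assert got == pytest.approx(expected)


def test_small_class_triggers_fold_reduction_warning(separable_binary):
    vectors, labels = separable_binary
    few = vectors[:30] + vectors[-3:]
    few_labels = labels[:30] + labels[-3:]
    with pytest.warns(UserWarning, match="reducing folds"):
        cross_validate(few, few_labels, folds=10, seed=0, n_trees=10)


@pytest.mark.parametrize(
    "ratio,prob,label,expected",
    [
        (0.4, 0.5, NCLDV_BINARY_LABEL, 2),
        (0.0, 0.05, "Other", 0),
        (0.35, 0.05, "Other", 1),
        (0.0, 0.2, "Other", 1),
        (0.0, 0.05, NCLDV_BINARY_LABEL, 1),
        (0.31, 0.0, NCLDV_BINARY_LABEL, 2),
        (0.3, 0.3, NCLDV_BINARY_LABEL, 1),  # strict > on both thresholds
        (0.3, 0.1, "Other", 0),
        (0.0, 0.31, "Other", 1),  # prob > 0.3 without NCLDV label is only 1
    ],
)
def test_contig_score_rule(ratio, prob, label, expected):
    assert score_contig(ratio, prob, label) == expected


def test_contig_score_alternative_parse():
    # under "A or (B and C)", high TATATA alone reaches score 2
    assert score_contig(0.4, 0.0, "Other", score2_requires_ncldv_label=False) == 2
    assert score_contig(0.4, 0.0, "Other") == 1


@given(
    r1=st.floats(0, 1), r2=st.floats(0, 1), p1=st.floats(0, 1), p2=st.floats(0, 1)
)
@settings(max_examples=200, deadline=None)
def test_contig_score_monotone(r1, r2, p1, p2):
    lo_r, hi_r = sorted([r1, r2])
    lo_p, hi_p = sorted([p1, p2])
    s_low = score_contig(lo_r, lo_p, "Other")
    assert score_contig(hi_r, hi_p, "Other") >= s_low
    assert score_contig(lo_r, lo_p, NCLDV_BINARY_LABEL) >= s_low


@pytest.mark.parametrize(
    "score,hits,n_genes,expected",
    [
        (0, 1, 5, True),  # exactly 20% of genes hit
        (2, 0, 5, True),  # RBS score alone selects
        (1, 0, 5, True),
        (0, 0, 5, False),
        (0, 19, 100, False),  # 0.19 just below the boundary
        (0, 20, 100, True),
        (0, 1, 6, False),  # 1/6 < 1/5, exact rational comparison
    ],
)
def test_select_for_binning_boundaries(score, hits, n_genes, expected):
    assert select_for_binning(score, hits=hits, n_genes=n_genes) is expected


def test_select_for_binning_accepts_plain_fraction():
    assert select_for_binning(0, 0.2) is True
    assert select_for_binning(0, 0.1999) is False
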