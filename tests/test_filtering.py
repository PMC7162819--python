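"""Bin/contig filters and dereplication."""

import numpy as np
import pandas as pd
import pytest

from gvmags.filtering import (
    DEFAULT_TAX_RULES,
    AniEdge,
    GenomeMeta,
    MarkerIdentityHit,
    TaxRule,
    copy_number_filter,
    dereplicate,
    duplication_ratio,
    filter_contigs_by_taxonomy,
)
from gvmags.registry import COPY_NUMBER_CAPS, DUP16


def test_copy_cap_violation_and_boundary():
    ok, reasons = copy_number_filter({"NCVOG0023": 21})
    assert not ok and "NCVOG0023" in reasons[0]
    ok, reasons = copy_number_filter({"NCVOG0038": 4})  # strict "more than"
    assert ok and reasons == []
    at_limit = dict(COPY_NUMBER_CAPS)  # every marker exactly at its cap
    ok, reasons = copy_number_filter(at_limit)
    assert ok and reasons == []


def test_copy_cap_reports_all_violations():
    bad = {m: c + 1 for m, c in COPY_NUMBER_CAPS.items()}
    ok, reasons = copy_number_filter(bad)
    assert not ok and len(reasons) == len(COPY_NUMBER_CAPS)


def test_duplication_ratio_arithmetic():
    singles = {m: 1 for m in DUP16}
    assert duplication_ratio(singles) == pytest.approx(1.0)
    table = dict(singles)
    two = sorted(DUP16)[:2]
    for m in two:
        table[m] = 2
    assert duplication_ratio(table) == pytest.approx(18 / 16)
    assert duplication_ratio({}) is None
    assert duplication_ratio({"NCVOG9999": 5}) is None  # non-DUP16 ignored


def test_duplication_ratio_ignores_markers_outside_set():
    table = {m: 1 for m in DUP16}
    table["NCVOG0023"] = 50  # core marker, not in DUP16
    assert duplication_ratio(table) == pytest.approx(1.0)


def _profile(rows):
    return pd.DataFrame(rows).set_index("contig_id")


def test_taxonomy_rule_application():
    prof = _profile(
        [
            {"contig_id": "c1", "Archaea": 0, "Bacteria": 9, "Eukaryota": 0,
             "phage": 0, "virus_NCLDV": 0, "Unknown": 1},
            {"contig_id": "c2", "Archaea": 0, "Bacteria": 0, "Eukaryota": 0,
             "phage": 0, "virus_NCLDV": 0, "Unknown": 10},
            {"contig_id": "c3", "Archaea": 0, "Bacteria": 2, "Eukaryota": 0,
             "phage": 0, "virus_NCLDV": 7, "Unknown": 1},
        ]
    )
    rules = [TaxRule("bac", greater={"Bacteria": 0.8}, less={"virus_NCLDV": 0.1})]
    kept, log = filter_contigs_by_taxonomy(prof, rules)
    assert kept == ["c2", "c3"]  # all-Unknown contig is kept
    assert list(log.contig_id) == ["c1"] and list(log.rule) == ["bac"]


def test_empty_rule_set_keeps_everything():
    prof = _profile(
        [{"contig_id": "c1", "Archaea": 0, "Bacteria": 10, "Eukaryota": 0,
          "phage": 0, "virus_NCLDV": 0, "Unknown": 0}]
    )
    kept, log = filter_contigs_by_taxonomy(prof, [])
    assert kept == ["c1"] and log.empty


def test_unknown_rule_column_rejected():
    prof = _profile(
        [{"contig_id": "c1", "Archaea": 1, "Bacteria": 0, "Eukaryota": 0,
          "phage": 0, "virus_NCLDV": 0, "Unknown": 0}]
    )
    with pytest.raises(KeyError):
        filter_contigs_by_taxonomy(prof, [TaxRule("x", greater={"Plants": 0.5})])


def test_contig_removal_is_local():
    rows = [
        {"contig_id": f"c{i}", "Archaea": 0, "Bacteria": 9 if i % 2 else 0,
         "Eukaryota": 0, "phage": 0, "virus_NCLDV": 0 if i % 2 else 9,
         "Unknown": 1}
        for i in range(6)
    ]
    prof = _profile(rows)
    kept_all, _ = filter_contigs_by_taxonomy(prof, DEFAULT_TAX_RULES)
    # decisions are unchanged when any other contig is withheld
    for drop in prof.index:
        sub = prof.drop(index=drop)
        kept_sub, _ = filter_contigs_by_taxonomy(sub, DEFAULT_TAX_RULES)
        assert set(kept_sub) == set(kept_all) - {drop}


def _meta(gid, size=100_000, prov="targeted"):
    return GenomeMeta(gid, size, prov)


def test_single_linkage_transitivity():
    genomes = [_meta(g) for g in "ABC"]
    edges = [
        AniEdge("A", "B", 96.0, 60.0, 55.0),
        AniEdge("B", "C", 96.0, 60.0, 55.0),
        AniEdge("A", "C", 80.0, 10.0, 10.0),  # below cutoff
    ]
    res = dereplicate(genomes, edges)
    assert res.cluster_of["A"] == res.cluster_of["B"] == res.cluster_of["C"]
    assert res.representatives == ["A", "B", "C"]  # no marker duplicates


def test_ani_edge_requires_both_thresholds():
    genomes = [_meta(g) for g in "AB"]
    for ani, af1, af2 in [(95.0, 60, 60), (96.0, 40, 49.9)]:
        res = dereplicate(genomes, [AniEdge("A", "B", ani, af1, af2)])
        assert res.cluster_of["A"] != res.cluster_of["B"]
    # AF of either direction suffices
    res = dereplicate(genomes, [AniEdge("A", "B", 96.0, 40.0, 50.0)])
    assert res.cluster_of["A"] == res.cluster_of["B"]


def _dup_hit(a, b, ncvog="NCVOG0022"):
    return MarkerIdentityHit(a, b, ncvog, 100.0, True)


def test_duplicate_provenance_then_size_then_id():
    edge = [AniEdge("A", "B", 97.0, 70.0, 70.0)]
    # conventional removed first even at equal size
    res = dereplicate(
        [_meta("A", 100, "targeted"), _meta("B", 100, "conventional")],
        edge, [_dup_hit("A", "B")],
    )
    assert res.representatives == ["A"]
    # both targeted: largest assembly retained
    res = dereplicate(
        [_meta("A", 200_000), _meta("B", 300_000)], edge, [_dup_hit("A", "B")]
    )
    assert res.representatives == ["B"]
    # full tie: smallest id retained
    res = dereplicate([_meta("A"), _meta("B")], edge, [_dup_hit("B", "A")])
    assert res.representatives == ["A"]
    assert res.removed == [("B", "duplicate of A")]


def test_marker_duplicates_need_full_length_identity_and_same_cluster():
    genomes = [_meta("A"), _meta("B")]
    edge = [AniEdge("A", "B", 97.0, 70.0, 70.0)]
    # partial-length or <100% identity hits do not mark duplicates
    res = dereplicate(genomes, edge, [MarkerIdentityHit("A", "B", "NCVOG0022", 100.0, False)])
    assert res.representatives == ["A", "B"]
    res = dereplicate(genomes, edge, [MarkerIdentityHit("A", "B", "NCVOG0022", 99.9, True)])
    assert res.representatives == ["A", "B"]
    # marker outside the six-long-marker registry is ignored
    res = dereplicate(genomes, edge, [_dup_hit("A", "B", "NCVOG0035")])
    assert res.representatives == ["A", "B"]
    # identical hit across different clusters is ignored
    res = dereplicate(genomes, [], [_dup_hit("A", "B")])
    assert res.representatives == ["A", "B"]


class _DSU:
    """Union-find oracle for the ANI cluster partition."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def test_cluster_partition_matches_union_find_oracle():
    rng = np.random.default_rng(42)
    for trial in range(60):
        n = int(rng.integers(2, 51))
        ids = [f"g{i}" for i in range(n)]
        genomes = [_meta(g) for g in ids]
        edges = []
        dsu = _DSU(ids)
        for _ in range(int(rng.integers(0, 3 * n))):
            a, b = rng.choice(n, 2, replace=False)
            ani = float(rng.uniform(80, 100))
            af1 = float(rng.uniform(0, 100))
            af2 = float(rng.uniform(0, 100))
            edges.append(AniEdge(ids[a], ids[b], ani, af1, af2))
            if ani > 95.0 and max(af1, af2) >= 50.0:
                dsu.union(ids[a], ids[b])
        res = dereplicate(genomes, edges)
        for a in ids:
            for b in ids:
                same_oracle = dsu.find(a) == dsu.find(b)
                same_impl = res.cluster_of[a] == res.cluster_of[b]
                assert same_oracle == same_impl, (trial, a, b)
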