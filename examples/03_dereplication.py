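"""Dereplicate bins at species level (95 % ANI) and drop duplicates.

Three genomes form one ANI cluster by single linkage; two of them share a
full-length 100 %-identity marker protein and are therefore duplicates of
the same assembly — the conventionally binned one is removed first.
"""

from gvmags.filtering import (
    AniEdge,
    GenomeMeta,
    MarkerIdentityHit,
    dereplicate,
)

genomes = [
    GenomeMeta("GVMAG_A", assembly_size=420_000, provenance="targeted"),
    GenomeMeta("GVMAG_B", assembly_size=450_000, provenance="conventional"),
    GenomeMeta("GVMAG_C", assembly_size=300_000, provenance="targeted"),
]
ani = [
    AniEdge("GVMAG_A", "GVMAG_B", ani=97.5, af_a=82.0, af_b=78.0),
    AniEdge("GVMAG_B", "GVMAG_C", ani=96.1, af_a=61.0, af_b=55.0),
]
marker_hits = [MarkerIdentityHit("GVMAG_A", "GVMAG_B", "NCVOG0023", 100.0, True)]

result = dereplicate(genomes, ani, marker_hits)
print("cluster membership :", result.cluster_of)
print("representatives    :", result.representatives)
print("removed            :", result.removed)
# A and B are marker-identical duplicates within the 95 % ANI cluster; B is
# dropped despite its larger assembly because conventionally binned
# duplicates are removed first. C stays: same species cluster, but no
# full-length identical marker.
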