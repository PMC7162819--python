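"""Classify contigs as giant-virus or not from their RBS motif profile.

Generates synthetic genomes for two groups (NCLDV vs canonical prokaryotes),
computes the 14 RBS/density features for each, trains the binary
random-forest classifier and scores a fresh NCLDV contig with the 0/1/2
targeted-binning rule.
"""

from gvmags.classify import score_contig, select_for_binning, train
from gvmags.io import genes_from_table
from gvmags.rbs import compute_features
from gvmags.synth import DEFAULT_GROUP_PROFILES, generate_gene_table

NCLDV = "NCLDV (non-pandoraviruses)"
BACT = "canonical bacteria and archaea"

vectors, labels = [], []
for gi, group in enumerate([NCLDV, BACT]):
    for j in range(40):
        table, _ = generate_gene_table(
            DEFAULT_GROUP_PROFILES[group], 50_000, seed=1000 * gi + j
        )
        vectors.append(compute_features(genes_from_table(table), 50_000))
        labels.append("Virus_NCLDV" if group == NCLDV else "Other")

model = train(vectors, labels, mode="binary", seed=0, n_trees=200)

contig, _ = generate_gene_table(DEFAULT_GROUP_PROFILES[NCLDV], 20_000, seed=999)
features = compute_features(genes_from_table(contig), 20_000)
pred = model.predict([features])[0]
ratio = features.motif_freqs["TATATA_3.6"]
score = score_contig(ratio, pred.ncldv_prob, pred.label)

print(f"TATATA motif frequency : {ratio:.3f}")
print(f"NCLDV probability      : {pred.ncldv_prob:.3f}  (label: {pred.label})")
print(f"RBS contig score       : {score}")
print(f"selected for binning   : {select_for_binning(score, hits=0, n_genes=5)}")
# A score of 2 means the contig shows both the alternating-A/T motif signal
# and a confident NCLDV prediction; any score >= 1 sends it to binning.
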