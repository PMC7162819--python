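# gvmags

Decision logic for mining **giant-virus genomes** (nucleocytoplasmic large
DNA viruses, NCLDV) from metagenomes, packaged as a tested Python library
with a thin `gvmag` command-line wrapper.

Giant viruses infect protists, algae and animals, yet most known genomes
come from co-cultivation with a handful of laboratory hosts. Mining public
metagenomes instead requires a chain of decisions: which contigs look viral,
which bins are credible genomes, how complete and contaminated each bin is,
which lineage an environmental capsid protein belongs to, and which
eukaryotes a viral lineage exchanged genes with. This package implements
that chain for users who already have the standard upstream products (gene
calls with ribosome-binding-site motifs, HMM marker hits, BLAST tabular
hits, ANI tables, Newick trees) and want reproducible, testable downstream
decisions.

## What is implemented

* **RBS motif profiling** (`gvmags.rbs`) — classifies upstream motifs into
  11 ordered categories (`None`, `SD_Canonical`, `SD_Bacteroidetes`,
  `Other_GA`, `TATATA_3.6`, `OnlyA`, `OnlyT`, `DoubleA`, `DoubleT`, `NoA`,
  `Other`); NCLDVs are marked by the short alternating A/T motif. Computes
  the 14 genome features: the 11 category frequencies *f₁…f₁₁*, gene density
  (genes/10 kb), coding density (bp/10 kb) and mean RBS spacer (bp), and
  groups genomes by hierarchical clustering of motif profiles.
* **NCLDV classifier & contig score** (`gvmags.classify`) — random forest
  (2,000 trees by default) on the 14 features, binary (`Virus_NCLDV` vs
  `Other`) or per genome group, with stratified k-fold cross-validation
  reporting per-group sensitivity and specificity. The targeted-binning
  score is 2 if (*f*<sub>TATATA</sub> > 0.3 ∨ *p*<sub>NCLDV</sub> > 0.3) ∧
  label = `Virus_NCLDV`, 1 if *f*<sub>TATATA</sub> > 0.3 ∨
  *p*<sub>NCLDV</sub> > 0.1 ∨ label = `Virus_NCLDV`, else 0; contigs with
  score ≥ 1 or ≥ 20 % of genes hitting NCLDV protein models enter binning.
* **Bin filtering & dereplication** (`gvmags.filtering`) — copy-number caps
  on five conserved NCVOG markers, a duplication ratio over 16 low-copy
  NCVOGs (Σcopies / #distinct, excluded above 3), contig-local taxonomy
  filters, and species-level dereplication (single-linkage clusters at
  ANI > 95 %, alignment fraction ≥ 50 %; within-cluster duplicates sharing a
  full-length 100 %-identity marker protein resolved
  provenance-then-size-then-id).
* **Quality tiers** (`gvmags.quality`) — completeness = markers present /
  superclade mean (high ≥ 0.9, medium ≥ 0.5); contamination = multicopy
  markers / superclade mean (low ≤ 1.2, medium ≤ 2); final tier combines
  both and is demoted unless assembly criteria hold (high: ≤ 30 contigs,
  ≥ 100 kb, a contig > 30 kb; medium: ≤ 50 contigs, ≥ 100 kb, > 15 kb).
* **Capsid-protein survey** (`gvmags.mcp`) — one-vs-rest logistic
  regression over per-lineage HMM score vectors; a protein is assigned only
  when its lineage probability exceeds 50 %, otherwise called *novel*;
  habitat counts are divided by the lineage's mean MCP copy number.
* **Virus–host linkage** (`gvmags.hgt`) — a viral protein is an HGT
  candidate when its best cellular hit (E ≤ 10⁻⁵⁰, identity ≥ 50 %,
  alignment fraction ≥ 50 %) has a strictly lower E-value than its best
  cross-lineage viral hit; candidate counts weight the undirected
  virus–host network.
* **Phylogenetic diversity** (`gvmags.phylo`) — 3-of-5 core-marker genome
  selection; PD = Σ branch lengths; expansion reported as
  PD(combined)/PD(reference).
* **Synthetic data** (`gvmags.synth`) — seeded generators for gene tables,
  marker tables, HGT scenarios and capsid score matrices with planted
  ground truth, so every stage is testable without any download.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
$ python examples/01_rbs_features_and_classifier.py
TATATA motif frequency : 0.625
NCLDV probability      : 1.000  (label: Virus_NCLDV)
RBS contig score       : 2
selected for binning   : True
```

A synthetic 20-kb contig drawn from the NCLDV profile carries the
alternating A/T motif upstream of 62.5 % of its genes; the binary classifier
is certain of its viral origin, the contig receives the top score of 2 and
is selected for targeted binning.

```bash
$ python examples/02_bin_filtering_and_quality.py
copy-number caps        : pass
duplication ratio       : 1.000  (excluded if > 3)
completeness            : 0.80 of superclade mean -> medium
contamination deviation : 1.00x superclade mean -> low
final quality tier      : medium
```

A bin retaining 16 of the 20 conserved markers of its superclade (80 %)
with one duplicated marker passes all hard filters and lands in the medium
quality tier. The remaining examples cover dereplication, the capsid
survey, host linkage and phylogenetic diversity the same way.

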