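# Methods

This note documents the models and rules the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the numerical conventions.

## RBS motif categories

Gene callers running a full upstream-motif scan emit, per gene, a short
motif string (or none). The eleven categories are evaluated strictly in
listing order — each later rule applies only to motifs "not already included
in a previous group":

1. **None** — no motif predicted.
2. **SD_Canonical** — contains a 5-bp window matching `AGGAG`, `GGAGG` or
   `GAGGA`, i.e. cores of the Shine–Dalgarno `AGGAGG` and its printed
   variants. A literal `x` in the motif matches any base (so `AGxAG` is
   canonical). Arbitrary base mismatches are deliberately *not* tolerated:
   a Hamming-1 rule would absorb `GAGGGA`, which is the defining exemplar
   of the Other_GA class. The pattern set is an argument and can be widened
   to emulate a gene caller's mismatch bins.
3. **SD_Bacteroidetes** — the full motif matches `TA{2,5}T?`.
4. **Other_GA** — contains `GA` anywhere (any GA-containing motif not
   already canonical; whether one or two GA occurrences should be required
   is not decidable from the class description, so the inclusive reading is
   used).
5. **TATATA_3.6** — the full motif is a 3–6 bp alternating A/T string,
   starting with either base (`TAT`, `ATAT`, `TATA`, `TATAT`, …).
6.–10. **OnlyA**, **OnlyT**, **DoubleA** (contains `AA`), **DoubleT**
   (contains `TT`), **NoA** (no `A`).
11. **Other** — fallback.

Wildcards use existential semantics: a motif containing `x` receives the
highest-precedence category reachable by any concretization of its
wildcards. This is equivalent to "x matches any single base during rule
matching" combined with ordered evaluation, and is implemented by
enumerating concretizations (motifs are ≤ ~8 bp, so the expansion is
trivial).

The categorizer is verified against an independent regex-based restatement
of the rules on the exhaustive enumeration of all 5,460 motifs of length
≤ 6 over `{A,C,G,T}`.

## Genome features and classifier

For a sequence of length *L* with *n* counted genes (confidence ≥ 90 and
caller score ≥ 50 when gates are applied):

* gene density = 10⁴·n/L, coding density = 10⁴·Σ(end−start)/L;
* mean spacer averages only genes with a predicted RBS (NaN sentinel when
  none — a spacer presupposes an RBS);
* the 11 motif-class frequencies sum to 1 for any non-empty gene set; an
  empty gene set yields an all-zero vector flagged `empty` rather than an
  error.

Genome grouping uses complete-linkage agglomerative clustering (the
classical `hclust` default) on Euclidean distances between motif-frequency
vectors, cut at the requested number of groups.

The classifier is a random forest, 2,000 trees by default with library
defaults otherwise, in a binary mode (`Virus_NCLDV` vs `Other`) and a
genome-group mode; the probability assigned to the NCLDV class is the
prediction score. Cross-validation is stratified k-fold with per-group
sensitivity and specificity, because training corpora are heavily skewed
towards bacteria; `folds = n` switches to leave-one-out. Tests and the
acceptance script run cross-validation with 200 trees — on the
well-separated synthetic groups used there, forest size is not the limiting
factor, and 200 trees keeps the benchmark inside a few seconds without
changing any outcome.

### Contig score parse

The printed form of the score-2 rule ("a score of 2 if A or B and the
prediction was NCLDV") is ambiguous between `(A ∨ B) ∧ C` and
`A ∨ (B ∧ C)`. The default parse is `(A ∨ B) ∧ C`: under the alternative, a
score of 2 could fire without an NCLDV prediction, which would make the
score-2 tier weaker than its stated intent of retaining specificity. Both
parses are selectable (`score2_requires_ncldv_label`). The 20 %-of-genes
binning threshold is compared with exact rational arithmetic on
(hits, genes) so boundary cases like 1/5 are never float artifacts.

## Marker registries

Five core NCVOGs (polymerase B, D5 helicase-primase, packaging ATPase,
SFII helicase, VLTF3-like factor) drive species-tree admission (≥ 3 of 5
present). Sixteen low-copy NCVOGs form the duplication set; six long-marker
NCVOGs flag dereplication duplicates. The twenty-marker quality set's
published membership is supplementary material not reproduced here; the
shipped default comprises the nineteen NCVOGs named across the pipeline
plus the DNA-directed RNA polymerase subunit (NCVOG0271), and every
consumer accepts an overriding registry. No result in this package depends
on the exact membership — baselines and bins are always scored against the
same set.

## Filtering and dereplication

Copy-number caps are strict "more than" comparisons (a genome at exactly
the cap passes). The duplication ratio is Σcopies/#distinct over the
16-marker set; genomes with no duplication-set markers get an undefined
ratio (`None`) and pass this filter — completeness screening catches them
downstream. Contig taxonomy rules are configuration (the published
threshold table is supplementary); the shipped defaults remove contigs with
> 80 % best hits to one cellular domain and < 10 % NCLDV hits, and rule
evaluation is contig-local by construction.

ANI clusters are connected components over edges requiring ANI strictly
above 95 % and alignment fraction ≥ 50 % in *either* direction (the
direction is unspecified upstream; max of the two is used). Single linkage
matches the conventional reading of a "95 % ANI cluster". Within a cluster,
genomes sharing any full-length 100 %-identity hit on a long-marker NCVOG
form duplicate groups; one member is kept per group, preferring targeted
over conventional binning provenance, then the largest assembly, then the
lexicographically smallest id — a total order, so the outcome is
deterministic and input-order invariant.

## Quality model

For each superclade, the baseline is the arithmetic mean number of
quality-set markers present, present once, and present multiple times over
member genomes; when the evaluated bin is part of the baseline population
it is excluded (leave-one-out) to avoid self-biasing small superclades.

* completeness fraction = markers present / mean present; ≥ 0.9 high,
  ≥ 0.5 medium, else low; the fraction is reported uncapped when a bin is
  richer than the mean.
* contamination deviation = multicopy markers / max(mean multicopy, 1);
  ≤ 1.2 low, ≤ 2 medium, else high. The comparison of "single- and
  multicopy" observations against the superclade mean is operationalized on
  the multicopy count because duplicated markers are the contamination
  signal; the divisor floor of 1 prevents superclades of essentially
  single-copy genomes from turning any duplication into an infinite
  deviation (such cases are still tierable and are flagged by the raw
  deviation value).

The final call combines the tiers (default matrix: high needs high
completeness and low contamination; medium needs ≥ medium completeness and
≤ medium contamination — the published combination table is supplementary,
so the matrix is an argument) and is demoted step-wise while its assembly
criteria fail. All boundary comparisons are closed exactly as stated
(≥ 0.9, ≥ 0.5, ≤ 1.2, ≤ 2; contig/size criteria use ≤, ≥ and strict > for
the longest contig).

## Capsid survey

The lineage classifier is a one-vs-rest panel of logistic regressions
(lbfgs solver), trained on protein × lineage-model score vectors with
missing scores imputed as 0 (no hit ≈ no affinity). A protein is assigned
to the arg-max lineage only when its probability strictly exceeds 0.5,
otherwise "novel". The reported probability is each lineage's **raw**
binary (calibrated one-vs-rest) probability rather than the
normalized-to-sum-1 variant: normalization rescales even uniformly poor
matches up to at least 1/k, which defeats the "novel" rule's purpose of
flagging out-of-distribution proteins; the normalized variant remains
selectable. Copy-number correction divides raw lineage × habitat counts by
the lineage's mean MCP copy number (computed over bins and reference
genomes, hence ≥ 1), so corrected counts never exceed raw ones.

## HGT and host networks

Cellular hits are gated at E ≤ 10⁻⁵⁰, identity ≥ 50 % and alignment
fraction ≥ 50 %, with the alignment fraction defined query-side (alignment
length / query length — conventional for protein searches, direction
otherwise unspecified). Viral-database hits to the query's own lineage are
removed before comparison. "Lower E-value" is read strictly: a tie is not a
candidate. Known-misclassified subject sets are handled as a blocklist
argument. Edge weights count candidate proteins per (lineage, host group);
the default network filter keeps weight ≥ 2, while the figure-style view
uses ≥ 4 — both thresholds appear upstream and both are exposed.

## Phylogenetic diversity

PD is the sum of all branch lengths (edges without a length, typically the
root edge, contribute 0; negative lengths raise). The diversity expansion
is reported as the ratio PD(combined)/PD(reference) *and* as the absolute
difference: the upstream description says "difference" but reports a
"fold", and only the ratio yields a fold. Newick parsing allows polytomies
and ignores internal labels.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* each stage consumes:

* **Gene tables** — genes placed left-to-right with exponential gaps and
  near-normal lengths calibrated so expected gene/coding densities match
  the group profile; motif categories drawn i.i.d. from the profile, one
  canonical literal string per category (the categorizer under test must
  accept all rule-conforming strings, so generation is decoupled from it).
  Coordinates are 0-based half-open in memory; GFF3 export is 1-based
  inclusive. The default group profiles are illustrative: the published
  per-group motif frequencies exist only as a figure, so the defaults
  encode each group's qualitative signature (NCLDV dominated by the
  alternating A/T motif at ~8.5 genes/10 kb; canonical prokaryotes by
  Shine–Dalgarno at high coding density; Bacteroidetes-like genomes by
  their TA-rich variant; eukaryote-like groups by absent motifs at low gene
  density, etc.) and are user-replaceable.
* **Marker tables** — presence subsampled to the completeness fraction;
  contamination adds one extra copy to a fraction (factor − 1) of retained
  markers, which makes the duplication ratio ≈ factor on a single-copy
  baseline and keeps multicopy counts integer and analytically predictable
  for planted-truth recovery.
* **HGT scenarios** — planted transfers pass every gate and beat their
  cross-lineage viral hit by construction (a better-scoring same-lineage
  hit is also planted to exercise the removal rule); background proteins
  each fail exactly one gate or lose the E-value comparison.
* **Score matrices** — lineage members score base + separation (± unit
  noise) on their own model and base elsewhere; novel proteins are flat at
  base. Separation 0 makes recovery chance-level by construction.

None of this emulates nucleotide sequences, read sampling, assembly
artifacts, chimeric bins with correlated contig composition, or the real
phylogenetic correlation structure among lineages. Passing tests therefore
demonstrate that the decision rules are implemented correctly and recover
planted structure under their stated assumptions — not that the pipeline's
published performance on real metagenomes is reproduced.

## Problem sizes and numerical conventions

Cross-validation benchmarks use 200 genomes per group at 100 kb (whole
sequences rather than 10–20 kb fragments: density features from a handful
of genes are too noisy to characterise the low-density eukaryote-like
groups, and the whole-genome condition is part of the feature design).
Quality recovery uses 500 bins with set-points placed ≥ 10 % from every
tier boundary; dereplication is checked against a union-find oracle on 200
random graphs of up to 50 genomes; PD against a string-scanning oracle on
100 random trees. All randomness flows through explicitly seeded
`numpy.random.Generator` instances — no global state — and identical seeds
give bitwise-identical serialized outputs.

Known limitations: the quality combination matrix, contig-taxonomy
thresholds and quality-set membership default to documented stand-ins for
unpublished supplementary tables (all overridable); the group classifier's
fragment-mode (10–20 kb) behaviour is implemented but its published
accuracy cannot be compared without the original training corpus; manual,
phylogeny-guided outlier curation is out of scope by design.
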