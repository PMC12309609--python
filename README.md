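# kirbind

Sequence-based prediction of KIR3DL1 binding to HLA class I allotypes.

The package implements the full modeling pipeline around a KIR3DL1 × HLA
bead-binding matrix:

- **`kirbind.sequences`** — aligned allotype sequences, the four region
  masks (`all`, `bw4`, `no_loops`, `helices`), one-hot (position, residue)
  encoding with invariant-position removal, Hamming distance, FASTA/TSV IO.
- **`kirbind.binding`** — replicate averaging with per-KIR max
  normalization, the log transform with zero replacement (1% of the
  minimal positive value), and the per-KIR 0–100 min-max view.
- **`kirbind.clustering`** — average-link (UPGMA) hierarchical clustering
  of both matrix axes, the three-cluster high/low/non-binder taxonomy, and
  group-difference statistics (rank-sum vs a reference group, one-way
  ANOVA, Tukey HSD).
- **`kirbind.logo`** — two-sample logo enrichment: per-(position, residue)
  binomial tests with Bonferroni family-wise control.
- **`kirbind.dimred`** — PCA (default) and MCA projections of the one-hot
  matrix to K dimensions (K = 7 by default).
- **`kirbind.classifiers`** — soft-margin SVM (box constraint 0.01,
  balanced class weights) and the joint binary/continuous linear objective
  (MLVO): one shared score trained against hinge loss on binary binding
  classes plus squared error on continuous log affinities. Weights are
  back-projected to per-feature betas, with per-position contribution
  summaries.
- **`kirbind.evaluation`** — allele-level 5-fold cross-validation (an
  allele is in the same fold for every KIR task), rank-based AUC, and
  two-way ANOVA comparisons across masks/loci.
- **`kirbind.prediction`** — the deployable 11-model bundle
  (overall binder, high-vs-low, and nine per-allotype models), percentile
  reporting against a reference panel, genotype averaging over expressed
  KIR3DL1 alleles, mutation deltas with exact reciprocity, and the
  degranulation Spearman analysis. Models serialize to a plain beta-matrix
  CSV plus a JSON sidecar.
- **`kirbind.coverage`** — per-locus population coverage of the tested
  panel, the joint KIR × HLA partition, and full-genotype coverage under
  independence.
- **`kirbind.simulate`** — seeded synthetic fixtures: polymorphic panels
  (optionally with founder-haplotype linkage or per-position residue
  weights), planted log-linear binding models with three binding classes,
  block matrices for clustering tests, Dirichlet frequency tables, and
  degranulation responses.

## CLI

All commands are under a single `kirbind` entry point:

```sh
kirbind simulate --n-hla 97 --n-kir 9 --seed 7 --out fixtures/
kirbind encode   --fasta fixtures/panel.fasta --mask helices --out encoded.tsv
kirbind cluster  --matrix fixtures/binding.tsv --axis hla --k 3 \
                 --out labels.tsv --newick tree.nwk
kirbind logo     --group-a binders.fasta --group-b nonbinders.fasta --out logo.tsv
kirbind train    --matrix fixtures/binding.tsv --fasta fixtures/panel.fasta \
                 --mask helices --method mlvo --out models/
kirbind cv       --matrix fixtures/binding.tsv --fasta fixtures/panel.fasta \
                 --mask helices --method mlvo --seed 17 --out auc.tsv
kirbind predict  --models models/ --seq fixtures/panel.fasta --out report.json
kirbind coverage --freqs freqs.tsv --tested "B*57:01,B*58:01" --out cov.tsv
```

`train` writes `betas.csv` (rows = (position, residue) features, columns =
the 11 models, final row = intercepts) and `bundle.json` (metadata plus
reference score distributions); `predict` consumes that directory and
reports per-model raw scores and percentiles, ignoring unknown (`*`)
residues.

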