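# chapnet

Regulatory classification of a chaperone gene network. The package
integrates three kinds of gene-level evidence over a 97-gene chaperone
universe — transcription-factor occupancy calls from ChIP-seq, muscle
expression enrichment, and literature-curated muscle requirement — and
provides the downstream analyses that go with it:

- **Evidence ranking and grouping** (`chapnet.evidence`): per-gene integer
  ranks (number of experiments per category identifying the gene, equal
  weight each), the muscle-associated union (enriched ∪ required), and a
  four-group partition (occupancy × muscle-association).
- **Exact set statistics** (`chapnet.setstats`): one-sided enrichment
  Fisher exact test (upper-tail hypergeometric, log-gamma based, exact to
  ≥12 significant digits), Mann-Whitney U with exact small-sample
  enumeration, and Venn region counts. All implemented from first
  principles and checked against brute-force enumeration oracles.
- **Expression clustering and MI classification** (`chapnet.clustering`):
  per-gene z-scoring of log2 profiles, hierarchical clustering
  (correlation/Euclidean, average/complete linkage), and a template
  classifier for the myogenesis-induced (MI) pattern: flat before 200 min
  of embryogenesis, ≥2-fold step-up from the ventral-enclosure stage
  (~290 min).
- **Promoter motif scanning** (`chapnet.motifs`): promoter extraction from
  genome FASTA + GFF3, degenerate-consensus scanning for the E-box
  (CANNTG) on both strands with TSS-relative coordinates (−1 = first base
  upstream), consensus→PWM construction, exact PWM p-values by dynamic
  programming over the null score distribution, and mutation-effect
  re-scanning (e.g. substituting ACGCGT over a site).
- **qPCR quantification** (`chapnet.qpcr`): 2^-ΔΔCt relative
  quantification with SEM over per-replicate folds and Mann-Whitney
  condition comparisons.
- **Synthetic data** (`chapnet.simulate`): seeded generators for evidence
  matrices (with a tunable occupancy↔muscle odds ratio), 10-stage time
  courses with a planted MI subset, background promoters with planted
  motif words, and replicate Ct tables with known fold changes — each with
  machine-readable ground truth.

A packaged mirror of the evidence workbook (97-gene catalog, 3 occupancy
sets, 3 enrichment sets, 3 curation criteria) ships under
`chapnet/data/`; ranking it reproduces the headline set sizes
(62 occupancy-positive, 46 enriched, 24 required, union 53) and overlap
p-values (0.008, 0.025, 0.99).

## CLI

The `chapnet` entry point exposes one subcommand per stage:

```sh
chapnet rank --out ranks.tsv                      # packaged evidence by default
chapnet overlap --set-a a.txt --set-b b.txt --universe u.txt
chapnet cluster --expression expr.tsv --out-dir out/
chapnet scan --promoters promoters.fasta --out hits.tsv
chapnet qpcr --ct-table ct.csv --reference-gene T07A9.15 --out folds.tsv
chapnet simulate catalog --seed 1 --out-dir sim/  # also: timecourse|promoters|qpcr
chapnet run --config config.yaml --out-dir out/   # full pipeline, one JSON report
```

`chapnet run` takes a YAML config naming input files and enabled stages
(`rank`, `overlap`, `cluster`, `scan`, `qpcr`); stages with missing inputs
are skipped with a recorded reason and the report echoes the config and
its hash.

Expression matrices are TSV with a `#minutes` comment line giving stage
times; evidence tables are wide-binary (gene_id + one 0/1 column per
experiment) or long (`set_name`, `gene_id`) and are auto-detected.

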