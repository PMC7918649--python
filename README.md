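# cryogill

Comparative gill-transcriptomics toolkit for detecting consistent
cross-species expression shifts — built around the kind of question
posed by Antarctic notothenioid fishes (Cryonotothenioidea), whose gill
transcriptomes show a shared signature of up-regulation relative to
temperate relatives.

The package is for computational biologists comparing bulk RNA-seq
expression across species panels where each species contributes one (or
few) libraries and genes are made comparable through single-copy
orthologs (e.g. BUSCO). It implements:

- **Ortholog expression tables** — per-species TPM matrices (or counts +
  effective lengths, converted via
  TPM<sub>g</sub> = 10⁶·(c<sub>g</sub>/ℓ<sub>g</sub>)/Σ<sub>j</sub>(c<sub>j</sub>/ℓ<sub>j</sub>))
  are averaged across libraries into an orthologs × species table;
  orthologs missing from a species' assembly are read as lack of
  expression (TPM = 0).
- **Consistency score (CS)** — for ortholog *g*, the count of
  cross-group species pairs (a, b) with
  (TPM<sub>ga</sub>+δ)/(TPM<sub>gb</sub>+δ) > 1.5, a over the Antarctic
  group, b over the other group; with 6 vs 8 species CS ∈ [0, 48], and
  candidates require CS ≥ 36 (75% of all comparisons). This is a
  robustness filter against outlier species and mis-assembled contigs.
- **Differential expression** — one-sided Welch *t*-test (Antarctic >
  other) on log₂(TPM+1) with species as replicates,
  Benjamini–Hochberg q-values; selection at CS ≥ 36 and q < 0.05.
- **Tissue specificity** — genes in the top decile of target-tissue
  expression with > 10-fold margin over every other tissue, plus
  one-sided hypergeometric term enrichment (GO and Pfam corrected as
  separate families).
- **Clustering transforms** — the gene heatmap recipe (≥ 1000 TPM
  filter, log₁₀(TPM+1), row Z-scores, average linkage on Pearson
  distance 1−r) and the species profile recipe (√TPM, per-gene
  max-standardization, median centring, average linkage on Euclidean
  distance over the CS ≥ 42 subset), with newick dendrogram export.
- **Expression share** — the percentage of a species' summed ortholog
  TPM contributed by a gene family (the statistic used to quantify the
  carbonic-anhydrase share of gill transcription).
- **Synthetic data** — a seeded generator planting known up-regulated
  orthologs, tissue-specific genes and enriched annotation terms, so
  every stage can be tested against ground truth without any sequencing
  data.

## Worked example

```bash
python examples/simulate_and_score.py
```

```
orthologs tested      : 2000
planted up-regulated  : 100 (true fold change 10)
selected candidates   : 98
sensitivity           : 0.960
false-discovery prop. : 0.020

top 5 candidates by q-value (CS out of 48, FC = group-mean ratio):
         cs       q_value  fold_change
og01900  48  3.279056e-07    12.126622
og00226  48  6.139087e-06    18.569784
og01427  48  6.139087e-06    10.332368
og00375  48  5.664275e-05    18.071888
og01045  48  1.199623e-04    6.797526
```

The generator planted 100 orthologs at a true 10-fold Antarctic
up-regulation among 2000; the CS ≥ 36 & q < 0.05 rule recovered 96 of
them with 2 false positives. The top candidates sit at the maximal
CS = 48 (higher in *every* cross-group comparison) with q-values far
below 0.05 — the same profile the real analysis reports for its
strongest cold-adaptation candidates.

Other capabilities, one script each: `examples/tissue_specificity.py`
(gill-specific selection + enrichment), `examples/clustering_profiles.py`
(both published transforms and the species dendrogram, which splits the
two groups into clean clades), `examples/expression_share.py`
(gene-family share of transcriptional effort).

## Command line

The same pipeline is scriptable from a shell:

```bash
cryogill simulate --seed 1 --outdir sim/
cryogill run-all --seed 1 --outdir run/     # all 7 stages + manifest
cryogill score --table run/ortholog_table.tsv --cs-min 36 --q-max 0.05
```

Exit codes: 0 success, 2 validation error, 1 runtime error.

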