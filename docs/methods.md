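# Methods

## The comparative model

The unit of comparison is the single-copy ortholog. Each species
contributes an averaged TPM value per ortholog; the comparative
statistics treat species — not libraries — as the biological replicates,
because each species is typically represented by a single individual or
pooled library and the scientific claim is about a species *group*
(Antarctic vs temperate), not about within-species variability.

Two complementary criteria define an up-regulated candidate:

1. **Consistency score.** CS counts the cross-group species pairs whose
   TPM ratio exceeds a fold-change threshold (default 1.5, strict `>`).
   It is deliberately non-parametric: a single aberrant species (outlier
   expression, chimeric or mis-assembled contig) can inflate a group
   mean but can perturb CS by at most its row/column of pairs. With
   n₁ = 6 and n₂ = 8 species, CS ranges 0–48 and the default selection
   threshold 36 demands attainment in at least 75% of comparisons.
2. **Welch test with FDR.** A one-sided Welch t-test (Antarctic > other)
   on log₂(TPM+1) per-species values, BH-adjusted across orthologs,
   selection at q < 0.05 (strict). The reference study derived its
   q-values from a bootstrap-based quantification model operating on raw
   reads; that requires read-level data this package does not consume,
   so the Welch test is this package's own two-group test, documented as
   such. The CS — the analysis' distinctive statistic — is reproduced
   exactly as defined.

Selection additionally requires an Antarctic-up group-mean fold change
(> 1), making the direction explicit rather than implied by the
one-sided test alone.

### Zero handling

Orthologs missing from a species' assembly are interpreted as absence of
expression and imputed as TPM 0 when the table is assembled. Bare ratios
with zeros are undefined, so every ratio criterion (CS, tissue fold
changes) adds a pseudocount δ (default 0.1 TPM) to numerator and
denominator. δ = 0 is supported: ratios are then evaluated
multiplicatively (a > thr·b), which defines 0/0 as not attained and
x/0 (x > 0) as attained. δ = 0.1 keeps "0 vs expressed" attained while
damping trace-level noise; it is configurable everywhere it is used.

Degenerate Welch inputs (zero variance in both groups) have no defined
t statistic; the test returns p = 1 unless the Antarctic mean is
strictly higher with zero variance, in which case it returns the
smallest positive float (p must stay in (0, 1]).

## Tissue specificity and enrichment

A gene is target-tissue-specific when (i) it falls within the top
`top_fraction` (default 10%) of the target tissue's expression ranking,
ties at the cutoff value included, and (ii) its pseudocounted fold
change against *every* other tissue exceeds `fc_min` (default 10,
strict). The ranking universe is all genes in the panel; the enrichment
universe likewise defaults to all panel genes (annotated or not) and is
configurable. Enrichment is the one-sided hypergeometric tail
P(X ≥ k) per term; GO terms and Pfam domains are corrected as two
separate BH families since they are distinct vocabularies. No GO-graph
ancestor propagation is performed.

## Clustering transforms

- Gene heatmap: genes with max TPM ≥ 1000 (inclusive — the procedural
  statement "a minimum TPM value of 1000" wins over the caption's
  "> 1000"; flag-overridable), log₁₀(TPM+1), per-row Z-scores, average
  linkage on Pearson distance 1 − r. Anti-correlated profiles are kept
  maximally distant (1 − r, not 1 − |r|) because opposite tissue
  profiles are biologically distinct. Zero-variance rows cannot be
  Z-scored or correlated and are dropped with a warning (the constant
  check uses a 10⁻¹² relative tolerance; a flat row's floating-point sd
  is ~10⁻¹⁶, not 0).
- Species profiles: on orthologs with CS ≥ 42, v = √TPM standardized on
  the per-gene maximum across species, then centred on the per-gene
  median across species (midpoint convention for even species counts) —
  all values lie in [−1, 1]; species clustered by average linkage on
  Euclidean column distances. The median subtraction is read per gene
  across species; the alternative reading (a single global median) is
  not supported.
- The average-linkage agglomeration is implemented directly (the
  standard UPGMA-style update d(i∪j, k) = (|i|d(i,k)+|j|d(j,k))/(|i|+|j|))
  so that ties between equal-distance candidate pairs break
  deterministically on the lexicographically smallest sorted label
  tuple; library implementations leave tie order unspecified. Trees
  serialize to newick with ultrametric branch lengths (half the merge
  height difference).

## Expression share

share_s = 100 · Σ_{g∈set} TPM_gs / Σ_g TPM_gs on the ortholog table,
summarized per group as mean ± sample standard deviation (ddof = 1)
across species — the "±" convention is taken as SD, not SEM.

## Synthetic data

The generator emulates the comparative study design, not any particular
dataset: 6 + 8 species, 2000 orthologs, lognormal baselines
(log₁₀ TPM ~ N(1.0, 0.8)), 5% planted orthologs at a 10-fold Antarctic
effect, per-(gene, species) log₁₀ noise N(0, 0.3), 1% missing
(species, ortholog) cells realized as absent matrix rows (so the
downstream TPM = 0 rule is exercised, not baked in), one library per
species. Planting overrides missingness in Antarctic species so truth
stays well-defined. When a species has ≥ 2 libraries, each library adds
independent replicate noise with sd = noise_sd/2; a lone library
observes the species-level value directly. TPM columns are not
renormalized to 10⁶ after planting, since the analysis operates on
ortholog subsets where the TPM-sum identity cannot hold anyway.

The tissue panel plants `n_specific = 25` of 500 genes at 50-fold
target-tissue excess over a shared baseline (log₁₀ ~ N(1.0, 0.3), noise
sd 0.1 per gene × tissue); under these conditions the probability that
any planted gene misses the top-decile or 10-fold criterion is
negligible (normal-tail z ≈ 3.8 and 4.9 per gene), which is what makes
the exact-recovery property a fair test. Annotations assign each term
independently at rate terms_per_gene/n_terms, with enriched terms
boosted by an odds factor inside the target set.

All substreams derive from one master seed via named child seeds
(CRC-32 of the component name), so adding a component never perturbs the
draws of another, and identical (params, seed) give byte-identical
serialized output.

### What the generator does not model

Read-level sampling noise and quantification uncertainty, length/GC
bias, between-gene correlation, phylogenetic autocorrelation of
expression between related species, and compositional closure of TPM.
Passing recovery tests therefore demonstrates that the statistics behave
as designed under the declared generative model — not that the
thresholds have any particular operating characteristics on real
cross-species data, where phylogenetic structure in particular can
inflate consistency among related species.

## Numerical choices and problem sizes

TPM normalization validates against all-zero counts and non-positive
lengths; its output sums to 10⁶ within 10⁻⁶ relative tolerance. The
low-expression filter removes genes strictly below 1 TPM at their
per-matrix maximum across samples (the least destructive reading of a
per-transcriptome filter). BH adjustment is the standard step-up,
computed once per family and restored to input order. File readers parse
floats in round-trip mode so write-then-read is exact to the last ulp.

The test suite and examples run the full analysis at the generator's
default scale (2000 orthologs × 14 species, 500-gene × 5-tissue panel),
which the package's own profiling puts at a few seconds per run; these
sizes are the package's declared study conditions, and larger inputs
simply scale linearly in genes × species.

## Known limitations

- The Welch test is a species-level approximation; with one library per
  species it cannot separate biological from technical variance.
- CS thresholds (36, 42) are design-specific: they presume the 6 × 8
  species layout and must be rescaled for other designs (the selection
  refuses thresholds exceeding n₁ × n₂).
- The hand-rolled agglomeration is O(n³); it is intended for species
  panels and filtered gene sets (≲ 10³ leaves), not whole-transcriptome
  clustering.
- Manual ortholog additions are supported as a user-supplied TSV
  (ortholog, species, gene); none ship with the package.
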