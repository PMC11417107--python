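# Methods

This note records the models, parameter choices and design decisions behind
each stage, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Noise model and genotype inference

A cell-site observation is `(ref, alt)` read counts with depth
`n = ref + alt`. Under a diploid genotype `g ∈ {RR, RA, AA}`, per-read error
rate `ε` and allele-dropout probability `ado`:

    L(RR) = Binom(alt | n, ε)
    L(AA) = Binom(ref | n, ε)
    L(RA) = (1 − ado)·Binom(alt | n, ½)
          + (ado/2)·Binom(alt | n, ε)        # alternate allele dropped
          + (ado/2)·Binom(ref | n, ε)        # reference allele dropped

Dropout splits its mass evenly between the two alleles ("random loss of one
allele" implies symmetry). The posterior is prior × likelihood, computed in
log space with zero-weight mixture terms dropped, so `ado = 0` and `ε = 0`
are handled exactly (no clipping); with `n = 0` the posterior equals the
prior. With `ado = 0` the model reduces term-by-term to the standard
diploid caller.

**Defaults.** Flat prior (1/3 each; an empirical cohort-frequency prior
exists but is off by default), `ε = 0.005`, `min_depth = 5`,
`min_posterior = 0.95`. A consequence of the ADO term worth knowing: at a
site whose reads are all reference, the RR posterior is capped near
`1/(1 + ado/2)` ≈ 0.951 at `ado = 0.103` — the model never fully excludes a
dropped alternate allele, so `min_posterior` above ~0.95 would turn every
wild-type call into CND.

**What "accuracy" means here.** A complete dropout leaves reads that are
information-theoretically indistinguishable from a homozygous site, so no
read-based caller can recover the pre-amplification genotype at such sites;
any caller errs there at a rate ≈ `ado` per heterozygous site. Genotype
accuracy is therefore measured against the *amplified template* (dropout
converts RA to a hemizygous template correctly read as RR or AA); the lost
information is quantified separately by the ADO estimator. At depth ≥ 20
and the default noise the MAP call matches the template on >99% of sites
(the test suite computes this).

## Rate estimation

Per cell: FP = non-reference calls / informative homozygous-reference
control sites; ADO = confident homozygous calls / heterozygous control
sites with a confident call. No-calls are excluded from denominators (the
natural reading of "confident call"; documented as a choice). Cohort
summaries follow the two conventions the estimates are usually quoted in:
mean for FP, median for ADO. Cells with zero informative sites carry NaN
and are excluded from summaries; all-uninformative input is an error, not a
zero. Control data are represented at the call level (coded call matrices)
— the estimators are defined on calls, and this keeps a 20-cell × 1e6-site
FP experiment in tens of megabytes.

## Heterogeneity and origin tracing

The pair statistic R is binary by definition: −1 iff at least one site is
determinably mutant in one cell and wild type in the other, +1 otherwise
(CND is compatible with anything; a pair with no informative site counts as
+1, and a flag can exclude such pairs). The tissue similarity index is the
mean R over all unordered pairs; `index = 1 − 2H` holds exactly.

Because binary R cannot rank candidate source regions, origin tracing uses
the graded concordance (equal-status fraction over informative sites,
minimum 5 by default) and assigns each metastatic cell to the region of its
most concordant primary cell; ties break by larger informative count, then
lexicographic region label, with a tie flag. Enrichment of the traced
source region against the primary sampling composition is a two-sided
Fisher 2×2 test (assigned-to-group vs rest against sampled-per-group vs
rest) — one concrete construction; the underlying table is configuration,
so no particular printed p-value is claimed.

With ~40 mutations per cell and 10% ADO, nearly every cell pair shows at
least one false MUT/WT conflict, so H saturates near 1 in all tissues and
differences in H alone are weak evidence. The seeding classifier therefore
counts *lineages*: metastatic cells are clustered on the CND-aware distance
1 − concordance (average linkage, cut at 0.15 — within-clone distances are
~0.03 under default noise, cross-branch distances ~0.3; singletons are not
counted as lineages). A metastasis is called polyclonal iff it contains ≥2
lineages and its H is within 0.1 of the traced source region's H (a
polyclonal metastasis mirrors the heterogeneity of the region that seeded
it); otherwise monoclonal. The pigeonhole-tree call from bulk CCF clusters
is computed alongside; the cell-level rule decides when single-cell
genotypes exist, the tree decides when only bulk clusters are available.

Normal-cell exclusion: a cell is presumed stromal/immune iff its mutation
burden is ≤2 **and** it carries no mutation in a driver gene (APC, TP53 by
default). Clustering uses distance 1 − concordance with average linkage
(CND-tolerant, matching the R logic); PCA runs on the MUT=1/WT=0 encoding
with CND imputed to the site mean.

## Mutational signatures

Substitutions are folded into the 96 pyrimidine-centric classes
(6 types × 16 flanking contexts, lexicographic order, labels like
`A[C>A]A`); purine-reference records are reverse-complemented, malformed
records rejected per row with a log entry.

NMF minimizes the Frobenius norm by multiplicative updates (max 1000
iterations, relative tolerance 1e-6); the objective is asserted
non-increasing every iteration. Signatures are column-normalized to
probability vectors with exposures rescaled. Per K the original catalog is
fitted from multiple random initializations (best kept) and stability is
assessed on bootstrap catalogs (per-sample multinomial resampling):
bootstrap signature vectors are matched to the best-fit signatures by
cosine similarity and stability is the mean cosine silhouette per matched
cluster (K = 1 is trivially stable).

**K selection.** "Maximize stability subject to improving error" is
degenerate taken literally (rank-1 is trivially stable and error always
decreases), so the rule is: K is *supported* when adding the K-th signature
reduces the Frobenius error by at least `min_gain = 0.10` (relative) and
keeps stability ≥ 0.8; the largest supported K wins. The 0.10 margin sits
between the ~5% error reduction that fitting one extra free component to
pure multinomial sampling noise buys and the several-fold larger gains a
genuine process produces; both thresholds are exposed.

The bundled reference catalogue (`synthetic_reference_signatures.tsv`) is a
synthetic 5-signature stand-in built from simple spectral archetypes, for
matching tests and demos; redistributing a published human signature
catalogue is a licensing decision left to the user, and `match_signatures`
accepts any 96×N matrix.

## Pigeonhole phylogenies

CCF = min(1, 2·VAF/purity), assuming diploid copy-neutral loci. Clusters
come from k-means over (primary, metastasis) CCF pairs with K chosen by
silhouette; additional samples (e.g. per-region VAFs) can join the
clustering space — two branches seeding a metastasis symmetrically have
identical pooled-primary and metastasis CCFs and are separable only through
regional samples. The trunk is the largest-CCF cluster clonal (≥0.8) in
both samples.

Trees are built by inserting clusters in decreasing CCF order, attaching
each to the *shallowest* (largest-CCF) parent for which every sample
satisfies the pigeonhole constraint (children's CCFs, including the new
child, sum to at most the parent's CCF + tolerance 0.1) — maximally
branched subject to the constraint, so nesting happens only when forced,
which is exactly the principle's content. A cluster with no valid parent is
attached to the trunk with a violation flag and a warning. The constraint
is re-verified on every output tree. Branch lengths are
`n_mutations / total` and sum to 1.

Seeding: metastasis-present means `ccf_met > 0.05`; monoclonal iff the
present clusters are totally ordered by ancestry (one root-to-leaf path),
polyclonal iff ≥2 present clusters are incomparable. The bundled
`cohort10.tsv` is a synthetic 10-patient cluster cohort constructed so that
4 cases are monoclonally and 6 polyclonally seeded by these definitions.

## Transcriptome scores

Projection: per primary cluster (≥3 cells), the centroid is the per-gene
median over the top 500 variance-ranked genes; each metastatic cell
computes cosine, Pearson and Spearman similarity to every centroid and is
assigned to the top centroid when ≥2 of the 3 measures agree on it and the
maximum similarity is ≥0.7 (all-zero cells are unassigned). The original
method's per-measure thresholds are collapsed into this one knob. MC score
of a cluster = fraction of assigned metastatic cells projecting onto it
(a flag includes unassigned cells in the denominator).

EMT module score: genes are binned into 24 equal-frequency bins of
cohort-average expression (rank-based, ties broken deterministically); per
set gene, 100 control genes are drawn with replacement from its bin; score
= mean(set) − mean(controls) per cell, seeded. A planted +δ shift of the
set genes is recovered slightly attenuated (a few percent) because set
genes can serve as their own bin-matched controls — inherent to
expression-matched scoring. CNV score = Σ over regions of
(value − baseline)², baseline 1.0 (the modified-expression neutral level).
The EMT~MC association is OLS of MC on mean EMT score across clusters.
Optional upstream QC drops cells with <200 detected genes or >20%
mitochondrial content.

## Cohort statistics

`fisher_exact_2x2` and `fisher_exact_rxc` implement the conditional exact
test with the minimum-likelihood two-sided rule (probabilities compared
with relative slack 1e-7, the convention of standard packages; r×c by
complete enumeration with a refusal above ~5e6 tables). `pearson_chi2_rxc`
is the asymptotic Pearson test without continuity correction. The bundled
TRPS1-by-stage table is reproduced with the convention each printed value
actually follows: Fisher exact for the 2×2 M-stage block, Pearson
chi-square for the T/N/AJCC blocks (all-zero rows dropped). Mid-p variants
are deliberately not default.

## The synthetic generator: what it emulates, and what it does not

`simulate_case` draws a uniform random recursive clone tree (mutation
counts multinomial across clones, every clone keeping ≥1 private mutation
for identifiability), homes non-trunk clones round-robin across primary
regions, and populates each region with cells from its home clones plus a
15% trunk fraction. Monoclonal seeding picks one deepest clone; polyclonal
picks two non-nested branch clones (preferring distinct home regions).
Coverage is negative binomial (mean 30, dispersion 3 — overdispersed MDA
coverage at the "≥30-fold" design depth); ADO, FP and read errors follow
the operational definitions above; bulk VAFs are binomial draws at 500×
from clone prevalences; control sites are generated at call level with a 2%
no-call fraction. Prevalences aggregate mixture weights up the tree, so the
pigeonhole constraint holds in the truth by construction. All randomness
flows from one seed through named substreams.

Not emulated: MDA chimeras and coverage waves along the genome, locus- or
GC-dependent dropout, copy-number variation in the exome data, doublets,
spatial structure beyond region labels, and read-level artifacts (no
FASTQ/BAM). Passing tests therefore demonstrate correctness of the
*inference machinery* under the stated noise model, not robustness to every
artifact of real MDA libraries.

`simulate_expression_case` plants cluster structure via non-overlapping
marker-gene up-regulation (markers never overlap the EMT set, so the
EMT-score null is clean), elevates EMT genes in two designated
high-contribution clusters, draws metastatic cells from those clusters with
80% weight, and gives them non-neutral CNV regions. Counts are Poisson; no
library-size variation, dropout zero-inflation or batch effects.

## Problem sizes

Default simulated cases are 4 regions × 10 cells plus two 10-cell
metastases over ~200 candidate sites — small enough that the test suite
runs 100 cases per seeding mode, and 25 planted-signature extractions
(50 samples × 500 mutations, K scanned 1–6 with 10 bootstrap resamples and
4 initializations), in a few minutes; the acceptance script uses 50 cases
per mode and 10 signature runs. All sizes are arguments, and the same code
paths run unchanged at larger sizes.

## Known limitations

- The binary R statistic saturates once cells carry tens of mutations at
  10% ADO; comparative statements based on H alone are then
  uninformative, which is why seeding calls rest on lineage counting and
  tree structure.
- CCF conversion ignores copy number and subclonal purity structure.
- The r×c exact test is enumeration-bound; large sparse tables need the
  chi-square route.
- The per-cluster-fraction reading of the MC score is implemented; an
  alternative per-cell similarity aggregated per cluster would color cells
  rather than clusters and is not provided.
- `filter_snvs` exposes both OR and AND combinations of the tissue-support
  and multi-cell clauses (default OR); which the field's pipelines intend
  varies, and neither is asserted as canonical.
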