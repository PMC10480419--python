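# Methods

## Problem and measurement model

The package scores how faithfully a preclinical model sample (cancer cell
line or PDX) reproduces the bulk expression profile of a tissue cohort.
The primitive measurement is Spearman's rank correlation ρ between two
expression profiles over a gene subset: ρ is the Pearson correlation of
average-rank-transformed values, is invariant under strictly increasing
transforms (so correlating on TPM and on log2(TPM+1) are the same
operation), and its two-sided p-value uses the t approximation
t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom. Constant vectors have
undefined ρ (returned as NaN, never silently zero).

For a model sample *m* and a tissue group *G* (all samples of one parent
tissue in one disease state), the engine computes ρ(*m*, *t*) against every
tissue sample *t* ∈ *G* and records the median — a per-model, per-group
summary robust to outlier tissue samples. Correlating against a median
tissue profile instead is available as `profile="median"` for comparison.
Internally each sample is rank-transformed once per gene subset and the
ρ matrix is a product of standardized rank matrices, so the cost is
O(S_model × S_tissue × |subset|) after an O(S × |subset| log|subset|)
transform.

**Matched-origin specificity** ranks, per model, all candidate groups
(every tumor and non-diseased tissue group) by median ρ, descending. The
statistic is the percentage of models whose top-ranked group is the tumor
group of their own annotated tissue of origin. Tie policy is strict: a
matched group tied at the top counts as best only if it also comes first
under group-ID-ascending ordering, and the tie is recorded — optimistic
tie-breaking would silently inflate specificity.

**Model-type comparisons** use the Wilcoxon rank-sum test on the per-model
median ρ values of cell lines vs PDXs within each (tissue group × disease
state), reported in Mann–Whitney U convention (U of the first sample; the
classical rank-sum W = U + n₁(n₁+1)/2 is also emitted since R reports that
convention). Exact p-values by enumeration are used for tie-free samples
with n₁+n₂ ≤ 20, otherwise the tie- and continuity-corrected normal
approximation. p-values are Bonferroni-corrected within the family of all
performed comparisons (one family per invocation by default); a winner is
declared only at adjusted p < 0.05, with undersized groups skipped with a
warning rather than failing on ragged metadata.

## Gene subsets

* **Most-variable genes**: per-gene sample variance across a reference
  cohort, computed on log2(TPM+1). Raw-TPM variance is dominated by a few
  extreme genes; the log scale matches standard most-variable-gene
  practice. The scale is exposed (`variance_scale="log"|"tpm"`). Ordering
  is variance descending with ties broken by gene ID ascending, making
  subsets deterministic across platforms and nested in k.
* **Purity-correlated genes**: within each tumor cohort (default grouping:
  tissue group) with ≥ 10 purity-annotated samples, gene-wise Spearman ρ
  against purity with BH (or Bonferroni) adjustment *within* the cohort. A
  gene is flagged when adjusted p < α (default 0.05) **and** |ρ| ≥ 0.3;
  the exported subset is the union of flagged genes across cohorts. A
  precomputed gene list can be supplied instead via the generic gene-list
  reader, matching the common usage pattern of published purity
  signatures.
* **Tissue-specific sets**: for tissue t and gene g,
  z = (mean_t − mean of the other tissues' per-tissue means) / s.d. of the
  other tissues' per-tissue means, on log2(TPM+1) over non-diseased tissue
  samples; genes with z ≥ 3 join `<t>_high`, z ≤ −3 join `<t>_low`.
  **Caveat**: the denominator is an s.d. across reference tissues, so with
  few tissues the null distribution of z is extremely heavy-tailed (with
  two reference tissues it is Cauchy-like and P(|z| > 3) ≈ 0.2). The
  caller is only well-posed with several reference tissues; externally
  curated sets should be ingested from GMT when available.

## Per-gene correlation classes

The per-gene comparison of two *unpaired* sample groups requires an
explicit pairing rule. The implemented rule is quantile pairing: sort the
gene's values within each group, evaluate both empirical distributions at
n = min(n₁, n₂) equally spaced probabilities (linear/type-7
interpolation), and compute Spearman ρ with its t-approximation p on the
paired quantiles. This is deterministic, invariant to sample order, and
equals 1 for identical distributions. Because both quantile vectors are
nondecreasing, ρ ≥ 0 for every gene and equals 1 exactly when both are
tie-free: the statistic measures distributional concordance (ties at low
expression reduce it), and the anticorrelated class labels in the schema
are reachable only by future pairing strategies that supply a shared
sample axis. Genes constant in either group are classed `undefined`.
Classes use the unadjusted p < 0.05 rule together with the sign of ρ.

Over-representation of gene classes against a GMT collection is the
one-sided hypergeometric upper tail P[X ≥ k] for an overlap of k between a
size-q query and a size-s set in a size-N universe, with BH (default) or
Bonferroni adjustment across sets and recall = k/s reported per set. The
universe defaults to the genes with defined ρ, per standard ORA practice.
A native analog of web-service multiple-testing schemes (e.g. g:SCS) is
deliberately not implemented.

## Synthetic cohort generator

The generator produces counts with the statistical structure the analysis
assumes, with full ground truth. All effects are on the log2 scale;
everything is deterministic given the master seed (per-stage substreams
have fixed labels, so adding stages never reshuffles earlier draws).

1. Baseline abundance μ_g ~ Uniform(3, 10) log2 units (≈ 8–1000 expected
   counts), i.e. the generator models the *expressed* transcriptome at
   desk scale, not the full annotation including silent genes.
   Purity-responsive genes draw their baseline from the top of this range
   (Uniform(8, 10)): bulk purity signatures are dominated by abundant
   immune/stromal/proliferation programs, and this abundance is what makes
   purity genes contribute strong concordant signal between models and
   tumors.
2. Tissue identity: each tissue adds a random shift N(0, σ_t²) per gene
   (σ_t = `tissue_signal_sd` = 1.0), except its tissue-specific markers,
   which get a deterministic ±Δ with Δ = 3σ_t (20 high + 20 low markers
   per tissue by default). Note the marker effect sits exactly at 3
   standard deviations of the background shift, so z-threshold-3 recovery
   is intentionally a borderline detection task.
3. Malignant program: each tissue's tumor state adds a second random shift
   N(0, σ_m²) per gene (σ_m = `tumor_signal_sd` = 1.0). Without such a
   shift a pure tumor-cell profile would be indistinguishable in
   expectation from the non-diseased profile and matched-tumor ranking
   would be ill-posed.
4. Tumor admixture: a bulk tumor with latent purity p ~ Beta(4, 1.5)
   (mean ≈ 0.73, the typical range of copy-number-based purity estimates)
   has linear-scale expectation p·2^(tumor-cell profile) +
   (1−p)·2^(stromal profile). The two compartment profiles share the
   tissue's tumor base profile and differ **only** at the
   purity-responsive genes: '+' genes are elevated by `purity_effect`
   (3 log2 units) in the malignant compartment, '−' genes in the stroma.
   Sharing the base profile is deliberate: if the stroma had an
   independent global profile, *every* gene carrying a tissue or tumor
   shift would covary with purity through the admixture and a
   purity-gene detector with type-I control would be impossible by
   construction.
5. Models: a cell line or PDX carries the pure tumor-cell profile of its
   origin tissue (purity 1, no stromal component) plus gene-wise drift
   N(0, drift²) — `drift_cell_line` = 1.0, `drift_pdx` = 0.3 by default,
   encoding the PDX-higher-fidelity regime. Setting both to 0 with
   `noise_sd` = 0 and near-Poisson counts (`zero_drift_config`) makes
   every model an exact copy of its origin profile up to counting noise.
6. Counts: NegativeBinomial(mean = 2^logmean × library factor,
   size = `dispersion` = 20) with library factor ~ LogNormal(0, 0.2);
   size ≥ 1e6 switches to the Poisson limit. Per-sample biological noise
   N(0, `noise_sd`² = 0.09) multiplies the expectation.

Default cohort: 3 tissues × (20 non-diseased + 30 tumor + 20 cell line +
20 PDX) samples × 2000 genes, of which 120 are tissue markers and 100
(50 '+', 50 '−') purity-responsive.

What the generator does *not* emulate: real variance spectra and gene
counts (tens of thousands of genes, most unexpressed), batch effects and
platform differences, per-tissue stromal composition, correlated gene
programs, or model-specific systematic artifacts (culture adaptation,
mouse stromal reads in PDXs). Passing recovery tests therefore shows the
pipeline is *correct under its assumed structure*, not that real cohorts
satisfy that structure.

## Numerical and testing conventions

* Matrices are genes × samples everywhere; all tables are TAB-delimited;
  Ensembl version suffixes are stripped before any gene matching.
* TPM columns must sum to 1e6 (rel. tol 1e-6) at construction; gene-
  restricted views keep the TPM scale without re-normalizing. All-zero
  samples convert to all-zero TPM columns with a warning.
* Ties are always broken deterministically (value descending, ID
  ascending) and strict-tie policies are logged.
* Rank statistics are validated against independent brute-force oracles
  (explicit average-rank construction; exhaustive rank-assignment
  enumeration for the rank-sum test; exhaustive query enumeration for the
  hypergeometric tail) to 1e-12.
* Statistical property tests run at reduced problem sizes chosen for
  desk-scale runs: drift monotonicity on 500-gene cohorts over 10 seeds,
  type-I control on 1000-gene null cohorts (equal drift, no
  purity-responsive genes) over 10 seeds, tissue-marker recovery at 8
  reference tissues (where the z denominator is stable; recall ≈ 0.6 and
  ≈ 30-fold precision enrichment at z = 3 reflect the deliberately
  borderline 3σ marker design, not an implementation deficiency).
* The pipeline writes outputs with fixed float formatting and sorted JSON
  keys; a rerun with identical config and seed is byte-identical, which
  the manifest checksums verify.

## Known limitations

* The quantile-pairing per-gene statistic cannot produce negative ρ (see
  above); interpreting "anticorrelation" requires a pairing with a shared
  axis, which bulk unpaired cohorts do not provide.
* The tissue-specific z caller is unstable below ~5 reference tissues.
* Purity detection requires ≥ 10 purity-annotated tumors per cohort and
  non-constant purity; cohorts below that are skipped with a warning.
* No batch correction is attempted; cross-cohort comparability is assumed
  to be handled upstream of ingestion.
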