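# Methods

`platsig` implements the downstream statistical analysis of a small
platinum-treated tumor exome cohort: substitution-in-context catalogs,
de novo mutational-signature extraction with stability-based selection of
the number of signatures, detection of the platinum (C>A at CpCpA/CpCpG)
signature, and a significantly-mutated-gene and response-group enrichment
analysis. This note records the models, their assumptions, the tunable
parameters, and the design choices that were genuinely open.

## The 96-channel catalog

Every somatic SNV is classified by its substitution type and the two
flanking reference bases. Substitutions reported with a purine reference
are reflected onto the opposite strand, so the six types are C>A, C>G,
C>T, T>A, T>C, T>G and the mapping is total over the 192 stranded
possibilities. Channel order is substitution-major, then 5' base A,C,G,T,
then 3' base A,C,G,T — the community convention, fixed so bundled
reference profiles align by index. Coordinates are 1-based on the
reference strand (MAF convention). Indels are excluded from the catalog
but counted in mutation rates; SNVs with an N in their context are
excluded and tallied in the parse report rather than silently dropped.
Mutation rates divide by 30 Mb of adequately covered coding exome, the
conventional figure for whole-exome data. Missing VAFs are never imputed;
records lacking one are dropped (and counted) by any VAF-dependent step.

## Signature model and KL-NMF

A cohort catalog `V` (samples x 96) is modelled as `V ~ E P` with
non-negative exposures `E` and `k` signature profiles `P` (rows summing
to 1). Fitting minimizes the generalized Kullback-Leibler divergence
`D(V || EP)` by Lee-Seung multiplicative updates — the natural objective
for count data (it is the Poisson deviance up to a constant). Updates run
until the relative objective change falls below `tol` (default 1e-9) or
`max_iter` (default 10,000) iterations; the objective is checked to be
non-increasing at every step, which the multiplicative updates guarantee
up to round-off. After convergence profiles are L1-normalized with the
exposures rescaled so the product is unchanged. All 96 channels are kept
by default (desk-scale catalogs are small; low-count channel filtering is
a non-default option of the caller's own making).

Initialization is uniform-random from the run seed. Exposure rows are
initialized from streams keyed by sample id rather than row position, so
permuting the rows of a catalog permutes the fitted exposures and leaves
the profiles bitwise unchanged — a property the tests exercise.

## Bootstrap stability and choosing the number of signatures

NMF solutions on a small cohort depend on the realized counts, so the
number of signatures is chosen by reproducibility rather than fit. Each of
`n_bootstrap` (default 100) replicates redraws every sample's 96-vector
from a multinomial with the sample's own total and channel proportions —
a parametric bootstrap that preserves mutation loads exactly. NMF is run
on each replicate and the `n_bootstrap * k` resulting profiles are pooled.

The pooled profiles are partitioned into `k` clusters under cosine
distance, with the constraint that each replicate contributes exactly one
profile to each cluster: an average-linkage hierarchical partition is
refined by per-replicate Hungarian matching to the cluster centroids until
stable. The constraint is essential to an honest stability measure. When
`k` exceeds the number of real processes, NMF pads the factorization with
near-duplicate components; free clustering groups those duplicates into
tight, spurious clusters and reports high silhouette for any `k`. The
one-per-replicate constraint forces duplicates into different clusters,
mixing them with unrelated profiles and collapsing the silhouette — which
is exactly the behaviour that makes the stability curve informative.

Stability at a given `k` is the mean silhouette width (cosine distance) of
the constrained partition; per-cluster means are reported as
per-signature stability. For `k = 1`, where the silhouette is undefined,
stability is the mean cosine similarity of the pooled profiles to their
centroid. Consensus profiles are the normalized cluster centroids, and
exposures are refit to the original (unresampled) catalog by multiplicative
updates with the consensus profiles held fixed; the reported
reconstruction error is the generalized KL divergence of that consensus
fit. The selected `k` is the largest one with stability at or above
`stability_min` (default 0.8 — the notion of a stable solution needs an
explicit, configurable cutoff); if no `k` qualifies, the argmax is
returned with a flag.

Design note: an earlier variant initialized the reassignment from a single
NMF run on the unresampled catalog. A single run regularly lands in a
split/merged local optimum on cohorts of this size, and seeding the
partition from it made the consensus inherit that optimum even when the
overwhelming majority of bootstrap runs contained every planted signature.
The deterministic hierarchical initialization plus matched refinement
removed that failure mode and needs no extra NMF run.

## Annotation and the platinum score

Extracted profiles are labeled by their best cosine match among a bundled
reference set, provided the similarity reaches `min_cos` (default 0.8);
otherwise they are "novel". The bundled references are synthetic idealized
profiles — a platinum profile concentrated on C[C>A]A and C[C>A]G, plus
APOBEC-, age-, UV- and smoking-like profiles built from each process's
qualitative context preferences — intended for annotation of synthetic
data and as a documented file format; they are not measurements from any
external catalog, and users substitute their own reference TSV for real
analyses. The platinum score of a profile is the summed weight on the two
CCR channels C[C>A]A and C[C>A]G (the footprint of adenine
misincorporation opposite the 5' guanine of Pt-GpG intrastrand adducts
during translesion synthesis); a uniform profile scores 2/96 ~ 0.021, the
bundled platinum reference ~0.72. No threshold is imposed for "being" the
platinum signature — the score is reported, the decision is the user's.

## Significantly mutated genes

Driver analysis first removes variants with VAF <= 0.2 (strictly "more
than 20%" survives), treating low-frequency variants as likely passengers
from ongoing mutagenesis or subclonal events. Per-sample background rates
are the filtered mutation counts over 30 Mb. For a gene of coding length
`L`, each sample's count in that gene is modelled Binomial(L, r_s); the
exact null distribution of the cohort total is the convolution of the
per-sample binomials (pmfs truncated at the observed total, which leaves
`P(total <= observed-1)` exact), and the p-value is the upper tail. This
is a single-category simplification of coverage-aware, category-stratified
convolution tests: neither per-gene covered bases nor substitution-category
backgrounds are recoverable from a MAF, so coding length is the exposure
and one background rate per sample is used. Genes mutated in at least two
patients of the scope are tested; Benjamini-Hochberg adjustment runs over
the tested genes only, and genes with q below `fdr_max` (default 0.2) are
reported. Subgroup discovery runs the same scan on the full cohort and on
each response group and reports genes significant in a group but not
cohort-wide.

Group enrichment builds patient-level 2x2 tables (a patient counts once no
matter how many qualifying mutations it carries) and applies the two-sided
Fisher exact test with the conventional rule — the sum of hypergeometric
point probabilities not exceeding the observed table's. The same test
compares per-gene mutated-patient fractions against an external cohort's
printed counts.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without any download. Defaults are the emulated
study's conditions:

- 18 samples, split 7 "sensitive" / 11 "resistant".
- Per-sample loads log-uniform over 4.8-80.9 mutations/Mb times a 30 Mb
  exome. Loads are assigned to samples in order of platinum dominance
  (platinum mutagenesis is what elevates loads in a platinum-treated
  cohort), with the non-platinum samples' loads rotated across the other
  processes so each spans high and low burdens.
- Five signature profiles (the bundled synthetic references). Exposures
  are Dirichlet draws with one dominant process per sample: platinum
  dominates 6 of 18 samples, the other four processes three each
  (concentration 4.0 for the dominant process, 0.45 otherwise; cohort-mean
  platinum exposure ~0.28). This mirrors the strongly patient-specific
  process mixtures real platinum cohorts show (Ti/Tv ratios spanning an
  order of magnitude) and keeps all five processes identifiable at these
  loads — a shared symmetric Dirichlet leaves one process unrecoverable in
  a sizeable fraction of realizations, which would misrepresent a cohort
  from which five signatures were in fact stably extracted.
- VAFs are origin-specific: platinum-origin Beta(1.2, 13) (92.3% below
  0.2, matching the ~92% sub-threshold fraction of platinum-attributed
  C>A mutations), other origins a 0.84/0.16 mixture of subclonal
  Beta(1.8, 10) and clonal Beta(6, 4) (~61% below 0.2). Because the
  high-load samples are the platinum-dominated ones, the mutation-weighted
  platinum share is ~0.48 and cohort-wide ~76% of SNVs fall below VAF
  0.2. Driver mutations draw clonal VAFs truncated above 0.2 so they
  always survive the driver filter.
- The gene model tiles the exome with 10 named genes at realistic coding
  lengths (TP53, CDKN2A, FBXW7, KRAS, REV3L, ...) plus 190 background
  regions of ~150 kb of aggregated coding territory. The coarse background
  is deliberate: with thousands of realistic short genes, the "mutated in
  >= 2 patients" screen preferentially selects extreme observations and
  false-discovery control over the tested genes becomes anticonservative;
  with coarse regions the screen is non-selective, and the smg null
  p-values are super-uniform (a property the tests check across seeds).
  A small toy gene-length TSV is also bundled for I/O tests.
- Planted drivers are specified per gene as (group, Bernoulli probability
  or an exact patient count, mutations per patient). Planted genes are
  withheld from the background gene pool, so planted contingency tables
  are exact by construction — with a 9.4 kb gene, a single background
  VAF>0.2 hit in the other group would otherwise contaminate roughly 40%
  of realizations.

Contexts are generated directly from the channel definition (reference
strand chosen uniformly); no reference genome is involved, and the FASTA
path of the reader is tested against a small synthetic FASTA instead.

What the generator does **not** emulate: sequencing and alignment error,
coverage variation (per-gene or per-sample), tumor purity and copy number
(VAFs are draws from fixed betas, not functions of clonal structure),
indels, inter-sample variation of the signature profiles themselves, and
any correlation between a gene's identity and its mutability beyond coding
length. Passing tests therefore demonstrate the statistical machinery is
correct under its own assumptions, not that those assumptions hold for any
particular real cohort.

## Numerical choices and degenerate inputs

- NMF: tol 1e-9 on relative objective change, max_iter 10,000, smallest
  positive normal as the division guard; monotonicity asserted each run.
- Zero-mutation samples: zero catalog rows pass through NMF (their
  exposures converge to 0) and are returned unchanged by the bootstrap
  with a warning.
- Fisher: point-probability comparisons inherit scipy's 1+1e-7 relative
  slack; tables with an empty margin raise, an all-zero mutated row gives
  p = 1 through the normal path.
- Convolution test: observed total 0 returns p = 1; rates outside [0, 1]
  raise; clipping guards tiny negative round-off in the tail sum.
- BH ties: equal p-values receive equal q-values (statsmodels
  implementation).
- Annotation ties break toward the first reference in bundled order.
- Problem sizes in the test suite are chosen to keep the full run on one
  CPU comfortable: 100 bootstraps for the headline stability scan, 30 for
  secondary recovery checks, 20/50 seeds for the power and null-calibration
  experiments, and Fisher enumeration up to table total 40.

## Known limitations

- The convolution test conditions on estimated per-sample rates (which
  include the tested gene's own mutations); with ~200 modelled units the
  induced conservatism/anticonservatism is negligible, but it is not a
  conditional test.
- Stability is a one-number summary; per-signature stability is reported
  but not used for selection.
- The platinum score is a two-channel sum, deliberately simple; it does
  not model the full CCR profile shape.
- Exposures are refit with profiles fixed, so exposure uncertainty from
  profile estimation is not propagated.
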