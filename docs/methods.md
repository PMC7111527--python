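# Methods

## Scope and data model

`apakit` analyzes differential 3′-UTR poly(A)-site usage between a tumor and
a normal RNA-seq cohort. Its inputs are per-sample per-base 3′-UTR coverage
(bedGraph), a one-interval-per-gene 3′-UTR annotation (BED6, name =
`gene|transcript`), a gene-level count matrix, a conserved miRNA site table
with cumulative weighted context++ scores (CWCS ≤ 0, more negative =
stronger predicted repression), and a clinical table. All genomic
coordinates are 0-based half-open; every coverage array handed to the
estimators is oriented 5′→3′ along the transcript (minus-strand intervals
are reversed on read, and site offsets are reflected:
`offset = utr_end − genomic_end`). Missing values are `NA` in every TSV.
All file I/O lives in `apakit.formats`; the other modules operate on
in-memory frames.

## PDUI estimation

The coverage model per gene is a two-level step with one breakpoint *P*
shared by all samples of both conditions. Sharing *P* is what makes PDUI
comparable across samples; the per-sample quantities are the abundances.
Given *P*, the least-squares abundances have closed form: α_long = mean
depth on [P, L), α_short = max(0, mean depth on [0, P) − α_long). The fit
scans *P* over `{margin, margin+grid_step, …, L−margin}` (defaults
grid_step = 10 bp, margin = 100 bp — the margin forbids degenerate end
fits) and minimizes the residual sum of squares summed over samples, using
prefix sums so the scan is linear per candidate; exact RSS ties break
toward the smallest *P*, and the winning RSS is recomputed directly from
residuals to shed the prefix-sum rounding. With `grid_step=1` the procedure
is an exhaustive per-base search, which is how it is validated.

Samples whose mean UTR depth falls below `min_mean_coverage` (default 20
reads/base) get a missing PDUI and do not inform *P*; the filter is per
sample per gene, mirroring the practice of excluding low-coverage
transcripts. PDUI = α_long/(α_long+α_short), clipped to [0, 1] and missing
when both abundances vanish. Genes with fewer than 10 non-missing samples
in either condition (configurable) are dropped when the matrix is
assembled. Coverage is not smoothed: noise is handled by the least-squares
objective. One proximal site per UTR is fitted; internal/intronic APA and
per-condition breakpoints are out of scope.

## Differential APA

ΔPDUI = MeanPDUI_T − MeanPDUI_N over non-missing samples; negative values
are tumor-associated shortening. Significance comes from a two-sided Fisher
exact test on the 2×2 table of rounded, summed short- and long-form
abundances per condition, BH-adjusted; the table construction (Σα per
condition) is this package's concretization — the test statistic is
pluggable in principle, and the class gate additionally requires
|ΔPDUI| above an effect threshold precisely because abundance-scale tests
saturate at cohort depth. Defaults: threshold 0.1, q < 0.05 (an `--fdr`
flag serves stricter volcano-style cuts at 0.01).

The threshold is justified by a permutation analysis: per gene, condition
labels are permuted (default n = 10,000) and the add-one p-value
P_perm = (1 + #{|ΔPDUI_perm| ≥ |ΔPDUI_obs|})/(n+1) is BH-adjusted within
the set of genes passing each candidate threshold (±0.05/0.10/0.15). The
report gives, per threshold, the fraction of passing genes with adjusted
p > 0.05; a sound threshold drives that fraction to zero. The permuted
statistic is compared against each gene's own observed value (not the fixed
threshold): of the two readings of the procedure this one is strictly more
conservative, and it is the one implemented.

Supporting operations: per-patient ΔPDUI (tumor PDUI minus the gene's
normal mean), Ward hierarchical clustering of genes × patients on Euclidean
distances (median imputation first; scipy linkage, deterministic leaf
order), the purity rule (flag a gene iff Pearson r > 0.3 and p < 0.05
against tumor purity — deliberately one-directional, as printed), subset
hit overlap, and a 100-bp histogram of base pairs lost/gained
(`utr_length − proximal_offset` per significant gene).

## Heterogeneity

Per gene, unbiased PDUI variances per condition; effect measure
var_diff = Var[Normal] − Var[Tumor]; F = var_tumor/var_normal on
(n_T−1, n_N−1) df with a two-sided p (doubled smaller tail, capped at 1 —
sidedness is a package choice). Classes combine the ±0.015 effect cutoff
with p < 0.05 on the raw p; a BH q is reported alongside but does not gate
the class, matching how such variance screens are usually drawn. Degenerate
cases: both variances zero → stable, p = 1; var_normal = 0 alone → the
one-sided limit p = 0, classed by the cutoff. The housekeeping control
reports the non-stable fraction of a designated gene set and warns above
5%.

## Expression association

The differential-expression step is intentionally minimal and transparent
(the package's contribution is not DE methodology, and an externally
computed result table with columns `gene_id, log2fc, de_p, de_q, de_class`
can be substituted): median-of-ratios size factors over genes positive in
all samples, log2 fold change of normalized condition means with
pseudocount 1, Welch's two-sided t on log2(normalized+1), BH. Note the
normalization implies a global fold is indistinguishable from library
depth; only relative folds are detectable. The quadrant association is a
Fisher exact test on {shortened, lengthened} × {up, down} restricted to
genes significant in both analyses. The housekeeping concordance control
correlates per-gene median log2 normalized expression between conditions
across the housekeeping set.

## miRNA binding-site loss

Sites are mapped to UTR-relative offsets and split at the fitted proximal
PAS: `shared` (present in both 3′-UTR forms) vs `distal_only` (lost when
the short form is used). Only conserved sites are scored. Per-gene lost
sites are the conserved distal-only sites of significantly shortened genes;
the headline fraction is the share of shortened genes losing ≥ 1 site.

Family scores weight each site by |CWCS| times the normalized abundance of
the 3′-UTR form containing it. Abundance per condition is constructed as
long = meanPDUI × mean normalized expression and short = (1 − meanPDUI) ×
the same (shared sites weighted by long+short, distal-only by long); this
construction is one reasonable reading of "form abundance" and is pluggable
— any frame with the four columns substitutes. CWCS values are stored as
provided (≤ 0); using |CWCS| makes the score a non-negative mass so that a
fold change f = S_tumor/S_normal < 1 and hence a low Z unambiguously mean
loss. The null permutes family labels across sites (positions, scores and
genes fixed, per-family site counts preserved; one shared permutation
stream per run, seeded); Z = (f − m)/s from the permutation mean and SD
(ddof = 1). Families with S_normal = 0 carry a sentinel and leave the
ranking; zero permutation spread flags Z undefined. f, and therefore Z, is
invariant to rescaling all abundances.

The per-patient matrix is the exact evaluation of
X_{m,i} = Σ_g (1 − PDUI_{i,g})·A_{g,m}, with A_{g,m} = 1 iff shortened gene
g carries ≥ 1 conserved distal-only site of family m (the matrix quantifies
APA-driven loss, so unchanged genes do not contribute). Missing PDUI
contributes 0; a completeness matrix reports the observed fraction per
cell.

## Survival

Clinical covariates (age numeric; sex, race, stage, grade, residual tumor
one-hot with the most frequent level as reference) enter Cox models fitted
by lifelines with a 1e-6 ridge — enough to keep the partial likelihood
well-behaved when indicators are collinear (e.g. cluster labels nested in a
covariate) while leaving estimates essentially unpenalized. Listwise
deletion of incomplete patients is logged; duplicate patients and
all-censored inputs raise.

Procedure (a): martingale residuals (event minus estimated cumulative
hazard; deviance residuals by flag) from the clinical-only model carry the
unexplained survival signal; significant-APA genes are screened by the
univariate linear association of residuals with tumor PDUI, ranked by p
(ties: |slope|, then gene id), top 20 kept; k-means (K = 3 by the elbow
heuristic, emitted as a WSS report for K = 1…6) over seeded restarts, with
labels from the minimum-WSS restart and stability = the fraction of
restarts whose labels give log-rank p < 0.05.

Procedure (b): Sure Independence Screening = univariate Cox per family on
X, constant families excluded; retention by p < 0.05 (a top-d override
exists — the screen rule is a package choice). Gaussian-mixture clustering
of patients on standardized selected features, k = 1…max_k by minimum BIC;
the t-SNE embedding (fixed seed, perplexity 30 capped at (n−1)/3) is
visualization-only and never feeds clustering. The nested-model test is the
likelihood-ratio chi-square 2(ℓ_full − ℓ_reduced) (clipped at 0) on
n_clusters − 1 df, clinical vs clinical + cluster indicators on the
identical patient set, with hazard ratios per non-reference cluster.
Proportional-hazards diagnostics are not gated.

## Synthetic cohorts

The generator defines the study conditions. Defaults: 200 genes on one
synthetic chromosome (alternating strands, 1-kb spacers, UTR lengths
uniform 500–2000 bp, true proximal PAS uniform in the central half of each
UTR); 50 tumor + 50 normal samples; 15% of genes shortened and 10%
lengthened with planted |ΔPDUI| = 0.3 (normal-side means drawn so the shift
stays inside (0, 1)); 10% housekeeping genes with identical distributions
across conditions; 10% heterogeneous genes whose tumor Beta concentration
drops 50 → 8 (a 6.25-fold variance inflation), drawn from the unchanged
pool so variance and mean effects stay orthogonal. Per-sample PDUI ~
Beta(mκ, (1−m)κ). Coverage is the two-level step at 50 reads/base expected
depth (per-gene factor uniform 0.7–1.5, per-sample library factor 0.8–1.2)
with Poisson noise per base (negative-binomial by flag, dispersion 0.1).
Expression is Poisson around a log-normal gene mean; genes with planted APA
carry the coupling exp(k·(1 − PDUI)) anchored at the normal mean (k = 1),
so shortening up-regulates. Thirty miRNA families place ~2 conserved sites
per UTR uniformly; two prognostic families get one strong conserved site in
the distal-only region of five shortened target genes each. Tumors split
into two latent outcome groups; the poorer group shortens the prognostic
target genes by a further 0.25 PDUI, which raises its X scores. Survival is
exponential under a Cox linear predictor (modest age/stage/grade/residual
effects plus 0.7 log-hazard per unit of summed prognostic X, centered),
with administrative censoring at 3 years against a 1500-day baseline median
(≈ 40–60% events at the defaults). Everything is deterministic given the
seed; coverage uses spawned per-gene RNG streams so it can be drawn lazily
without materializing the base-level matrix.

What the generator does **not** emulate: read-level artifacts (FASTQ,
alignment, GC bias), batch effects between cohorts, overlapping genes or
multiple PAS per UTR, correlated gene–gene expression structure, and
informative censoring. Passing tests therefore demonstrate that the
estimators recover their own model's truth at realistic noise levels — not
that the model captures every property of real tumor cohorts.

## Numerical and design choices

* Fisher tables use rounded abundance sums; all-zero tables get p = 1.
* The permutation p uses the add-one estimator; permutation indicator
  matrices are drawn column-wise from one seeded generator.
* Ward clustering uses scipy's linkage; with all-tied distances a maxclust
  cut may return fewer groups than requested, deterministically.
* The two-segment fit compares candidates by prefix-sum RSS (exact enough
  for ranking) and reports a directly recomputed RSS; the oracle-agreement
  tolerance is relative 1e-9.
* BH is `statsmodels.multipletests(method="fdr_bh")` throughout.
* Cox fits: lifelines `CoxPHFitter(penalizer=1e-6)`; deviance chi-square is
  clipped at zero before the chi² tail.
* t-SNE initialization falls back from PCA to random when only one feature
  survives screening.
* Problem sizes in the test-suite and acceptance script (replicate counts
  of 10–50, permutation counts of 300–10,000, the 100-gene end-to-end
  cohort) were chosen so the whole validation runs on a laptop-class single
  core in a few minutes while keeping binomial error on the rate criteria
  well inside the asserted margins.

## Known limitations

Exact parity with any published APA caller's output is a non-goal; the
contract is the model stated here. The Fisher construction on summed
abundances is anti-conservative for genes with very deep coverage relative
to biological spread — the effect-size threshold, not the q-value, is the
load-bearing filter, which is exactly why the permutation calibration is
part of the pipeline. The DE step is a deliberately simple Welch test;
substitute a dedicated DE table for production use. Survival modeling
assumes proportional hazards and non-informative censoring; diagnostics are
logged, not enforced.
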