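# apakit

Alternative polyadenylation (APA) shapes how long a transcript's 3′ UTR is:
when a gene switches from its distal to its proximal poly(A) site (PAS), the
discarded distal region takes its miRNA and RNA-binding-protein sites with
it. In tumors this 3′-UTR shortening can release oncogenes from
miRNA repression. `apakit` is a library for mapping that landscape in a
tumor-versus-normal bulk RNA-seq comparison — from raw per-base 3′-UTR
coverage all the way to survival modeling — together with a synthetic cohort
generator that plants known effects so every stage can be validated by
parameter recovery.

It is aimed at computational biologists who have per-sample coverage
(bedGraph), a 3′-UTR annotation (BED6), a count matrix, a TargetScan-style
conserved miRNA site table and a clinical table, and want a tested,
scriptable implementation of the full analysis chain.

## The model

**PDUI estimation.** Per gene, coverage along the 3′ UTR is modeled as a
two-level step with a common breakpoint *P* (the proximal PAS) across
samples:

    c(x) ≈ (α_long + α_short)·1[x < P] + α_long·1[x ≥ P]

with per-sample abundances in closed form (α_long = mean depth beyond *P*,
α_short = the non-negative excess before it). The Percentage Distal Usage
Index is PDUI = α_long / (α_long + α_short): 1 = all transcripts long, 0 =
all short. *P* minimizes the pooled residual sum of squares on a grid.

**Differential APA.** ΔPDUI = MeanPDUI_tumor − MeanPDUI_normal; significance
by Fisher's exact test on summed short/long abundances with
Benjamini–Hochberg correction; the |ΔPDUI| effect threshold is calibrated by
a condition-label permutation test. Per-patient ΔPDUI, Ward clustering,
tumor-purity correlation and subset-overlap controls included.

**Heterogeneity.** Var[Normal] − Var[Tumor] of PDUI per gene with a
two-sided F test and a ±0.015 effect cutoff; housekeeping genes serve as the
negative control.

**miRNA site loss.** Conserved sites in the lost (distal-only) region of
shortened genes; per-family CWCS-weighted scores S_tumor/S_normal, fold
change f and permutation Z = (f − m)/s (low Z = preferential loss); the
per-patient burden X_{m,i} = Σ_g (1 − PDUI_{i,g})·A_{g,m}.

**Survival.** (a) Cox martingale residuals from the clinical model → PDUI
feature screen → k-means cohorts → Kaplan–Meier/log-rank with restart
stability; (b) Sure Independence Screening of X → Gaussian-mixture clusters
(BIC) → analysis-of-deviance of nested Cox models with per-cluster hazard
ratios.

## Worked example

```bash
python examples/02_differential_apa.py
```

prints (seed 7):

```
apa_class
unchanged     150
shortened      30
lengthened     20
sensitivity 1.00, empirical FDR 0.00
 threshold  n_passing  frac_padj_gt_05
      0.05         50              0.0
      0.10         50              0.0
      0.15         50              0.0
hit overlap in high-purity subset: 1.00
```

All 50 planted events (30 shortened, 20 lengthened at |ΔPDUI| = 0.3) are
recovered with no false calls; at every candidate threshold, no passing gene
has a non-significant permutation p (the calibration that justifies ±0.1 as
the default cutoff); and every hit persists when the analysis is rerun on
the high-purity tumor half, the control that rules out stromal
contamination. The other scripts in `examples/` walk through PDUI
estimation, heterogeneity, expression association, miRNA site loss and the
two survival procedures; `examples/07_full_pipeline.py` (or
`apakit run-all --outdir out --seed 19`) chains everything from written
files.

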