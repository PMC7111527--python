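"""Association of APA classes with gene-expression changes.

Differential expression here is deliberately minimal and transparent
(median-of-ratios library normalization, log2 fold change with pseudocount
1, Welch's t on log2-transformed normalized counts, BH adjustment); an
externally computed result table with the same columns can be substituted
at every downstream step.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("apakit")

__all__ = ["size_factors", "normalize_counts", "differential_expression",
           "quadrant_association", "housekeeping_concordance"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed over genes with nonzero
    counts in every sample)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    logs = np.log(arr[positive])
    ref = logs.mean(axis=1, keepdims=True)          # log geometric mean
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


def differential_expression(counts: pd.DataFrame, labels: pd.Series,
                            q_cut: float = 0.05) -> pd.DataFrame:
    """Tumor-vs-normal differential expression on raw non-negative counts.

    log2fc = log2((mean normalized tumor + 1) / (mean normalized normal + 1));
    p from Welch's two-sided t on log2(normalized + 1); BH q; class up/down
    requires q < ``q_cut``.  All-zero genes are dropped.
    """
    lab = labels.loc[counts.columns]
    t_cols = counts.columns[(lab == "tumor").to_numpy()]
    n_cols = counts.columns[(lab == "normal").to_numpy()]
    if len(t_cols) < 3 or len(n_cols) < 3:
        raise ValueError("need >=3 samples per condition")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    nz = counts.sum(axis=1) > 0
    if (~nz).any():
        log.info("differential_expression: dropped %d all-zero genes",
                 int((~nz).sum()))
    counts = counts[nz]

    norm = normalize_counts(counts)
    logn = np.log2(norm + 1.0)
    log2fc = np.log2((norm[t_cols].mean(axis=1) + 1.0)
                     / (norm[n_cols].mean(axis=1) + 1.0))
    t_stat, p = stats.ttest_ind(logn[t_cols], logn[n_cols], axis=1,
                                equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    cls = np.where((q < q_cut) & (log2fc > 0), "up",
                   np.where((q < q_cut) & (log2fc < 0), "down", "ns"))
    return pd.DataFrame({
        "gene_id": counts.index,
        "log2fc": log2fc.to_numpy(),
        "de_p": p,
        "de_q": q,
        "de_class": cls,
    }).reset_index(drop=True)


def quadrant_association(apa_results: pd.DataFrame,
                         expr_results: pd.DataFrame) -> dict:
    """Fisher exact association of shortening with up-regulation.

    Restricted to genes significant in both analyses ({shortened,
    lengthened} x {up, down}); counts per quadrant reported alongside the
    two-sided p for the shortened <-> up association.
    """
    apa = apa_results.set_index("gene_id")["apa_class"]
    de = expr_results.set_index("gene_id")["de_class"]
    common = apa.index.intersection(de.index)
    apa, de = apa.loc[common], de.loc[common]
    mask = apa.isin(["shortened", "lengthened"]) & de.isin(["up", "down"])
    if not mask.any():
        raise ValueError("no co-classified genes")
    apa, de = apa[mask], de[mask]
    counts = {
        "shortened_up": int(((apa == "shortened") & (de == "up")).sum()),
        "shortened_down": int(((apa == "shortened") & (de == "down")).sum()),
        "lengthened_up": int(((apa == "lengthened") & (de == "up")).sum()),
        "lengthened_down": int(((apa == "lengthened") & (de == "down")).sum()),
    }
    table = [[counts["shortened_up"], counts["shortened_down"]],
             [counts["lengthened_up"], counts["lengthened_down"]]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {**counts, "fisher_p": float(p), "n": int(mask.sum())}


def housekeeping_concordance(counts: pd.DataFrame, hk_genes,
                             labels: pd.Series) -> dict:
    """Batch-effect control: Pearson correlation across housekeeping genes
    of per-gene median log2 normalized expression, tumor vs normal."""
    hk = counts.index.intersection(pd.Index(list(hk_genes)))
    if len(hk) < 3:
        raise ValueError(f"need >=3 housekeeping genes in the matrix, got {len(hk)}")
    lab = labels.loc[counts.columns]
    norm = np.log2(normalize_counts(counts).loc[hk] + 1.0)
    med_t = norm[counts.columns[(lab == "tumor").to_numpy()]].median(axis=1)
    med_n = norm[counts.columns[(lab == "normal").to_numpy()]].median(axis=1)
    r, p = stats.pearsonr(med_t, med_n)
    return {"pearson_r": float(r), "p": float(p), "n_genes": int(len(hk))}
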