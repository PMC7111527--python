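"""Differential APA between tumor and normal cohorts.

Per gene, dPDUI = MeanPDUI_T - MeanPDUI_N over non-missing samples; a
negative value marks tumor-associated 3'-UTR shortening.  Significance is a
two-sided Fisher exact test on the 2x2 table of summed, rounded short- and
long-form abundances (sum of alpha_short / alpha_long over each condition's
samples), BH-adjusted across genes.  A gene is called shortened when
dPDUI < -threshold with FDR below q_cut, lengthened symmetrically; the
default effect threshold 0.1 is the one a permutation analysis calibrates
(see :func:`permutation_threshold_eval`).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .formats import ApaDataset

log = logging.getLogger("apakit")

__all__ = ["differential_apa", "permutation_threshold_eval", "per_patient_delta",
           "cluster_patients_ward", "purity_association", "hit_overlap",
           "utr_change_histogram"]


def _condition_means(pdui: pd.DataFrame, labels: pd.Series):
    t_cols = pdui.columns[(labels.loc[pdui.columns] == "tumor").to_numpy()]
    n_cols = pdui.columns[(labels.loc[pdui.columns] == "normal").to_numpy()]
    if len(t_cols) == 0 or len(n_cols) == 0:
        raise ValueError("need at least one sample per condition")
    return pdui[t_cols].mean(axis=1), pdui[n_cols].mean(axis=1), t_cols, n_cols


def differential_apa(dataset: ApaDataset, threshold: float = 0.1,
                     q_cut: float = 0.05) -> pd.DataFrame:
    """Per-gene dPDUI, Fisher exact p, BH q and APA class.

    ``threshold`` is the |dPDUI| effect cutoff (must be > 0); ``q_cut`` the
    BH FDR gate (0.05 by default; a stricter 0.01 reproduces volcano-style
    selections).  Genes with PDUI missing in every sample of a condition are
    excluded.  Also reports ``utr_change_bp`` (distal boundary minus fitted
    proximal PAS) and the lost UTR-relative interval.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if dataset.alpha_long is None or dataset.alpha_short is None:
        raise ValueError("dataset lacks segment abundances (alpha matrices); "
                         "they are required for the Fisher test")
    mean_t, mean_n, t_cols, n_cols = _condition_means(dataset.pdui, dataset.labels)
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need >=2 samples per condition")
    keep = mean_t.notna() & mean_n.notna()

    long_t = np.rint(np.nansum(dataset.alpha_long[t_cols].to_numpy(), axis=1))
    short_t = np.rint(np.nansum(dataset.alpha_short[t_cols].to_numpy(), axis=1))
    long_n = np.rint(np.nansum(dataset.alpha_long[n_cols].to_numpy(), axis=1))
    short_n = np.rint(np.nansum(dataset.alpha_short[n_cols].to_numpy(), axis=1))

    genes = dataset.pdui.index
    pvals = np.ones(len(genes))
    for i in range(len(genes)):
        if not keep.iloc[i]:
            continue
        table = np.array([[long_t[i], short_t[i]], [long_n[i], short_n[i]]], dtype=int)
        if table.sum() == 0:
            continue
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    res = pd.DataFrame({
        "gene_id": genes,
        "mean_pdui_tumor": mean_t.to_numpy(),
        "mean_pdui_normal": mean_n.to_numpy(),
        "delta_pdui": (mean_t - mean_n).to_numpy(),
        "fisher_p": pvals,
    })[keep.to_numpy()].reset_index(drop=True)
    res["fdr_q"] = multipletests(res["fisher_p"], method="fdr_bh")[1]

    cls = np.where(
        (res["delta_pdui"] < -threshold) & (res["fdr_q"] < q_cut), "shortened",
        np.where((res["delta_pdui"] > threshold) & (res["fdr_q"] < q_cut),
                 "lengthened", "unchanged"))
    res["apa_class"] = cls
    if dataset.proximal_offset is not None and dataset.utr_length is not None:
        P = dataset.proximal_offset.reindex(res["gene_id"]).to_numpy(dtype=float)
        L = dataset.utr_length.reindex(res["gene_id"]).to_numpy(dtype=float)
        res["proximal_offset"] = P
        res["utr_length"] = L
        res["utr_change_bp"] = L - P
        res["lost_region_start"] = P
        res["lost_region_end"] = L
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("differential_apa: %d genes excluded (all-missing in one "
                 "condition)", n_excluded)
    return res


def permutation_threshold_eval(pdui: pd.DataFrame, labels: pd.Series,
                               thresholds=(0.05, 0.10, 0.15),
                               n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Calibrate |dPDUI| effect thresholds by condition-label permutation.

    For each gene the condition labels are permuted ``n_perm`` times and the
    permuted |dPDUI| compared with the gene's observed value; the add-one
    permutation p-value is P_perm = (1 + #{perm >= obs}) / (n_perm + 1).
    Within the set of genes whose observed |dPDUI| exceeds each candidate
    threshold, P_perm is BH-adjusted and the fraction of passing genes with
    adjusted p > 0.05 is reported.  A threshold whose passing set carries no
    such genes (fraction 0) separates real effects from permutation noise.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lab = labels.loc[pdui.columns]
    if lab.nunique() < 2:
        raise ValueError("both conditions required")
    V = pdui.to_numpy(dtype=float)
    M = np.isfinite(V)
    V0 = np.where(M, V, 0.0)
    is_t = (lab == "tumor").to_numpy()
    n_t = int(is_t.sum())

    def deltas(ind_t: np.ndarray) -> np.ndarray:
        # ind_t: samples x draws indicator; nan-aware group means
        st, ct = V0 @ ind_t, M @ ind_t
        sn, cn = V0 @ (1 - ind_t), M @ (1 - ind_t)
        with np.errstate(invalid="ignore", divide="ignore"):
            return st / ct - sn / cn

    obs = deltas(is_t.astype(float)[:, None])[:, 0]
    rng = np.random.default_rng(seed)
    n_samples = V.shape[1]
    # permuted tumor indicators, one column per permutation
    ind = np.zeros((n_samples, n_perm))
    for j in range(n_perm):
        ind[rng.permutation(n_samples)[:n_t], j] = 1.0
    perm = deltas(ind)
    exceed = (np.abs(perm) >= np.abs(obs)[:, None]).sum(axis=1)
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for t in thresholds:
        passing = np.abs(obs) > t
        idx = np.flatnonzero(passing & np.isfinite(obs))
        if idx.size:
            p_adj = multipletests(p_perm[idx], method="fdr_bh")[1]
            frac = float((p_adj > 0.05).mean())
        else:
            frac = 0.0
        rows.append(dict(threshold=t, n_passing=int(idx.size),
                         frac_padj_gt_05=frac))
    report = pd.DataFrame(rows)
    report.attrs["p_perm"] = pd.Series(p_perm, index=pdui.index)
    report.attrs["observed_delta"] = pd.Series(obs, index=pdui.index)
    return report


def per_patient_delta(pdui: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-patient dPDUI: tumor sample PDUI minus the gene's normal mean.

    Genes with no non-missing normal sample are dropped (logged).  Entries
    stay missing where the patient's PDUI is missing.
    """
    lab = labels.loc[pdui.columns]
    t_cols = pdui.columns[(lab == "tumor").to_numpy()]
    n_cols = pdui.columns[(lab == "normal").to_numpy()]
    normal_mean = pdui[n_cols].mean(axis=1)
    keep = normal_mean.notna()
    if (~keep).any():
        log.info("per_patient_delta: dropped %d genes without normal data",
                 int((~keep).sum()))
    return pdui.loc[keep, t_cols].sub(normal_mean[keep], axis=0)


def cluster_patients_ward(patient_delta: pd.DataFrame, n_row_groups: int = 2,
                          n_col_groups: int = 5) -> dict:
    """Ward hierarchical clustering of genes (rows) and patients (columns).

    Missing entries are median-imputed per gene first (logged).  Returns
    deterministic leaf orders (scipy's tie-handling is input-order stable)
    and flat group labels at the requested cuts.  When all pairwise
    distances tie (e.g. a constant matrix) the cut yields a single group.
    """
    X = patient_delta.copy()
    n_missing = int(X.isna().to_numpy().sum())
    if n_missing:
        med = X.median(axis=1)
        X = X.apply(lambda row: row.fillna(med[row.name]), axis=1)
        log.info("cluster_patients_ward: median-imputed %d missing entries",
                 n_missing)

    def _cluster(mat: np.ndarray, k: int):
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0]), np.ones(mat.shape[0], dtype=int)
        Z = hierarchy.linkage(mat, method="ward")
        order = hierarchy.leaves_list(Z)
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        return order, lab

    row_order, row_labels = _cluster(X.to_numpy(), n_row_groups)
    col_order, col_labels = _cluster(X.to_numpy().T, n_col_groups)
    return {
        "row_order": X.index[row_order],
        "col_order": X.columns[col_order],
        "row_labels": pd.Series(row_labels, index=X.index),
        "col_labels": pd.Series(col_labels, index=X.columns),
    }


def purity_association(pdui_row: pd.Series, purity: pd.Series) -> dict:
    """Pearson correlation of one gene's tumor PDUI with tumor purity.

    Flagged exactly by the one-directional printed rule: r > 0.3 and
    p < 0.05.  Requires >= 3 paired non-missing values; zero-variance purity
    yields an undefined r, flagged False, with a warning.
    """
    paired = pd.concat([pdui_row.rename("pdui"), purity.rename("purity")],
                       axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError(f"need >=3 paired values, got {len(paired)}")
    if paired["purity"].nunique() == 1 or paired["pdui"].nunique() == 1:
        warnings.warn("zero-variance input: correlation undefined", stacklevel=2)
        return {"pearson_r": float("nan"), "p": float("nan"), "flagged": False,
                "n": len(paired)}
    r, p = stats.pearsonr(paired["pdui"], paired["purity"])
    return {"pearson_r": float(r), "p": float(p),
            "flagged": bool(r > 0.3 and p < 0.05), "n": len(paired)}


def hit_overlap(full_results: pd.DataFrame, subset_results: pd.DataFrame) -> float:
    """Fraction of full-analysis hits (class != unchanged) recovered as hits
    in a subset analysis."""
    full_hits = set(full_results.loc[full_results["apa_class"] != "unchanged",
                                     "gene_id"])
    sub_hits = set(subset_results.loc[subset_results["apa_class"] != "unchanged",
                                      "gene_id"])
    if not full_hits:
        return float("nan")
    return len(full_hits & sub_hits) / len(full_hits)


def utr_change_histogram(results: pd.DataFrame, bin_bp: int = 100) -> pd.DataFrame:
    """Histogram of base pairs lost (shortened) / gained (lengthened) per
    significant gene, in ``bin_bp`` bins of ``utr_change_bp``."""
    sig = results[results["apa_class"] != "unchanged"]
    if sig.empty:
        return pd.DataFrame(columns=["bin_start", "bin_end", "shortened",
                                     "lengthened"]).astype(int)
    bins = (sig["utr_change_bp"] // bin_bp).astype(int)
    top = int(bins.max()) + 1
    out = pd.DataFrame({
        "bin_start": np.arange(top) * bin_bp,
        "bin_end": (np.arange(top) + 1) * bin_bp,
        "shortened": np.bincount(bins[sig["apa_class"] == "shortened"],
                                 minlength=top),
        "lengthened": np.bincount(bins[sig["apa_class"] == "lengthened"],
                                  minlength=top),
    })
    return out[(out["shortened"] > 0) | (out["lengthened"] > 0)].reset_index(drop=True)
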