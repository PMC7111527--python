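"""Per-gene heterogeneity of proximal PAS usage across samples.

For every gene the sample variance of PDUI is computed separately in tumor
and normal cohorts; var_diff = Var[Normal] - Var[Tumor] is the effect
measure (negative = more variable in tumors) and a two-sided F test of the
variance ratio supplies significance.  Classes combine the +/-0.015 effect
cutoff with the significance gate.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import ApaDataset

log = logging.getLogger("apakit")

__all__ = ["heterogeneity_table", "housekeeping_control"]


def heterogeneity_table(dataset: ApaDataset, cutoff: float = 0.015,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Variance comparison of PDUI between conditions per gene.

    Unbiased sample variances; F = var_tumor / var_normal on
    (n_T - 1, n_N - 1) degrees of freedom; two-sided p doubles the smaller
    tail (capped at 1).  ``het_class`` is tumor_variable when
    var_diff < -cutoff with p < alpha, normal_variable when
    var_diff > +cutoff with p < alpha, else stable.  Genes with fewer than
    3 non-missing samples in either condition are dropped (logged).
    Classes use the raw F p; a BH q column is reported alongside.
    """
    t_cols = dataset.tumor_samples
    n_cols = dataset.normal_samples
    vt = dataset.pdui[t_cols].var(axis=1, ddof=1)
    vn = dataset.pdui[n_cols].var(axis=1, ddof=1)
    ct = dataset.pdui[t_cols].notna().sum(axis=1)
    cn = dataset.pdui[n_cols].notna().sum(axis=1)
    keep = (ct >= 3) & (cn >= 3)
    if (~keep).any():
        log.info("heterogeneity_table: dropped %d genes with <3 samples in a "
                 "condition", int((~keep).sum()))

    vt, vn, ct, cn = vt[keep], vn[keep], ct[keep], cn[keep]
    p = np.ones(len(vt))
    f = np.full(len(vt), np.nan)
    for i, (a, b, na, nb) in enumerate(zip(vt, vn, ct, cn)):
        if a == 0 and b == 0:
            p[i] = 1.0
            continue
        if b == 0:
            # one-sided limit of the ratio test as var_normal -> 0
            f[i] = np.inf
            p[i] = 0.0
            continue
        f[i] = a / b
        dist = stats.f(na - 1, nb - 1)
        p[i] = min(1.0, 2.0 * min(dist.cdf(f[i]), dist.sf(f[i])))

    var_diff = (vn - vt).to_numpy()
    cls = np.where((var_diff < -cutoff) & (p < alpha), "tumor_variable",
                   np.where((var_diff > cutoff) & (p < alpha),
                            "normal_variable", "stable"))
    out = pd.DataFrame({
        "gene_id": vt.index,
        "var_tumor": vt.to_numpy(),
        "var_normal": vn.to_numpy(),
        "var_diff": var_diff,
        "f_stat": f,
        "f_p": p,
        "het_class": cls,
    }).reset_index(drop=True)
    out["f_q"] = multipletests(out["f_p"], method="fdr_bh")[1]
    return out


def housekeeping_control(het_table: pd.DataFrame, hk_genes) -> dict:
    """Negative control: housekeeping genes should be variance-stable.

    Returns the count and fraction of housekeeping genes classified
    non-stable; warns when the fraction exceeds 5% (a hint of systematic
    batch differences between the cohorts).
    """
    hk = set(hk_genes)
    if not hk:
        raise ValueError("housekeeping gene set is empty")
    sub = het_table[het_table["gene_id"].isin(hk)]
    if sub.empty:
        raise ValueError("no housekeeping genes present in the heterogeneity table")
    n_nonstable = int((sub["het_class"] != "stable").sum())
    frac = n_nonstable / len(sub)
    if frac > 0.05:
        warnings.warn(
            f"housekeeping control: {frac:.1%} of {len(sub)} housekeeping genes "
            "show heterogeneity shifts; cohorts may not be comparable",
            stacklevel=2)
    return {"n_housekeeping": len(sub), "n_nonstable": n_nonstable,
            "fraction_nonstable": frac}
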