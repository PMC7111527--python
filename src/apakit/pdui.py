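"""De novo proximal poly(A)-site estimation and per-sample PDUI.

The model: per gene, coverage along the 3' UTR is approximated by a
two-level step shared across samples,

    c(x) ~ (alpha_long + alpha_short) * 1[x < P]  +  alpha_long * 1[x >= P]

with one common breakpoint P (the proximal PAS) fitted jointly over all
samples that pass the coverage filter, and per-sample abundances solved in
closed form: alpha_long is the mean depth on [P, L) and alpha_short is the
non-negative excess of the mean depth on [0, P).  The Percentage Distal
Usage Index is PDUI = alpha_long / (alpha_long + alpha_short): 1 means all
transcripts use the distal PAS (long 3' UTR), 0 means all use the proximal
one.  P is chosen on a grid minimizing the summed residual sum of squares;
exact RSS ties break toward the smallest P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import ApaDataset

log = logging.getLogger("apakit")

__all__ = ["GeneAPAFit", "estimate_pdui_gene", "build_pdui_matrix",
           "estimate_cohort"]


@dataclass
class GeneAPAFit:
    """Fitted proximal PAS and per-sample abundances for one gene."""

    gene_id: str
    utr_length: int
    proximal_offset: int | None        # bp, transcript frame; None if no fit
    alpha_long: pd.Series              # per-sample long-form depth (>= 0)
    alpha_short: pd.Series             # per-sample short-only depth (>= 0)
    pdui: pd.Series                    # per-sample, NaN where filtered
    fit_rss: float
    n_samples_used: int

    @property
    def fitted(self) -> bool:
        return self.proximal_offset is not None


def estimate_pdui_gene(coverage: dict, gene_id: str = "gene",
                       grid_step: int = 10, margin: int = 100,
                       min_mean_coverage: float = 20.0) -> GeneAPAFit | None:
    """Fit the two-segment model for one gene.

    Parameters
    ----------
    coverage
        Mapping sample_id -> per-base depth array oriented 5'->3'.  All
        arrays must share one length L (the UTR length).
    grid_step, margin
        Candidate breakpoints are ``{margin, margin+grid_step, ..., L-margin}``;
        the margins avoid degenerate end fits.  ``grid_step=1`` makes the fit
        an exhaustive per-base search.
    min_mean_coverage
        Per-sample filter: samples whose mean UTR depth falls below this get
        a missing PDUI and do not inform the breakpoint.

    Returns ``None`` when the UTR is shorter than ``2 * margin`` (gene
    skipped, reason logged).  When every sample fails the filter the gene
    keeps a fit object with all-missing PDUI rather than raising.
    """
    samples = list(coverage)
    if not samples:
        raise ValueError("no coverage tracks supplied")
    lengths = {len(np.asarray(coverage[s])) for s in samples}
    if len(lengths) != 1:
        raise ValueError(f"{gene_id}: coverage arrays of unequal length {lengths}")
    L = lengths.pop()
    if L < 2 * margin:
        log.info("%s skipped: UTR length %d < 2*margin=%d", gene_id, L, 2 * margin)
        return None

    mat = np.vstack([np.asarray(coverage[s], dtype=float) for s in samples])
    if (mat < 0).any():
        raise ValueError(f"{gene_id}: negative coverage")
    means = mat.mean(axis=1)
    passing = means >= min_mean_coverage
    nan = pd.Series(np.nan, index=samples)
    if not passing.any():
        return GeneAPAFit(gene_id=gene_id, utr_length=L, proximal_offset=None,
                          alpha_long=nan.copy(), alpha_short=nan.copy(),
                          pdui=nan.copy(), fit_rss=float("nan"), n_samples_used=0)

    sub = mat[passing]
    grid = np.arange(margin, L - margin + 1, grid_step, dtype=int)
    # prefix sums of depth and squared depth per passing sample
    S = np.concatenate([np.zeros((sub.shape[0], 1)), np.cumsum(sub, axis=1)], axis=1)
    Q = np.concatenate([np.zeros((sub.shape[0], 1)), np.cumsum(sub**2, axis=1)], axis=1)
    tot, tot2 = S[:, -1:], Q[:, -1:]

    P = grid[None, :].astype(float)
    m1 = S[:, grid] / P                                  # mean on [0, P)
    m2 = (tot - S[:, grid]) / (L - P)                    # mean on [P, L)
    lvl1 = np.maximum(m1, m2)                            # alpha_long + alpha_short
    rss1 = Q[:, grid] - 2 * lvl1 * S[:, grid] + lvl1**2 * P
    rss2 = (tot2 - Q[:, grid]) - 2 * m2 * (tot - S[:, grid]) + m2**2 * (L - P)
    total_rss = (rss1 + rss2).sum(axis=0)
    best = int(np.argmin(total_rss))                     # first minimum = smallest P
    P_hat = int(grid[best])
    # recompute the winning RSS directly from residuals (the prefix-sum
    # algebra above is exact enough to rank candidates but loses a few ulps)
    lvl1_best = lvl1[:, best][:, None]
    m2_best = m2[:, best][:, None]
    rss_best = float(((sub[:, :P_hat] - lvl1_best) ** 2).sum()
                     + ((sub[:, P_hat:] - m2_best) ** 2).sum())

    a_long = np.full(len(samples), np.nan)
    a_short = np.full(len(samples), np.nan)
    a_long[passing] = m2[:, best]
    a_short[passing] = np.maximum(0.0, m1[:, best] - m2[:, best])
    with np.errstate(invalid="ignore", divide="ignore"):
        pdui = a_long / (a_long + a_short)
    pdui = np.clip(pdui, 0.0, 1.0)
    # alpha_long + alpha_short == 0: undefined usage, keep missing
    pdui[np.nan_to_num(a_long) + np.nan_to_num(a_short) == 0] = np.nan
    pdui[~passing] = np.nan

    return GeneAPAFit(
        gene_id=gene_id, utr_length=L, proximal_offset=P_hat,
        alpha_long=pd.Series(a_long, index=samples),
        alpha_short=pd.Series(a_short, index=samples),
        pdui=pd.Series(pdui, index=samples),
        fit_rss=rss_best, n_samples_used=int(passing.sum()),
    )


def build_pdui_matrix(fits, labels: pd.Series,
                      min_samples_per_condition: int = 10) -> ApaDataset:
    """Assemble per-gene fits into a genes x samples PDUI matrix.

    Genes without a fitted breakpoint, or with fewer than
    ``min_samples_per_condition`` non-missing PDUI values in either
    condition, are dropped (counts logged).  Duplicate gene ids raise.
    """
    fits = [f for f in fits if f is not None]
    ids = [f.gene_id for f in fits]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    if not fits:
        raise ValueError("no fits supplied")
    samples = fits[0].pdui.index
    missing = set(samples) - set(labels.index)
    if missing:
        raise ValueError(f"labels do not cover samples: {sorted(missing)[:5]}")
    lab = labels.loc[samples]
    is_t = (lab == "tumor").to_numpy()
    is_n = (lab == "normal").to_numpy()

    kept, dropped = [], 0
    for f in fits:
        if not f.fitted:
            dropped += 1
            continue
        ok = f.pdui.notna().to_numpy()
        if ok[is_t].sum() < min_samples_per_condition or \
           ok[is_n].sum() < min_samples_per_condition:
            dropped += 1
            continue
        kept.append(f)
    if dropped:
        log.info("build_pdui_matrix: dropped %d/%d genes (no fit or too few "
                 "covered samples per condition)", dropped, len(fits))
    if not kept:
        raise ValueError("no genes pass the per-condition coverage minimum")

    idx = [f.gene_id for f in kept]
    return ApaDataset(
        pdui=pd.DataFrame([f.pdui.to_numpy() for f in kept], index=idx, columns=samples),
        labels=lab,
        alpha_long=pd.DataFrame([f.alpha_long.to_numpy() for f in kept],
                                index=idx, columns=samples),
        alpha_short=pd.DataFrame([f.alpha_short.to_numpy() for f in kept],
                                 index=idx, columns=samples),
        proximal_offset=pd.Series([f.proximal_offset for f in kept], index=idx),
        utr_length=pd.Series([f.utr_length for f in kept], index=idx),
    )


def estimate_cohort(coverage_iter, labels: pd.Series, grid_step: int = 10,
                    margin: int = 100, min_mean_coverage: float = 20.0,
                    min_samples_per_condition: int = 10) -> ApaDataset:
    """Fit every gene from an iterator of (gene_id, coverage dict) and build
    the PDUI matrix.  Convenience wrapper used by the CLI and pipelines."""
    fits = [estimate_pdui_gene(cov, gene_id=g, grid_step=grid_step,
                               margin=margin, min_mean_coverage=min_mean_coverage)
            for g, cov in coverage_iter]
    return build_pdui_matrix(fits, labels,
                             min_samples_per_condition=min_samples_per_condition)
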