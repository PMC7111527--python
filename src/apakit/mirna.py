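"""Conserved miRNA binding-site loss from 3'-UTR shortening.

Three quantities:

* per-gene lost-site counts — conserved sites lying in the distal-only
  region (at or beyond the fitted proximal PAS) of significantly shortened
  genes, i.e. the sites removed when the short 3'-UTR form is used;
* per-family Z-scores — a CWCS-weighted site score per condition
  (|CWCS| x abundance of the 3'-UTR form containing the site), fold change
  f = S_tumor / S_normal, compared against a null built by permuting family
  labels across sites: z = (f - m) / s.  More negative z = the family's
  sites are preferentially lost on shortening;
* the per-patient loss matrix X_{m,i} = sum_g (1 - PDUI_{i,g}) * A_{g,m},
  where A_{g,m} indicates a conserved distal-only site of family m in a
  significantly shortened gene g.

CWCS values are stored as provided (<= 0, more negative = stronger
repression); scoring uses |CWCS| so the weighted score is a non-negative
mass and a low z unambiguously means excess loss.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .formats import ApaDataset

log = logging.getLogger("apakit")

__all__ = ["annotate_site_regions", "count_conserved_site_loss",
           "build_form_abundance", "family_zscores", "mirna_loss_matrix"]


def annotate_site_regions(sites: pd.DataFrame,
                          proximal_offset: pd.Series) -> pd.DataFrame:
    """Attach region = shared (5' of the proximal PAS) vs distal_only
    (at/beyond it) using each gene's fitted proximal offset."""
    out = sites.copy()
    P = proximal_offset.reindex(out["gene_id"]).to_numpy(dtype=float)
    out["region"] = np.where(out["utr_offset_start"].to_numpy() >= P,
                             "distal_only", "shared")
    out.loc[np.isnan(P), "region"] = "unknown"
    return out


def count_conserved_site_loss(apa_results: pd.DataFrame,
                              sites: pd.DataFrame) -> dict:
    """Lost conserved sites per shortened gene and the fraction of shortened
    genes losing at least one site."""
    shortened = apa_results.loc[apa_results["apa_class"] == "shortened", "gene_id"]
    if "region" not in sites.columns:
        P = apa_results.set_index("gene_id")["proximal_offset"]
        sites = annotate_site_regions(sites, P)
    lost = sites[sites["conserved"] & (sites["region"] == "distal_only")
                 & sites["gene_id"].isin(set(shortened))]
    counts = lost.groupby("gene_id").size().reindex(shortened, fill_value=0)
    frac = float((counts >= 1).mean()) if len(counts) else float("nan")
    return {"per_gene": counts, "fraction_with_loss": frac,
            "n_shortened": int(len(counts))}


def build_form_abundance(dataset: ApaDataset, counts: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Normalized abundance of each gene's long and short 3'-UTR forms per
    condition: long = mean PDUI x mean normalized expression, short =
    (1 - mean PDUI) x mean normalized expression.

    Without an expression matrix the expression term is 1, i.e. abundances
    reduce to the PDUI fractions.  This construction is pluggable: any
    frame with columns long_tumor/short_tumor/long_normal/short_normal
    indexed by gene can replace it in :func:`family_zscores`.
    """
    mean_t = dataset.pdui[dataset.tumor_samples].mean(axis=1)
    mean_n = dataset.pdui[dataset.normal_samples].mean(axis=1)
    if counts is not None:
        from .expression import normalize_counts
        norm = normalize_counts(counts)
        lab = dataset.labels.loc[norm.columns] if set(norm.columns) <= set(
            dataset.labels.index) else None
        if lab is None:
            raise ValueError("count matrix samples not covered by labels")
        e_t = norm[norm.columns[(lab == "tumor").to_numpy()]].mean(axis=1)
        e_n = norm[norm.columns[(lab == "normal").to_numpy()]].mean(axis=1)
        e_t = e_t.reindex(mean_t.index).fillna(0.0)
        e_n = e_n.reindex(mean_n.index).fillna(0.0)
    else:
        e_t = pd.Series(1.0, index=mean_t.index)
        e_n = pd.Series(1.0, index=mean_n.index)
    return pd.DataFrame({
        "long_tumor": mean_t * e_t,
        "short_tumor": (1 - mean_t) * e_t,
        "long_normal": mean_n * e_n,
        "short_normal": (1 - mean_n) * e_n,
    })


def _site_weights(sites: pd.DataFrame, form_abundance: pd.DataFrame):
    """Per-site condition weights |cwcs| * abundance(form containing site)."""
    ab = form_abundance.reindex(sites["gene_id"])
    distal = (sites["region"] == "distal_only").to_numpy()
    w = np.abs(sites["cwcs"].to_numpy())
    # distal-only sites sit only in the long form; shared sites in both
    w_t = w * np.where(distal, ab["long_tumor"].to_numpy(),
                       ab["long_tumor"].to_numpy() + ab["short_tumor"].to_numpy())
    w_n = w * np.where(distal, ab["long_normal"].to_numpy(),
                       ab["long_normal"].to_numpy() + ab["short_normal"].to_numpy())
    return w_t, w_n


def family_zscores(apa_results: pd.DataFrame, sites: pd.DataFrame,
                   form_abundance: pd.DataFrame, n_perm: int = 1000,
                   seed: int = 0, permutations: np.ndarray | None = None
                   ) -> pd.DataFrame:
    """CWCS-weighted per-family fold change and permutation Z-score.

    Scores sum over conserved sites of each family within significantly
    shortened genes.  The null permutes the family labels across that site
    set (site positions, CWCS and genes fixed; per-family site counts
    preserved); permutations are shared across families within a run.
    ``permutations`` may supply an explicit (n_perm, n_sites) index array —
    rows are permutations of arange(n_sites) — so an external
    re-implementation can consume an identical permutation stream.

    Families with S_normal = 0 get f = NaN (sentinel) and are excluded from
    ranking; s = 0 yields an undefined z with ``z_defined`` False.
    """
    if n_perm < 1 and permutations is None:
        raise ValueError("n_perm must be >= 1")
    shortened = set(apa_results.loc[apa_results["apa_class"] == "shortened",
                                    "gene_id"])
    if "region" not in sites.columns:
        sites = annotate_site_regions(
            sites, apa_results.set_index("gene_id")["proximal_offset"])
    use = sites[sites["conserved"] & sites["gene_id"].isin(shortened)
                & (sites["region"] != "unknown")].reset_index(drop=True)
    fams = sorted(use["mirna_family"].unique())
    if not fams:
        raise ValueError("no conserved sites in shortened genes")
    fam_codes = pd.Categorical(use["mirna_family"], categories=fams).codes
    n_fam, n_sites = len(fams), len(use)
    w_t, w_n = _site_weights(use, form_abundance)

    def scores(codes: np.ndarray):
        s_t = np.bincount(codes, weights=w_t, minlength=n_fam)
        s_n = np.bincount(codes, weights=w_n, minlength=n_fam)
        return s_t, s_n

    s_t, s_n = scores(fam_codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(s_n > 0, s_t / s_n, np.nan)

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(n_sites) for _ in range(n_perm)])
    perm_f = np.full((len(permutations), n_fam), np.nan)
    for j, perm in enumerate(permutations):
        pt, pn = scores(fam_codes[perm])
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_f[j] = np.where(pn > 0, pt / pn, np.nan)
    m = np.nanmean(perm_f, axis=0)
    s = np.nanstd(perm_f, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (f - m) / s
    defined = np.isfinite(f) & (s > 0)
    n_def = int((~defined & np.isfinite(f)).sum())
    if n_def:
        log.info("family_zscores: %d families have degenerate permutation "
                 "spread (z undefined)", n_def)
    return pd.DataFrame({
        "mirna_family": fams,
        "s_tumor": s_t,
        "s_normal": s_n,
        "fold_change": f,
        "perm_mean": m,
        "perm_sd": s,
        "z": np.where(defined, z, np.nan),
        "z_defined": defined,
        "n_sites": np.bincount(fam_codes, minlength=n_fam),
    })


def mirna_loss_matrix(dataset: ApaDataset, apa_results: pd.DataFrame,
                      sites: pd.DataFrame) -> dict:
    """Per-patient loss scores X_{m,i} = sum_g (1 - PDUI_{i,g}) * A_{g,m}
    over tumor samples.

    A_{g,m} = 1 iff gene g is significantly shortened and carries >= 1
    conserved site of family m in its distal-only region.  Missing PDUI
    entries contribute 0; a per-cell completeness matrix (fraction of A=1
    genes with observed PDUI) is returned alongside.
    """
    shortened = set(apa_results.loc[apa_results["apa_class"] == "shortened",
                                    "gene_id"])
    if "region" not in sites.columns:
        sites = annotate_site_regions(
            sites, apa_results.set_index("gene_id")["proximal_offset"])
    lost = sites[sites["conserved"] & (sites["region"] == "distal_only")
                 & sites["gene_id"].isin(shortened)]
    tumor = dataset.tumor_samples
    fams = sorted(lost["mirna_family"].unique())
    if not fams:
        X = pd.DataFrame(index=pd.Index([], name="mirna_family"),
                         columns=tumor, dtype=float)
        return {"X": X, "A": pd.DataFrame(), "completeness": X.copy()}
    pairs = lost[["mirna_family", "gene_id"]].drop_duplicates()
    A = pd.crosstab(pairs["mirna_family"], pairs["gene_id"]).clip(upper=1)
    A = A.reindex(index=fams, columns=dataset.pdui.index, fill_value=0).astype(float)
    P = dataset.pdui[tumor].to_numpy(dtype=float)
    observed = np.isfinite(P).astype(float)
    loss = np.where(np.isfinite(P), 1.0 - P, 0.0)
    X = pd.DataFrame(A.to_numpy() @ loss, index=A.index, columns=tumor)
    denom = A.sum(axis=1).to_numpy()[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = (A.to_numpy() @ observed) / denom
    completeness = pd.DataFrame(comp, index=A.index, columns=tumor)
    return {"X": X, "A": A, "completeness": completeness}
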