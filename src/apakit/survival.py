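"""Prognostic modeling from APA and miRNA-loss features.

Two procedures:

(a) APA cohorts — fit a Cox proportional-hazards model on the clinical
    covariates alone (age, sex, race, stage, grade, residual tumor), take
    its martingale residuals as the survival signal left unexplained by the
    clinical subspace, screen significant-APA genes by univariate
    association of residuals with PDUI, and k-means the patients in the
    selected feature space (K = 3, repeated restarts; stability = fraction
    of restarts whose labels split survival at log-rank p < 0.05).

(b) miRNA-loss signature — Sure Independence Screening of the per-patient
    loss matrix X against survival (univariate Cox per family), Gaussian-
    mixture clustering of patients in the selected feature space with BIC
    choosing the cluster number (a 2-D t-SNE embedding is emitted for
    plotting only), and an analysis-of-deviance test of nested Cox models
    (clinical vs clinical + cluster indicators) with per-cluster hazard
    ratios against a declared reference cluster.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture

log = logging.getLogger("apakit")

__all__ = ["clinical_design_matrix", "clinical_residuals", "select_pdui_features",
           "kmeans_cohorts", "km_logrank", "sis_mirna_features", "gmm_clusters",
           "nested_cox_deviance"]

CLINICAL_COVARIATES = ["age", "sex", "race", "stage", "grade", "residual_tumor"]

# small ridge keeps the partial likelihood well-behaved when indicator
# covariates are collinear (e.g. cluster labels nested in a covariate)
_PENALIZER = 1e-6


def clinical_design_matrix(clinical: pd.DataFrame,
                           covariates=CLINICAL_COVARIATES) -> pd.DataFrame:
    """One-hot encode categorical covariates with the most frequent level as
    the reference; numeric covariates pass through."""
    cl = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    parts = []
    for c in covariates:
        col = cl[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).to_frame(c))
        else:
            ref = col.value_counts().idxmax()
            levels = [l for l in col.value_counts().index if l != ref]
            for lv in levels:
                parts.append((col == lv).astype(float).to_frame(f"{c}[{lv}]"))
    return pd.concat(parts, axis=1)


def _prepare_survival_frame(clinical: pd.DataFrame,
                            covariates=CLINICAL_COVARIATES) -> pd.DataFrame:
    cl = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    if cl.index.duplicated().any():
        raise ValueError(
            f"duplicate patient rows: {cl.index[cl.index.duplicated()].tolist()[:5]}")
    design = clinical_design_matrix(cl, covariates)
    df = pd.concat([cl[["time", "event"]], design], axis=1)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        log.info("survival: listwise-deleted %d patients with missing "
                 "covariates", n0 - len(df))
    return df


def _fit_cox(df: pd.DataFrame, penalizer: float = _PENALIZER) -> CoxPHFitter:
    if df["event"].sum() == 0:
        raise ValueError("all-censored input: Cox model is unidentifiable")
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="time", event_col="event")
    return cph


def clinical_residuals(clinical: pd.DataFrame, kind: str = "martingale"
                       ) -> pd.Series:
    """Residuals from the clinical-only Cox model.

    Martingale residuals (event indicator minus estimated cumulative
    hazard) by default; ``kind='deviance'`` switches.  They carry whatever
    survival signal the clinical covariates do not explain, and sum to ~0
    across patients.
    """
    df = _prepare_survival_frame(clinical)
    if len(df) < 20:
        raise ValueError(f"need >=20 complete patients, got {len(df)}")
    cph = _fit_cox(df)
    res = cph.compute_residuals(df, kind=kind)
    out = res[kind].reindex(df.index)
    out.name = f"{kind}_residual"
    return out


def select_pdui_features(residuals: pd.Series, pdui: pd.DataFrame,
                         candidate_genes=None, k: int = 20) -> pd.DataFrame:
    """Screen genes by univariate linear association of clinical-model
    residuals with tumor PDUI.

    ``candidate_genes`` restricts the screen (normally the significant APA
    hits).  Returns the top ``k`` genes ranked by p-value, ties broken by
    |slope| then gene id.  Asks for more genes than exist -> all genes,
    with a warning.
    """
    genes = pdui.index if candidate_genes is None else \
        pdui.index.intersection(pd.Index(list(candidate_genes)))
    if len(genes) == 0:
        raise ValueError("no candidate genes present in the PDUI matrix")
    samples = pdui.columns.intersection(residuals.index)
    rows = []
    for g in genes:
        x = pdui.loc[g, samples]
        y = residuals.loc[samples]
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].nunique() < 2:
            continue
        fit = stats.linregress(x[ok], y[ok])
        rows.append(dict(gene_id=g, slope=fit.slope, p=fit.pvalue, n=int(ok.sum())))
    scr = pd.DataFrame(rows)
    if scr.empty:
        raise ValueError("no gene had enough paired residual/PDUI values")
    scr["abs_slope"] = scr["slope"].abs()
    scr = scr.sort_values(["p", "abs_slope", "gene_id"],
                          ascending=[True, False, True]).drop(columns="abs_slope")
    if k > len(scr):
        warnings.warn(f"requested k={k} features but only {len(scr)} genes "
                      "screened; returning all", stacklevel=2)
        k = len(scr)
    return scr.head(k).reset_index(drop=True)


def kmeans_cohorts(selected: pd.DataFrame, K: int = 3, n_restarts: int = 100,
                   seed: int = 0, times: pd.Series | None = None,
                   events: pd.Series | None = None) -> dict:
    """k-means patient cohorts in the selected feature space.

    ``selected`` is patients x features; missing entries are median-imputed.
    Runs ``n_restarts`` independently seeded single initializations and
    reports the labels of the restart with minimal within-cluster sum of
    squares.  When survival columns are supplied, stability = fraction of
    restarts whose labels give log-rank p < 0.05.  An elbow report (WSS for
    K = 1..6) is emitted alongside.
    """
    if K < 2:
        raise ValueError("K must be >= 2 (a single cohort admits no log-rank test)")
    X = selected.apply(lambda c: c.fillna(c.median()), axis=0).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    signif = 0
    n_tested = 0
    for _ in range(n_restarts):
        km = KMeans(n_clusters=K, n_init=1,
                    random_state=int(rng.integers(2**31))).fit(X)
        if best is None or km.inertia_ < best.inertia_:
            best = km
        if times is not None and events is not None:
            lr = multivariate_logrank_test(times.loc[selected.index],
                                           km.labels_, events.loc[selected.index])
            n_tested += 1
            signif += int(lr.p_value < 0.05)
    labels = pd.Series(best.labels_, index=selected.index, name="cohort")
    elbow = []
    for kk in range(1, 7):
        if kk > len(selected):
            break
        km = KMeans(n_clusters=kk, n_init=5, random_state=seed).fit(X)
        elbow.append(dict(K=kk, wss=float(km.inertia_)))
    return {"labels": labels,
            "stability": signif / n_tested if n_tested else None,
            "inertia": float(best.inertia_),
            "elbow": pd.DataFrame(elbow)}


def km_logrank(times: pd.Series, events: pd.Series, labels: pd.Series) -> dict:
    """Kaplan-Meier curves per group and the k-group log-rank test."""
    groups = pd.Series(labels)
    if groups.nunique() < 2:
        raise ValueError("need >=2 groups for a log-rank test")
    if events.sum() == 0:
        raise ValueError("need >=1 event")
    curves = {}
    for g in sorted(groups.unique()):
        sel = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(times)[sel], np.asarray(events)[sel], label=str(g))
        curves[g] = kmf.survival_function_
    lr = multivariate_logrank_test(times, groups, events)
    return {"curves": curves, "chi2": float(lr.test_statistic),
            "p": float(lr.p_value), "df": int(groups.nunique() - 1)}


def sis_mirna_features(loss_matrix: pd.DataFrame, clinical: pd.DataFrame,
                       p_screen: float = 0.05, top_d: int | None = None
                       ) -> pd.DataFrame:
    """Sure Independence Screening of miRNA-loss scores against survival.

    Univariate Cox per family on X_{m,.}; families constant across patients
    are excluded (no information).  Retains families with p below
    ``p_screen`` (or the ``top_d`` smallest p when given), ranked by p.
    """
    cl = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    common = loss_matrix.columns.intersection(cl.index)
    if len(common) < 10:
        raise ValueError("too few patients shared between X and clinical")
    rows = []
    for fam in loss_matrix.index:
        x = loss_matrix.loc[fam, common].astype(float)
        if x.nunique() <= 1:
            log.info("sis: family %s constant across patients; excluded", fam)
            continue
        df = pd.DataFrame({"time": cl.loc[common, "time"],
                           "event": cl.loc[common, "event"], "x": x})
        try:
            cph = _fit_cox(df.dropna())
        except Exception as exc:  # non-convergent family: skip, keep screening
            log.warning("sis: Cox fit failed for %s (%s)", fam, exc)
            continue
        rows.append(dict(mirna_family=fam, coef=float(cph.params_["x"]),
                         p=float(cph.summary.loc["x", "p"])))
    scr = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    if top_d is not None:
        return scr.head(top_d)
    return scr[scr["p"] < p_screen].reset_index(drop=True)


def gmm_clusters(selected_X: pd.DataFrame, max_k: int = 6, seed: int = 0,
                 tsne_perplexity: float = 30.0) -> dict:
    """Model-based Gaussian clustering with BIC model selection.

    ``selected_X`` is patients x features; features are standardized before
    fitting.  k runs 1..max_k, the minimum-BIC model supplies labels.  The
    returned t-SNE embedding is for visualization only and never feeds the
    clustering.
    """
    if len(selected_X) < 10:
        raise ValueError("need >=10 patients")
    X = selected_X.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    bics = []
    models = {}
    for k in range(1, max_k + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=5, random_state=seed).fit(X)
        bics.append(dict(k=k, bic=float(gm.bic(X))))
        models[k] = gm
    bic_frame = pd.DataFrame(bics)
    chosen = int(bic_frame.loc[bic_frame["bic"].idxmin(), "k"])
    labels = pd.Series(models[chosen].predict(X), index=selected_X.index,
                       name="cluster")
    perplexity = min(tsne_perplexity, (len(selected_X) - 1) / 3.0)
    init = "pca" if X.shape[1] >= 2 else "random"
    embedding = TSNE(n_components=2, perplexity=perplexity, init=init,
                     random_state=seed).fit_transform(X)
    return {"labels": labels, "chosen_k": chosen, "bic": bic_frame,
            "embedding": pd.DataFrame(embedding, index=selected_X.index,
                                      columns=["tsne1", "tsne2"])}


def nested_cox_deviance(clinical: pd.DataFrame, cluster_labels: pd.Series,
                        reference_cluster=None) -> dict:
    """Likelihood-ratio (analysis of deviance) test of nested Cox models:
    clinical covariates vs clinical + cluster indicators.

    chi2 = 2 (loglik_full - loglik_reduced) clipped at 0, df = n_clusters-1;
    hazard ratios are reported for each non-reference cluster indicator.
    Both models are fitted on the identical patient set.
    """
    df = _prepare_survival_frame(clinical)
    labels = cluster_labels.loc[df.index]
    k = labels.nunique()
    if k < 2:
        raise ValueError("need >=2 clusters")
    if reference_cluster is None:
        reference_cluster = sorted(labels.unique())[0]
    reduced = _fit_cox(df)
    full_df = df.copy()
    dummy_cols = []
    for c in sorted(labels.unique()):
        if c == reference_cluster:
            continue
        col = f"cluster[{c}]"
        full_df[col] = (labels == c).astype(float)
        dummy_cols.append(col)
    full = _fit_cox(full_df)
    chi2 = max(0.0, 2.0 * (full.log_likelihood_ - reduced.log_likelihood_))
    df_test = k - 1
    p = float(stats.chi2.sf(chi2, df_test))
    hrs = {c: float(np.exp(full.params_[c])) for c in dummy_cols}
    return {"chi2": float(chi2), "df": df_test, "p": p,
            "hazard_ratios": hrs, "reference_cluster": reference_cluster,
            "loglik_reduced": float(reduced.log_likelihood_),
            "loglik_full": float(full.log_likelihood_)}
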