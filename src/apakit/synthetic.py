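"""Synthetic tumor/normal APA cohorts with known ground truth.

The generator emulates the statistical structure of a bulk RNA-seq
tumor-versus-normal comparison of 3'-UTR poly(A)-site usage:

* per-gene two-level step coverage over the 3' UTR (full depth up to the
  proximal PAS, ``depth x PDUI`` beyond it) with Poisson or negative-binomial
  count noise per base;
* per-sample PDUI drawn from Beta distributions whose means encode condition
  and planted APA class (shortened / lengthened / unchanged) and whose
  concentration is deflated in tumors for a "heterogeneous" gene subset;
* gene expression counts coupled to short-form usage for miRNA-regulated
  genes (multiplier ``exp(k * (1 - PDUI))``), so 3'-UTR shortening drives
  up-regulation;
* a TargetScan-style conserved site table, with designated prognostic miRNA
  families whose sites sit exclusively in the distal (lost-on-shortening)
  regions of shortened genes;
* survival times from an exponential proportional-hazards model whose linear
  predictor combines clinical covariates and the planted per-patient
  miRNA-loss scores X_{m,i}, with administrative censoring.

Everything is deterministic given ``config.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (ApaDataset, UTRAnnotation, runs_from_array,
                      write_bedgraph, write_labels, write_matrix,
                      write_site_table, write_table, write_utr_bed)

log = logging.getLogger("apakit")

__all__ = ["SimulationConfig", "GroundTruth", "SyntheticCohort",
           "simulate_cohort", "simulate_pdui_dataset", "dataset_from_truth",
           "truth_join", "write_cohort"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized discovery cohort: 200 genes, 50 tumors vs
    50 normals at 50x UTR coverage, 15% of genes planted shortened and 10%
    lengthened with |dPDUI| = 0.3, 10% of genes with 6.25-fold tumor variance
    inflation (Beta concentration 50 -> 8), and two prognostic miRNA families
    whose site loss carries log-hazard 0.7 per unit X.
    """

    n_genes: int = 200
    n_tumor: int = 50
    n_normal: int = 50
    utr_length_range: tuple = (500, 2000)
    fraction_shortened: float = 0.15
    fraction_lengthened: float = 0.10
    planted_delta_pdui: float = 0.3
    fraction_heterogeneous: float = 0.10
    fraction_housekeeping: float = 0.10
    concentration: float = 50.0          # Beta concentration, homogeneous genes
    tumor_variance_inflation: float = 6.25  # het genes: concentration / this
    depth_mean: float = 50.0             # expected reads/base on the shared segment
    noise_model: str = "poisson"         # or "negative_binomial"
    nb_dispersion: float = 0.1           # 1/size for the NB model
    n_mirna_families: int = 30
    sites_per_utr_rate: float = 2.0
    conserved_fraction: float = 0.9
    prognostic_mirnas: tuple = ("miR-P1", "miR-P2")
    prognostic_genes_per_family: int = 5
    prognostic_pdui_shift: float = 0.25  # extra shortening in the poor-outcome group
    planted_log_hazard_per_unit_X: float = 0.7
    expression_coupling_k: float = 1.0
    baseline_median_survival_days: float = 1500.0
    censor_horizon_days: float = 1095.0
    spacer_bp: int = 1000
    chrom: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        fr = (self.fraction_shortened, self.fraction_lengthened,
              self.fraction_heterogeneous, self.fraction_housekeeping)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_shortened + self.fraction_lengthened + self.fraction_housekeeping > 1:
            raise ValueError("planted class fractions sum to more than 1")
        if min(self.n_genes, self.n_tumor, self.n_normal) <= 0:
            raise ValueError("n_genes, n_tumor, n_normal must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        lo, hi = self.utr_length_range
        if lo < 400 or hi < lo:
            raise ValueError("utr_length_range must satisfy 400 <= lo <= hi; "
                             "shorter UTRs leave no room for a proximal PAS "
                             "inside the fit margins")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.planted_delta_pdui <= 0 or self.planted_delta_pdui > 0.5:
            raise ValueError("planted_delta_pdui must be in (0, 0.5]")
        if len(self.prognostic_mirnas) > self.n_mirna_families:
            raise ValueError("more prognostic families than families")


@dataclass
class GroundTruth:
    """Everything the generator decided, for parameter-recovery scoring."""

    genes: pd.DataFrame          # per-gene: class, true PAS, means, flags
    pdui: pd.DataFrame           # genes x samples true PDUI
    labels: pd.Series            # sample -> condition
    counts: pd.DataFrame         # genes x samples expression counts
    sites: pd.DataFrame          # genomic site table (SITE_COLUMNS)
    clinical: pd.DataFrame       # tumor samples only
    x_true: pd.DataFrame         # prognostic families x tumor samples
    hazard: pd.DataFrame         # per-tumor linear predictor and group


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    utrs: UTRAnnotation
    truth: GroundTruth
    _coverage_seeds: list = field(repr=False, default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.truth.pdui.columns

    def gene_coverage(self, gene_id: str) -> dict:
        """Per-sample 5'->3' coverage arrays for one gene, drawn lazily but
        deterministically (each gene owns a spawned RNG stream)."""
        g = self.truth.genes.set_index("gene_id").loc[gene_id]
        i = int(g["gene_index"])
        rng = np.random.default_rng(self._coverage_seeds[i])
        L = int(g["utr_length"])
        P = int(g["true_pas"])
        depth = self.config.depth_mean * float(g["depth_factor"])
        lib = self.truth.hazard.attrs["lib_factor"]  # per-sample, all samples
        pdui = self.truth.pdui.loc[gene_id]
        out = {}
        for s in self.samples:
            mean = np.empty(L)
            mean[:P] = depth * lib[s]
            mean[P:] = depth * lib[s] * pdui[s]
            out[s] = _draw_counts(rng, mean, self.config)
        return out

    def iter_gene_coverage(self):
        for gene_id in self.truth.genes["gene_id"]:
            yield gene_id, self.gene_coverage(gene_id)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 config: SimulationConfig) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(mean).astype(np.int32)
    size = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam).astype(np.int32)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort (annotation, truth, coverage streams).

    Use :func:`write_cohort` to materialize it in the on-disk formats the
    pipeline reads.  Coverage is drawn lazily per gene so large cohorts never
    hold the full base-level matrix in memory.
    """
    config.validate()
    master = np.random.SeedSequence([int(config.seed), 2**20])
    truth_rng = np.random.default_rng(master.spawn(1)[0])
    coverage_seeds = np.random.SeedSequence([int(config.seed), 2**20 + 1]).spawn(config.n_genes)

    genes = _plant_genes(config, truth_rng)
    utrs = _layout_utrs(config, genes)
    labels = _sample_labels(config)
    clinical_frame, group = _draw_clinical(config, truth_rng)
    pdui = _draw_pdui(config, truth_rng, genes, labels, group)
    sites = _plant_sites(config, truth_rng, genes, utrs)
    counts = _draw_counts_matrix(config, truth_rng, genes, pdui, labels)
    x_true = _planted_x(config, genes, sites, utrs, pdui, labels)
    clinical, hazard = _draw_survival(config, truth_rng, clinical_frame, group, x_true)

    lib = pd.Series(
        truth_rng.uniform(0.8, 1.2, size=len(labels)), index=labels.index
    )
    hazard.attrs["lib_factor"] = lib

    truth = GroundTruth(genes=genes, pdui=pdui, labels=labels, counts=counts,
                        sites=sites, clinical=clinical, x_true=x_true, hazard=hazard)
    return SyntheticCohort(config=config, utrs=utrs, truth=truth,
                           _coverage_seeds=list(coverage_seeds))


def _sample_labels(config: SimulationConfig) -> pd.Series:
    tumor = [f"T{i:03d}" for i in range(config.n_tumor)]
    normal = [f"N{i:03d}" for i in range(config.n_normal)]
    return pd.Series(["tumor"] * len(tumor) + ["normal"] * len(normal),
                     index=tumor + normal)


def _plant_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    lo, hi = config.utr_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    # proximal PAS well inside the UTR so the fit margins never clip it
    pas = np.floor(lengths * rng.uniform(0.25, 0.75, size=n)).astype(int)
    pas = np.clip(pas, 150, lengths - 150)

    n_hk = int(round(config.fraction_housekeeping * n))
    n_short = int(round(config.fraction_shortened * n))
    n_long = int(round(config.fraction_lengthened * n))
    order = rng.permutation(n)
    hk_idx = order[:n_hk]
    short_idx = order[n_hk:n_hk + n_short]
    long_idx = order[n_hk + n_short:n_hk + n_short + n_long]
    rest = order[n_hk + n_short + n_long:]
    n_het = int(round(config.fraction_heterogeneous * n))
    if n_het > len(rest):
        raise ValueError("not enough unchanged genes to plant heterogeneity; "
                         "lower fraction_heterogeneous or the class fractions")
    het_idx = rest[:n_het]

    apa_class = np.array(["unchanged"] * n, dtype=object)
    apa_class[short_idx] = "shortened"
    apa_class[long_idx] = "lengthened"
    hk = np.zeros(n, dtype=bool)
    hk[hk_idx] = True
    het = np.zeros(n, dtype=bool)
    het[het_idx] = True

    d = config.planted_delta_pdui
    normal_mean = rng.uniform(0.30, 0.70, size=n)
    normal_mean[short_idx] = rng.uniform(0.55, 0.80, size=len(short_idx))
    normal_mean[long_idx] = rng.uniform(0.20, 0.45, size=len(long_idx))
    tumor_mean = normal_mean.copy()
    tumor_mean[short_idx] -= d
    tumor_mean[long_idx] += d
    tumor_mean = np.clip(tumor_mean, 0.05, 0.95)

    # prognostic target genes: drawn from the shortened set; small cohorts
    # cap the plant at the genes available
    n_fams = len(config.prognostic_mirnas)
    per_fam = config.prognostic_genes_per_family
    if n_fams and per_fam * n_fams > len(short_idx):
        per_fam = len(short_idx) // n_fams
        if per_fam == 0:
            raise ValueError("no shortened genes available for the prognostic "
                             "plant; raise fraction_shortened or drop "
                             "prognostic_mirnas")
        log.info("prognostic plant capped at %d genes/family", per_fam)
    prog_family = np.array([""] * n, dtype=object)
    if n_fams:
        prog_targets = rng.choice(short_idx, size=per_fam * n_fams, replace=False)
        for j, fam in enumerate(config.prognostic_mirnas):
            prog_family[prog_targets[j * per_fam:(j + 1) * per_fam]] = fam

    return pd.DataFrame({
        "gene_index": np.arange(n),
        "gene_id": [f"gene{i:04d}" for i in range(n)],
        "utr_length": lengths,
        "true_pas": pas,
        "apa_class": apa_class,
        "housekeeping": hk,
        "heterogeneous": het,
        "normal_mean_pdui": normal_mean,
        "tumor_mean_pdui": tumor_mean,
        "prognostic_family": prog_family,
        "expression_factor": rng.lognormal(mean=np.log(200.0), sigma=0.6, size=n),
        "depth_factor": rng.uniform(0.7, 1.5, size=n),
    })


def _layout_utrs(config: SimulationConfig, genes: pd.DataFrame) -> UTRAnnotation:
    """Gene blocks laid head-to-tail on one synthetic chromosome with
    fixed spacers; strands alternate to exercise the reflection logic."""
    rows = []
    pos = config.spacer_bp
    for r in genes.itertuples(index=False):
        strand = "+" if r.gene_index % 2 == 0 else "-"
        rows.append(dict(gene_id=r.gene_id, transcript_id=f"tx{r.gene_index:04d}",
                         chrom=config.chrom, utr_start=pos,
                         utr_end=pos + int(r.utr_length), strand=strand))
        pos += int(r.utr_length) + config.spacer_bp
    return UTRAnnotation(pd.DataFrame(rows))


def _draw_clinical(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_tumor
    samples = [f"T{i:03d}" for i in range(n)]
    group = pd.Series(rng.integers(0, 2, size=n), index=samples)  # latent outcome group
    frame = pd.DataFrame({
        "sample_id": samples,
        "age": np.clip(rng.normal(65, 9, size=n), 40, 88).round(1),
        "sex": rng.choice(["male", "female"], size=n),
        "race": rng.choice(["white", "black", "asian", "other"], size=n,
                           p=[0.7, 0.12, 0.12, 0.06]),
        "stage": rng.choice(["I", "II", "III", "IV"], size=n,
                            p=[0.1, 0.6, 0.2, 0.1]),
        "grade": rng.choice(["G1", "G2", "G3"], size=n, p=[0.15, 0.55, 0.3]),
        "residual_tumor": rng.choice(["R0", "R1", "R2"], size=n, p=[0.6, 0.3, 0.1]),
        "purity": np.round(rng.beta(8, 3, size=n), 3),
    })
    return frame, group


def _draw_pdui(config: SimulationConfig, rng: np.random.Generator,
               genes: pd.DataFrame, labels: pd.Series,
               group: pd.Series) -> pd.DataFrame:
    n_genes, n_samples = len(genes), len(labels)
    is_tumor = (labels == "tumor").to_numpy()
    mean = np.empty((n_genes, n_samples))
    mean[:, is_tumor] = genes["tumor_mean_pdui"].to_numpy()[:, None]
    mean[:, ~is_tumor] = genes["normal_mean_pdui"].to_numpy()[:, None]

    # poor-outcome tumors (group 1) shorten the prognostic target genes further
    prog = (genes["prognostic_family"] != "").to_numpy()
    tumor_cols = np.flatnonzero(is_tumor)
    poor = np.array([c for c, s in zip(tumor_cols, labels.index[tumor_cols])
                     if group.get(s, 0) == 1], dtype=int)
    if prog.any() and poor.size:
        mean[np.ix_(prog, poor)] = np.clip(
            mean[np.ix_(prog, poor)] - config.prognostic_pdui_shift, 0.05, 0.95)

    kappa = np.full((n_genes, n_samples), config.concentration)
    het = genes["heterogeneous"].to_numpy()
    kappa[np.ix_(het, is_tumor)] = config.concentration / config.tumor_variance_inflation
    a = mean * kappa
    b = (1.0 - mean) * kappa
    pdui = rng.beta(a, b)
    return pd.DataFrame(pdui, index=genes["gene_id"].to_numpy(), columns=labels.index)


def _plant_sites(config: SimulationConfig, rng: np.random.Generator,
                 genes: pd.DataFrame, utrs: UTRAnnotation) -> pd.DataFrame:
    """Conserved miRNA sites in genomic coordinates.

    Background families get sites uniform over each UTR; each prognostic
    family gets one strong conserved site in the distal-only region of each
    of its target genes, plus the planted "lost-sites" structure that the
    family Z-score stage is meant to recover.
    """
    fam_names = [f"miR-b{j:02d}" for j in range(
        config.n_mirna_families - len(config.prognostic_mirnas))]
    site_w = 7
    rows = []
    ann = utrs.table.set_index("gene_id")
    for r in genes.itertuples(index=False):
        L = int(r.utr_length)
        n_sites = rng.poisson(config.sites_per_utr_rate)
        for _ in range(n_sites):
            rel = int(rng.integers(0, L - site_w))
            rows.append((rng.choice(fam_names), r.gene_id, rel,
                         -float(np.round(rng.uniform(0.05, 0.6), 3)),
                         bool(rng.random() < config.conserved_fraction)))
        if r.prognostic_family:
            lo = int(r.true_pas) + 10
            rel = int(rng.integers(lo, max(lo + 1, L - site_w)))
            rows.append((r.prognostic_family, r.gene_id, rel,
                         -float(np.round(rng.uniform(0.35, 0.6), 3)), True))
    out = []
    for fam, gene_id, rel, cwcs, cons in rows:
        a = ann.loc[gene_id]
        if a["strand"] == "+":
            s0 = int(a["utr_start"]) + rel
        else:
            s0 = int(a["utr_end"]) - rel - site_w
        out.append(dict(mirna_family=fam, gene_id=gene_id, chrom=a["chrom"],
                        site_start=s0, site_end=s0 + site_w, cwcs=cwcs,
                        conserved_flag=cons))
    return pd.DataFrame(out, columns=["mirna_family", "gene_id", "chrom",
                                      "site_start", "site_end", "cwcs",
                                      "conserved_flag"])


def _draw_counts_matrix(config: SimulationConfig, rng: np.random.Generator,
                        genes: pd.DataFrame, pdui: pd.DataFrame,
                        labels: pd.Series) -> pd.DataFrame:
    """Expression counts; miRNA-regulated genes (>=1 conserved site planted
    later implies regulation, here: all shortened/lengthened genes plus a
    random subset) carry the exp(k * (1 - PDUI)) coupling."""
    base = genes["expression_factor"].to_numpy()[:, None]
    lib = rng.lognormal(0.0, 0.15, size=len(labels))[None, :]
    regulated = (genes["apa_class"] != "unchanged").to_numpy()
    coupling = np.ones((len(genes), len(labels)))
    k = config.expression_coupling_k
    if k != 0:
        p = pdui.to_numpy()
        norm_mean = genes["normal_mean_pdui"].to_numpy()[:, None]
        # anchored at the normal-state mean so unregulated-looking baselines
        # stay comparable across classes
        coupling[regulated] = np.exp(k * ((1 - p[regulated])
                                          - (1 - norm_mean[regulated])))
    mean = base * lib * coupling
    counts = _draw_counts(rng, mean, config).astype(np.int64)
    return pd.DataFrame(counts, index=pdui.index, columns=labels.index)


def _planted_x(config: SimulationConfig, genes: pd.DataFrame, sites: pd.DataFrame,
               utrs: UTRAnnotation, pdui: pd.DataFrame,
               labels: pd.Series) -> pd.DataFrame:
    """True X_{m,i} = sum_g (1 - PDUI_{i,g}) * A_{g,m} over tumor samples,
    with A from conserved sites in the distal-only region of truly
    shortened genes."""
    from .formats import map_sites_to_utr
    mapped = map_sites_to_utr(sites, utrs)
    gmeta = genes.set_index("gene_id")
    shortened = gmeta["apa_class"] == "shortened"
    pas = gmeta["true_pas"]
    keep = (mapped["conserved"]
            & shortened.loc[mapped["gene_id"]].to_numpy()
            & (mapped["utr_offset_start"].to_numpy()
               >= pas.loc[mapped["gene_id"]].to_numpy()))
    lost = mapped[keep]
    tumor = labels.index[(labels == "tumor").to_numpy()]
    if lost.empty:
        return pd.DataFrame(index=pd.Index([], name="mirna_family"), columns=tumor,
                            dtype=float)
    a = (lost.groupby(["mirna_family", "gene_id"]).size() > 0).astype(float)
    A = a.unstack(fill_value=0.0).reindex(columns=pdui.index, fill_value=0.0)
    loss = (1.0 - pdui[tumor]).to_numpy()
    X = A.to_numpy() @ loss
    return pd.DataFrame(X, index=A.index, columns=tumor)


def _draw_survival(config: SimulationConfig, rng: np.random.Generator,
                   clinical: pd.DataFrame, group: pd.Series,
                   x_true: pd.DataFrame):
    """Exponential survival under a Cox linear predictor: modest clinical
    effects plus the planted miRNA-loss score effect; administrative
    censoring at the configured horizon."""
    cl = clinical.set_index("sample_id")
    lp = (
        0.02 * (cl["age"] - 65.0)
        + cl["stage"].isin(["III", "IV"]).astype(float) * 0.4
        + (cl["grade"] == "G3").astype(float) * 0.3
        + cl["residual_tumor"].isin(["R1", "R2"]).astype(float) * 0.5
    )
    beta = config.planted_log_hazard_per_unit_X
    x_prog = x_true.reindex(list(config.prognostic_mirnas)).fillna(0.0)
    x_sum = x_prog.sum(axis=0).reindex(cl.index).fillna(0.0)
    lp = lp + beta * (x_sum - x_sum.mean())
    lam0 = np.log(2.0) / config.baseline_median_survival_days
    t = rng.exponential(1.0 / (lam0 * np.exp(lp - lp.mean())))
    horizon = config.censor_horizon_days
    event = (t <= horizon).astype(int)
    time = np.ceil(np.minimum(t, horizon)).astype(int).clip(min=1)
    out = clinical.copy()
    out.insert(1, "time", time)
    out.insert(2, "event", event)
    hazard = pd.DataFrame({"sample_id": cl.index, "group": group.loc[cl.index].to_numpy(),
                           "linear_predictor": lp.to_numpy()})
    return out, hazard


# ---------------------------------------------------------------------------
# fast PDUI-level cohorts (no coverage): for stage-level calibration studies
# ---------------------------------------------------------------------------

def dataset_from_truth(cohort: SyntheticCohort) -> ApaDataset:
    """Build an :class:`ApaDataset` from the generator's true PDUI values,
    bypassing coverage fitting (as if estimation were perfect).

    Segment abundances are set consistently with the coverage model
    (``alpha_long + alpha_short`` = expected shared-segment depth), so the
    Fisher-count construction downstream behaves as it would after a
    noise-free fit.
    """
    t = cohort.truth
    genes = t.genes
    lib = t.hazard.attrs["lib_factor"].loc[t.pdui.columns]
    depth = (cohort.config.depth_mean
             * genes["depth_factor"].to_numpy()[:, None]
             * lib.to_numpy()[None, :])
    pdui = t.pdui
    return ApaDataset(
        pdui=pdui, labels=t.labels,
        alpha_long=pd.DataFrame(depth * pdui.to_numpy(), index=pdui.index,
                                columns=pdui.columns),
        alpha_short=pd.DataFrame(depth * (1 - pdui.to_numpy()), index=pdui.index,
                                 columns=pdui.columns),
        proximal_offset=pd.Series(genes["true_pas"].to_numpy(),
                                  index=genes["gene_id"].to_numpy()),
        utr_length=pd.Series(genes["utr_length"].to_numpy(),
                             index=genes["gene_id"].to_numpy()),
        purity=t.clinical.set_index("sample_id")["purity"],
    )


def simulate_pdui_dataset(config: SimulationConfig,
                          seed: int | None = None) -> tuple:
    """Simulate a cohort and return ``(dataset, cohort)`` where the dataset
    carries the true PDUI values directly (no coverage fitting).

    The fast path for stage-level calibration studies: the coverage arrays
    are never drawn, but the truth tables (classes, sites, clinical, X) are
    the same ones a full run would see.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    cohort = simulate_cohort(config)
    return dataset_from_truth(cohort), cohort


# ---------------------------------------------------------------------------
# writing and truth joins
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Materialize a cohort in the formats the pipeline reads.

    Writes the UTR BED, one bedGraph per sample, the count matrix, site
    table, clinical table, labels, and the ground-truth tables.  Returns a
    dict of paths.  Deterministic: the same config yields byte-identical
    files.
    """
    os.makedirs(outdir, exist_ok=True)
    covdir = os.path.join(outdir, "coverage")
    os.makedirs(covdir, exist_ok=True)
    paths = {
        "utr_bed": os.path.join(outdir, "utr.bed"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "sites": os.path.join(outdir, "sites.tsv"),
        "clinical": os.path.join(outdir, "clinical.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "coverage_dir": covdir,
        "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
        "truth_pdui": os.path.join(outdir, "truth_pdui.tsv"),
        "truth_x": os.path.join(outdir, "truth_x.tsv"),
        "config": os.path.join(outdir, "config.json"),
    }
    t = cohort.truth
    write_utr_bed(cohort.utrs, paths["utr_bed"])
    write_matrix(t.counts, paths["counts"])
    write_site_table(t.sites, paths["sites"])
    write_table(t.clinical, paths["clinical"])
    write_labels(t.labels, paths["labels"])
    write_table(t.genes, paths["truth_genes"])
    write_matrix(t.pdui, paths["truth_pdui"])
    write_matrix(t.x_true, paths["truth_x"])
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1, default=list)

    ann = cohort.utrs.table.set_index("gene_id")
    buffers = {s: [] for s in cohort.samples}
    for gene_id, cov in cohort.iter_gene_coverage():
        a = ann.loc[gene_id]
        for s, arr in cov.items():
            genomic = arr[::-1] if a["strand"] == "-" else arr
            buffers[s].extend(
                runs_from_array(genomic, a["chrom"], int(a["utr_start"])))
    for s, records in buffers.items():
        write_bedgraph(records, os.path.join(covdir, f"{s}.bedgraph"))
    log.info("cohort written to %s (%d genes, %d samples)", outdir,
             len(ann), len(cohort.samples))
    return paths


def truth_join(result_table: pd.DataFrame, truth_genes: pd.DataFrame,
               pdui_est: pd.DataFrame | None = None,
               pdui_true: pd.DataFrame | None = None) -> dict:
    """Score a differential-APA result table against the generator's truth.

    Returns the APA-class confusion matrix, sensitivity (truly altered genes
    recovered with the correct direction), empirical FDR among called genes,
    and - when the estimated/true PDUI matrices and fits are supplied - the
    PDUI mean absolute error and the median proximal-PAS breakpoint error.
    """
    res = result_table.set_index("gene_id") if "gene_id" in result_table else result_table
    tg = truth_genes.set_index("gene_id")
    unknown = res.index.difference(tg.index)
    if len(unknown):
        raise ValueError(f"result genes absent from truth: {list(unknown[:5])}")
    common = res.index
    pred = res.loc[common, "apa_class"]
    true = tg.loc[common, "apa_class"]
    confusion = pd.crosstab(true, pred).reindex(
        index=["shortened", "lengthened", "unchanged"],
        columns=["shortened", "lengthened", "unchanged"], fill_value=0)
    altered = true != "unchanged"
    called = pred != "unchanged"
    n_altered = int(altered.sum())
    sensitivity = float((altered & (pred == true)).sum() / n_altered) if n_altered else float("nan")
    n_called = int(called.sum())
    fdr = float((called & ~altered).sum() / n_called) if n_called else 0.0
    out = {"confusion": confusion, "sensitivity": sensitivity,
           "empirical_fdr": fdr, "n_called": n_called, "n_altered": n_altered}
    if pdui_est is not None and pdui_true is not None:
        shared = pdui_est.index.intersection(pdui_true.index)
        cols = pdui_est.columns.intersection(pdui_true.columns)
        err = (pdui_est.loc[shared, cols] - pdui_true.loc[shared, cols]).abs()
        out["pdui_mae"] = float(np.nanmedian(err.to_numpy()))
    if "proximal_offset" in res.columns:
        bp = (res.loc[common, "proximal_offset"] - tg.loc[common, "true_pas"]).abs()
        out["breakpoint_median_error_bp"] = float(np.nanmedian(bp.to_numpy()))
    return out
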