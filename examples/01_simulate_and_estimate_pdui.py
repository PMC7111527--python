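"""Simulate a small tumor/normal cohort and estimate PDUI from coverage.

Builds a 40-gene, 12+12-sample cohort, fits the two-segment coverage model
per gene and compares the fitted proximal PAS and PDUI values against the
generator's ground truth.
"""

import numpy as np
import pandas as pd

from apakit import SimulationConfig, simulate_cohort
from apakit.pdui import build_pdui_matrix, estimate_pdui_gene

cfg = SimulationConfig(n_genes=40, n_tumor=12, n_normal=12, seed=1)
cohort = simulate_cohort(cfg)

fits = [estimate_pdui_gene(cov, gene_id=g)
        for g, cov in cohort.iter_gene_coverage()]
dataset = build_pdui_matrix(fits, cohort.truth.labels,
                            min_samples_per_condition=5)

truth = cohort.truth
common = dataset.pdui.index
mae = float(np.nanmedian(
    (dataset.pdui.loc[common] - truth.pdui.loc[common]).abs().to_numpy()))
bp_err = (dataset.proximal_offset
          - truth.genes.set_index("gene_id").loc[common, "true_pas"]).abs()

print(f"genes fit              : {len(common)} / {cfg.n_genes}")
print(f"median |PDUI error|    : {mae:.4f}")
print(f"median breakpoint error: {bp_err.median():.0f} bp")
# PDUI near truth (error ~ the Poisson noise floor at 50x coverage) and a
# breakpoint within a few bases mean the fitted proximal poly(A) site and
# the long/short-form mixture per sample are trustworthy downstream.
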