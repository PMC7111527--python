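import numpy as np
import pandas as pd
import pytest

from apakit import SimulationConfig, differential_apa, simulate_pdui_dataset
from apakit.formats import ApaDataset, map_sites_to_utr
from apakit.mirna import annotate_site_regions


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized planted cohort (truth-level PDUI, no coverage), shared
    across tests that only need a realistic dataset."""
    ds, cohort = simulate_pdui_dataset(SimulationConfig(seed=11))
    return ds, cohort


@pytest.fixture(scope="session")
def default_results(default_cohort):
    ds, cohort = default_cohort
    return differential_apa(ds)


@pytest.fixture(scope="session")
def default_sites(default_cohort):
    ds, cohort = default_cohort
    mapped = map_sites_to_utr(cohort.truth.sites, cohort.utrs)
    return annotate_site_regions(mapped, ds.proximal_offset)


def make_dataset(pdui: np.ndarray, labels, genes=None, depth: float = 100.0,
                 **kw) -> ApaDataset:
    """Small hand-built dataset; alpha matrices derived from PDUI at a fixed
    depth, matching the generator's construction."""
    pdui = np.asarray(pdui, dtype=float)
    genes = genes or [f"g{i}" for i in range(pdui.shape[0])]
    samples = [f"s{j}" for j in range(pdui.shape[1])]
    labels = pd.Series(list(labels), index=samples)
    frame = pd.DataFrame(pdui, index=genes, columns=samples)
    return ApaDataset(
        pdui=frame, labels=labels,
        alpha_long=frame * depth,
        alpha_short=(1 - frame) * depth,
        **kw,
    )
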