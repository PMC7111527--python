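import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from apakit import SimulationConfig, simulate_pdui_dataset
from apakit.diffapa import (cluster_patients_ward, differential_apa,
                            hit_overlap, per_patient_delta,
                            permutation_threshold_eval, purity_association,
                            utr_change_histogram)

from conftest import make_dataset


def fisher_enumeration(table):
    """Brute-force two-sided Fisher p: sum hypergeometric probabilities of
    all tables with the observed margins no more likely than the observed."""
    (a, b), (c, d) = table
    r1, n = a + b, a + b + c + d
    c1 = a + c
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in support}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


class TestDifferentialApa:
    def test_identical_conditions_are_unchanged(self):
        row = [0.5, 0.5, 0.5, 0.5]
        ds = make_dataset([row], "tumor tumor normal normal".split())
        res = differential_apa(ds)
        assert res.loc[0, "delta_pdui"] == 0.0
        assert res.loc[0, "fisher_p"] == 1.0
        assert res.loc[0, "apa_class"] == "unchanged"

    def test_strong_shift_called_shortened(self):
        ds = make_dataset([[0.3, 0.3, 0.3, 0.6, 0.6, 0.6]],
                          ["tumor"] * 3 + ["normal"] * 3, depth=200.0)
        res = differential_apa(ds)
        assert res.loc[0, "delta_pdui"] == pytest.approx(-0.3)
        assert res.loc[0, "apa_class"] == "shortened"
        assert res.loc[0, "fdr_q"] < 0.01

    def test_fisher_p_matches_enumeration(self):
        table = [[60, 40], [30, 70]]
        assert stats.fisher_exact(table)[1] == pytest.approx(
            fisher_enumeration(table), rel=1e-9)

    def test_label_swap_antisymmetry(self, default_cohort):
        from apakit.formats import ApaDataset
        ds, _ = default_cohort
        res = differential_apa(ds)
        ds_sw = ApaDataset(
            pdui=ds.pdui,
            labels=ds.labels.map({"tumor": "normal", "normal": "tumor"}),
            alpha_long=ds.alpha_long, alpha_short=ds.alpha_short)
        res_sw = differential_apa(ds_sw)
        np.testing.assert_allclose(res_sw["delta_pdui"], -res["delta_pdui"],
                                   atol=1e-12)
        flip = {"shortened": "lengthened", "lengthened": "shortened",
                "unchanged": "unchanged"}
        assert (res_sw["apa_class"] == res["apa_class"].map(flip)).all()

    def test_bh_q_monotone_in_p_rank(self, default_results):
        r = default_results.sort_values("fisher_p")
        assert (np.diff(r["fdr_q"]) >= -1e-12).all()

    def test_threshold_must_be_positive(self, default_cohort):
        with pytest.raises(ValueError, match="threshold"):
            differential_apa(default_cohort[0], threshold=0.0)


class TestPermutationEval:
    def test_permutation_floor(self):
        # one gene with a shift far beyond anything a permutation can reach
        rng = np.random.default_rng(1)
        pdui = np.concatenate([rng.uniform(0.0, 0.1, 15),
                               rng.uniform(0.9, 1.0, 15)])[None, :]
        labels = ["tumor"] * 15 + ["normal"] * 15
        ds = make_dataset(pdui, labels)
        rep = permutation_threshold_eval(ds.pdui, ds.labels, n_perm=200, seed=0)
        p = rep.attrs["p_perm"].iloc[0]
        assert p == pytest.approx(1.0 / 201.0)

    def test_noisy_null_fraction_shrinks_with_threshold(self):
        cfg = SimulationConfig(n_genes=300, n_tumor=20, n_normal=20,
                               fraction_shortened=0, fraction_lengthened=0,
                               fraction_heterogeneous=0, concentration=8.0,
                               prognostic_mirnas=(), seed=7)
        ds, _ = simulate_pdui_dataset(cfg)
        rep = permutation_threshold_eval(ds.pdui, ds.labels, n_perm=500, seed=1)
        fr = rep.set_index("threshold")["frac_padj_gt_05"]
        assert fr[0.05] > fr[0.15]

    def test_single_condition_rejected(self):
        ds = make_dataset([[0.5, 0.5]], ["tumor", "tumor"])
        with pytest.raises(ValueError):
            permutation_threshold_eval(ds.pdui, ds.labels, n_perm=10)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold_eval(ds.pdui, ds.labels, n_perm=0)


class TestPatientDelta:
    def test_patient_minus_normal_mean(self):
        ds = make_dataset([[0.5, np.nan, 0.7, 0.7]],
                          "tumor tumor normal normal".split())
        delta = per_patient_delta(ds.pdui, ds.labels)
        assert delta.loc["g0", "s0"] == pytest.approx(-0.2)
        assert np.isnan(delta.loc["g0", "s1"])

    def test_patients_at_normal_mean_give_zero(self):
        ds = make_dataset([[0.6, 0.6, 0.6, 0.6]],
                          "tumor tumor normal normal".split())
        assert (per_patient_delta(ds.pdui, ds.labels).to_numpy() == 0).all()


class TestWardClustering:
    def test_recovers_planted_patient_blocks(self):
        rng = np.random.default_rng(0)
        block = np.r_[np.full(15, -0.3), np.full(15, 0.3)]
        mat = pd.DataFrame(block[None, :].repeat(20, axis=0)
                           + rng.normal(0, 0.02, (20, 30)),
                           columns=[f"p{j}" for j in range(30)])
        out = cluster_patients_ward(mat, n_col_groups=2)
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, out["col_labels"]) == 1.0

    def test_single_group_request(self):
        mat = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 8)))
        out = cluster_patients_ward(mat, n_col_groups=1)
        assert out["col_labels"].nunique() == 1

    def test_constant_matrix_is_stable(self):
        mat = pd.DataFrame(np.zeros((6, 7)))
        a = cluster_patients_ward(mat, n_col_groups=3)
        b = cluster_patients_ward(mat, n_col_groups=3)
        pd.testing.assert_series_equal(a["col_labels"], b["col_labels"])


class TestPurityAndOverlap:
    def test_purity_identical_series_flagged(self):
        x = pd.Series(np.linspace(0.2, 0.9, 10), index=[f"p{j}" for j in range(10)])
        out = purity_association(x, x)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["flagged"]

    def test_constant_purity_not_flagged(self):
        x = pd.Series(np.linspace(0.2, 0.9, 10), index=[f"p{j}" for j in range(10)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = purity_association(x, pd.Series(0.5, index=x.index))
        assert not out["flagged"]
        assert np.isnan(out["pearson_r"])

    def test_too_few_pairs_raise(self):
        x = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError, match=">=3"):
            purity_association(x, x)

    def test_negative_correlation_not_flagged(self):
        # the printed rule is one-directional: only r > 0.3 flags
        x = pd.Series(np.linspace(0.2, 0.9, 10), index=[f"p{j}" for j in range(10)])
        out = purity_association(x, 1.0 - x)
        assert out["pearson_r"] == pytest.approx(-1.0)
        assert not out["flagged"]

    def test_hit_overlap(self):
        full = pd.DataFrame({"gene_id": ["a", "b", "c"],
                             "apa_class": ["shortened", "lengthened", "unchanged"]})
        assert hit_overlap(full, full) == 1.0
        disjoint = full.assign(apa_class=["unchanged", "unchanged", "shortened"])
        assert hit_overlap(full, disjoint) == 0.0


class TestHistogram:
    def test_change_lands_in_expected_bin(self):
        res = pd.DataFrame({"gene_id": ["a"], "apa_class": ["shortened"],
                            "utr_change_bp": [600.0]})
        h = utr_change_histogram(res)
        row = h[h["bin_start"] == 600].iloc[0]
        assert row["shortened"] == 1
        assert row["bin_end"] == 700

    def test_no_significant_genes_empty(self):
        res = pd.DataFrame({"gene_id": ["a"], "apa_class": ["unchanged"],
                            "utr_change_bp": [600.0]})
        assert utr_change_histogram(res).empty
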