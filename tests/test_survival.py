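import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from apakit.survival import (clinical_design_matrix, clinical_residuals,
                             gmm_clusters, km_logrank, kmeans_cohorts,
                             nested_cox_deviance, select_pdui_features,
                             sis_mirna_features)


def null_clinical(n=200, seed=0):
    """Clinical table whose covariates carry no survival signal."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(500, size=n)
    horizon = 900.0
    return pd.DataFrame({
        "sample_id": [f"T{i:03d}" for i in range(n)],
        "time": np.minimum(t, horizon).clip(min=1).round(),
        "event": (t <= horizon).astype(int),
        "age": rng.normal(65, 8, size=n).round(1),
        "sex": rng.choice(["male", "female"], size=n),
        "race": rng.choice(["white", "black", "asian"], size=n),
        "stage": rng.choice(["I", "II", "III"], size=n),
        "grade": rng.choice(["G1", "G2", "G3"], size=n),
        "residual_tumor": rng.choice(["R0", "R1"], size=n),
        "purity": rng.beta(8, 3, size=n).round(3),
    })


class TestClinicalResiduals:
    def test_martingale_residuals_sum_to_zero(self):
        res = clinical_residuals(null_clinical())
        assert abs(res.sum()) < 1e-6

    def test_null_residuals_uncorrelated_with_covariates(self):
        clin = null_clinical(seed=1)
        res = clinical_residuals(clin)
        design = clinical_design_matrix(clin)
        for col in design.columns:
            r = np.corrcoef(design[col].loc[res.index], res)[0, 1]
            assert abs(r) < 0.1, col

    def test_duplicate_patient_rows_raise(self):
        clin = null_clinical(n=30)
        dup = pd.concat([clin, clin.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            clinical_residuals(dup)

    def test_all_censored_raises(self):
        clin = null_clinical(n=30)
        clin["event"] = 0
        with pytest.raises(ValueError, match="censored"):
            clinical_residuals(clin)


class TestFeatureScreen:
    def test_gene_equal_to_residuals_ranked_first(self):
        clin = null_clinical(n=60, seed=2)
        res = clinical_residuals(clin)
        rng = np.random.default_rng(3)
        pdui = pd.DataFrame(rng.uniform(0, 1, size=(10, len(res))),
                            index=[f"g{i}" for i in range(10)],
                            columns=res.index)
        scaled = (res - res.min()) / (res.max() - res.min())
        pdui.loc["gStar"] = scaled
        top = select_pdui_features(res, pdui, k=5)
        assert top.loc[0, "gene_id"] == "gStar"
        assert top.loc[0, "p"] < 1e-12

    def test_k_exceeding_gene_count_warns_and_returns_all(self):
        clin = null_clinical(n=40, seed=4)
        res = clinical_residuals(clin)
        pdui = pd.DataFrame(np.random.default_rng(5).uniform(size=(3, len(res))),
                            index=["a", "b", "c"], columns=res.index)
        with pytest.warns(UserWarning, match="features"):
            top = select_pdui_features(res, pdui, k=10)
        assert len(top) == 3


class TestKMeansAndLogrank:
    def test_recovers_separated_cohorts(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [6, 0], [0, 6]])
        truth = np.repeat([0, 1, 2], 30)
        X = pd.DataFrame(centers[truth] + rng.normal(0, 0.4, size=(90, 2)),
                         index=[f"p{i}" for i in range(90)])
        out = kmeans_cohorts(X, K=3, n_restarts=10, seed=0)
        assert adjusted_rand_score(truth, out["labels"]) == 1.0
        assert out["stability"] is None  # no survival supplied

    def test_single_cluster_request_rejected(self):
        X = pd.DataFrame(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="K"):
            kmeans_cohorts(X, K=1)

    def test_identical_groups_give_null_logrank(self):
        times = pd.Series([5, 8, 12, 5, 8, 12.0])
        events = pd.Series([1, 1, 0, 1, 1, 0])
        labels = pd.Series([0, 0, 0, 1, 1, 1])
        out = km_logrank(times, events, labels)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0)

    def test_six_patient_example_matches_hand_computation(self):
        # group 0: events at 2, 4; censored 6 / group 1: events at 3, 5, 6
        times = pd.Series([2, 4, 6, 3, 5, 6.0])
        events = pd.Series([1, 1, 0, 1, 1, 1])
        labels = pd.Series([0, 0, 0, 1, 1, 1])
        # from-scratch log-rank: sum over event times of (O1 - E1), variance
        o_minus_e, var = 0.0, 0.0
        for t in sorted(times[events == 1].unique()):
            at_risk = times >= t
            n, n1 = at_risk.sum(), (at_risk & (labels == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (labels == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        out = km_logrank(times, events, labels)
        assert out["chi2"] == pytest.approx(expected_chi2, rel=1e-9)

    def test_logrank_invariant_to_relabeling_and_time_rescaling(self):
        rng = np.random.default_rng(7)
        times = pd.Series(rng.exponential(10, size=40))
        events = pd.Series(rng.integers(0, 2, size=40))
        events.iloc[0] = 1
        labels = pd.Series(rng.integers(0, 3, size=40))
        base = km_logrank(times, events, labels)
        relabeled = km_logrank(times, events, labels.map({0: 7, 1: 5, 2: 9}))
        rescaled = km_logrank(times * 365.0, events, labels)
        assert relabeled["chi2"] == pytest.approx(base["chi2"], rel=1e-9)
        assert rescaled["chi2"] == pytest.approx(base["chi2"], rel=1e-9)

    def test_requires_events_and_groups(self):
        times = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="group"):
            km_logrank(times, pd.Series([1, 1, 1]), pd.Series([0, 0, 0]))
        with pytest.raises(ValueError, match="event"):
            km_logrank(times, pd.Series([0, 0, 0]), pd.Series([0, 1, 1]))


class TestSIS:
    def test_constant_family_excluded(self):
        clin = null_clinical(n=50, seed=8)
        X = pd.DataFrame(
            [np.ones(50), np.random.default_rng(9).uniform(size=50)],
            index=["flat", "varies"], columns=clin["sample_id"])
        out = sis_mirna_features(X, clin, p_screen=1.1)
        assert set(out["mirna_family"]) == {"varies"}

    def test_null_retention_near_screen_level(self):
        clin = null_clinical(n=150, seed=10)
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.uniform(size=(40, 150)),
                         index=[f"f{i}" for i in range(40)],
                         columns=clin["sample_id"])
        out = sis_mirna_features(X, clin, p_screen=0.05)
        assert len(out) <= 0.05 * 40 + 2 * np.sqrt(40 * 0.05 * 0.95) + 1


class TestGMMAndDeviance:
    def test_single_spherical_cluster_chooses_k_one(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(120, 2)),
                         index=[f"p{i}" for i in range(120)])
        out = gmm_clusters(X, max_k=4, seed=0)
        assert out["chosen_k"] == 1

    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(13)
        centers = np.array([[0, 0], [5, 0], [0, 5]])
        truth = np.repeat([0, 1, 2], 40)
        X = pd.DataFrame(centers[truth] + rng.normal(0, 0.5, size=(120, 2)))
        out = gmm_clusters(X, max_k=5, seed=0)
        assert out["chosen_k"] == 3
        assert adjusted_rand_score(truth, out["labels"]) == 1.0
        assert out["embedding"].shape == (120, 2)

    def test_max_k_one_is_trivial(self):
        X = pd.DataFrame(np.random.default_rng(14).normal(size=(15, 2)))
        out = gmm_clusters(X, max_k=1, seed=0)
        assert out["chosen_k"] == 1
        assert out["labels"].nunique() == 1

    def test_deviance_zero_when_labels_nested_in_covariate(self):
        clin = null_clinical(n=120, seed=15)
        labels = pd.Series((clin["sex"] == "male").astype(int).to_numpy(),
                           index=clin["sample_id"])
        out = nested_cox_deviance(clin, labels)
        assert out["chi2"] >= 0.0
        assert out["chi2"] == pytest.approx(0.0, abs=1e-3)

    def test_planted_cluster_effect_detected(self):
        rng = np.random.default_rng(16)
        n = 200
        group = rng.integers(0, 2, size=n)
        t = rng.exponential(500 * np.exp(-0.8 * group))
        clin = null_clinical(n=n, seed=17)
        clin["time"] = np.minimum(t, 900).clip(min=1).round()
        clin["event"] = (t <= 900).astype(int)
        labels = pd.Series(group, index=clin["sample_id"])
        out = nested_cox_deviance(clin, labels, reference_cluster=0)
        assert out["p"] < 0.01
        assert out["hazard_ratios"]["cluster[1]"] > 1.5
        assert out["df"] == 1
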