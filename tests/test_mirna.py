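import numpy as np
import pandas as pd
import pytest

from apakit.formats import ApaDataset
from apakit.mirna import (annotate_site_regions, build_form_abundance,
                          count_conserved_site_loss, family_zscores,
                          mirna_loss_matrix)

from conftest import make_dataset


def site_rows(rows):
    return pd.DataFrame(rows, columns=["mirna_family", "gene_id",
                                       "utr_offset_start", "utr_offset_end",
                                       "cwcs", "conserved"])


def apa_rows(rows):
    return pd.DataFrame(rows, columns=["gene_id", "apa_class",
                                       "proximal_offset"])


class TestSiteLossCounting:
    def test_sites_beyond_breakpoint_are_lost(self):
        apa = apa_rows([("gA", "shortened", 400.0), ("gB", "shortened", 400.0),
                        ("gC", "unchanged", 300.0)])
        sites = site_rows([
            ("m1", "gA", 500, 507, -0.3, True),
            ("m2", "gA", 800, 807, -0.2, True),
            ("m1", "gB", 100, 107, -0.3, True),   # before P: retained
            ("m1", "gC", 900, 907, -0.4, True),   # unchanged gene: ignored
        ])
        out = count_conserved_site_loss(apa, sites)
        assert out["per_gene"]["gA"] == 2
        assert out["per_gene"]["gB"] == 0
        assert "gC" not in out["per_gene"].index
        assert out["fraction_with_loss"] == 0.5

    def test_unconserved_sites_do_not_count(self):
        apa = apa_rows([("gA", "shortened", 400.0)])
        sites = site_rows([("m1", "gA", 500, 507, -0.3, False)])
        out = count_conserved_site_loss(apa, sites)
        assert out["per_gene"]["gA"] == 0


def toy_zscore_inputs():
    """20 genes, 5 families; family fam_lost sits exclusively beyond the
    breakpoints of strongly shortened genes."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(20)]
    apa = apa_rows([(g, "shortened", 400.0) for g in genes])
    rows = []
    for g in genes:
        rows.append(("fam_lost", g, int(rng.integers(420, 900)), 0, -0.5, True))
        for fam in ("famA", "famB", "famC", "famD"):
            rows.append((fam, g, int(rng.integers(0, 390)), 0, -0.3, True))
    sites = site_rows([(f, g, s, s + 7, c, b) for f, g, s, _, c, b in rows])
    ab = pd.DataFrame({
        "long_tumor": 0.2, "short_tumor": 0.8,
        "long_normal": 0.7, "short_normal": 0.3,
    }, index=pd.Index(genes))
    return apa, sites, ab


def brute_force_zscores(apa, sites, ab, permutations):
    """Loop-based reference scorer sharing the caller's permutation stream."""
    shortened = set(apa.loc[apa["apa_class"] == "shortened", "gene_id"])
    P = apa.set_index("gene_id")["proximal_offset"]
    use = sites[sites["conserved"] & sites["gene_id"].isin(shortened)].reset_index(drop=True)
    fams = sorted(use["mirna_family"].unique())

    def weight(row, cond):
        a = ab.loc[row["gene_id"]]
        distal = row["utr_offset_start"] >= P[row["gene_id"]]
        form = a[f"long_{cond}"] if distal else a[f"long_{cond}"] + a[f"short_{cond}"]
        return abs(row["cwcs"]) * form

    def fold(fam_of_site):
        out = {}
        for fam in fams:
            st = sum(weight(use.iloc[i], "tumor")
                     for i in range(len(use)) if fam_of_site[i] == fam)
            sn = sum(weight(use.iloc[i], "normal")
                     for i in range(len(use)) if fam_of_site[i] == fam)
            out[fam] = st / sn if sn > 0 else np.nan
        return out

    observed = fold(list(use["mirna_family"]))
    perms = []
    base = list(use["mirna_family"])
    for perm in permutations:
        perms.append(fold([base[j] for j in perm]))
    rows = []
    for fam in fams:
        vals = np.array([p[fam] for p in perms], dtype=float)
        m, s = np.nanmean(vals), np.nanstd(vals, ddof=1)
        rows.append(dict(mirna_family=fam, fold_change=observed[fam],
                         perm_mean=m, perm_sd=s, z=(observed[fam] - m) / s))
    return pd.DataFrame(rows)


class TestFamilyZScores:
    def test_dual_implementation_agrees_at_machine_precision(self):
        """Vectorized scorer vs an independent loop-based scorer consuming
        the identical permutation stream: agreement to rounding error."""
        apa, sites, ab = toy_zscore_inputs()
        sites = annotate_site_regions(sites, apa.set_index("gene_id")["proximal_offset"])
        rng = np.random.default_rng(42)
        perms = np.array([rng.permutation(len(sites)) for _ in range(200)])
        ours = family_zscores(apa, sites, ab, permutations=perms)
        ref = brute_force_zscores(apa, sites, ab, perms)
        merged = ours.merge(ref, on="mirna_family", suffixes=("", "_ref"))
        for col in ("fold_change", "perm_mean", "perm_sd", "z"):
            np.testing.assert_allclose(merged[col].to_numpy(),
                                       merged[f"{col}_ref"].to_numpy(),
                                       rtol=1e-12)

    def test_planted_lost_family_attains_minimum_z(self):
        apa, sites, ab = toy_zscore_inputs()
        sites = annotate_site_regions(sites, apa.set_index("gene_id")["proximal_offset"])
        out = family_zscores(apa, sites, ab, n_perm=500, seed=1)
        assert out.loc[out["z"].idxmin(), "mirna_family"] == "fam_lost"

    def test_single_family_degenerate_null_flagged(self):
        apa = apa_rows([("gA", "shortened", 400.0)])
        sites = annotate_site_regions(
            site_rows([("m1", "gA", 500, 507, -0.3, True)]),
            apa.set_index("gene_id")["proximal_offset"])
        ab = pd.DataFrame({"long_tumor": [0.2], "short_tumor": [0.8],
                           "long_normal": [0.7], "short_normal": [0.3]},
                          index=["gA"])
        out = family_zscores(apa, sites, ab, n_perm=50, seed=0)
        assert not out.loc[0, "z_defined"]
        assert np.isnan(out.loc[0, "z"])

    def test_z_invariant_to_abundance_rescaling(self):
        apa, sites, ab = toy_zscore_inputs()
        sites = annotate_site_regions(sites, apa.set_index("gene_id")["proximal_offset"])
        a = family_zscores(apa, sites, ab, n_perm=200, seed=3)
        b = family_zscores(apa, sites, ab * 37.5, n_perm=200, seed=3)
        np.testing.assert_allclose(a["z"], b["z"], rtol=1e-9)


class TestLossMatrix:
    def _inputs(self, pdui):
        ds = make_dataset(pdui, ["tumor"] * pdui.shape[1])
        apa = apa_rows([(g, "shortened", 100.0) for g in ds.pdui.index])
        sites = site_rows([("m1", g, 200, 207, -0.3, True)
                           for g in ds.pdui.index])
        sites = annotate_site_regions(sites, apa.set_index("gene_id")["proximal_offset"])
        return ds, apa, sites

    def test_all_distal_usage_gives_zero(self):
        ds, apa, sites = self._inputs(np.ones((3, 4)))
        out = mirna_loss_matrix(ds, apa, sites)
        assert (out["X"].to_numpy() == 0).all()

    def test_direct_arithmetic_on_formula(self):
        ds, apa, sites = self._inputs(np.full((2, 1), 0.4))
        out = mirna_loss_matrix(ds, apa, sites)
        assert out["X"].iloc[0, 0] == pytest.approx(1.2)

    def test_matches_triple_loop_on_random_inputs(self):
        rng = np.random.default_rng(5)
        pdui = rng.uniform(0, 1, size=(15, 8))
        pdui[rng.random(pdui.shape) < 0.1] = np.nan
        ds = make_dataset(np.nan_to_num(pdui, nan=0.5),
                          ["tumor"] * 8)  # placeholder to get ids
        ds.pdui.iloc[:, :] = pdui
        apa = apa_rows([(g, "shortened", 100.0) for g in ds.pdui.index])
        rows = []
        for g in ds.pdui.index:
            for fam in rng.choice(["m1", "m2", "m3"],
                                  size=rng.integers(0, 3), replace=False):
                rows.append((fam, g, 150, 157, -0.4, True))
        if not rows:
            rows.append(("m1", ds.pdui.index[0], 150, 157, -0.4, True))
        sites = annotate_site_regions(site_rows(rows),
                                      apa.set_index("gene_id")["proximal_offset"])
        out = mirna_loss_matrix(ds, apa, sites)
        A = out["A"]
        for fam in A.index:
            for i, s in enumerate(ds.pdui.columns):
                expected = sum(
                    (1 - pdui[gi, i]) * A.loc[fam, g]
                    for gi, g in enumerate(ds.pdui.index)
                    if np.isfinite(pdui[gi, i]))
                assert out["X"].loc[fam, s] == pytest.approx(expected, abs=1e-12)

    def test_family_without_targets_gives_zero_row(self):
        ds, apa, sites = self._inputs(np.full((2, 3), 0.5))
        sites.loc[sites["gene_id"] == ds.pdui.index[1], "conserved"] = False
        out = mirna_loss_matrix(ds, apa, sites)
        assert out["A"].loc["m1", ds.pdui.index[1]] == 0
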