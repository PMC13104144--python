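import numpy as np
import pandas as pd
import pytest

from plastevo.coexpression import (
    _scale_free_r2,
    compute_tom,
    detect_modules,
    export_network,
    hub_genes,
    make_trait_table,
    module_eigengene,
    module_trait_stats,
    pick_soft_threshold,
)


def tom_oracle(em_values, beta):
    """Hand-evaluated TOM formula with explicit loops."""
    r = np.corrcoef(em_values)
    n = r.shape[0]
    a = np.abs(r) ** beta
    for i in range(n):
        a[i, i] = 0.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            k_i = sum(a[i, u] for u in range(n))
            k_j = sum(a[j, u] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
    return tom


class TestTOM:
    def test_three_gene_toy_matches_hand_arithmetic(self):
        em = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.1, 2.0, 2.9, 4.2], [4.0, 1.0, 3.0, 2.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"],
        )
        tom, dis = compute_tom(em, beta=2)
        expected = tom_oracle(em.to_numpy(), 2)
        np.testing.assert_allclose(tom.to_numpy(), expected, atol=1e-9)
        np.testing.assert_allclose(dis.to_numpy(), 1 - expected, atol=1e-9)

    def test_perfectly_correlated_pair_with_identical_neighbors(self):
        # two genes that are exact scalar copies: a = 1 and no third
        # neighbor, so the formula collapses to TOM = 1
        em = pd.DataFrame(
            [[1.0, 2.0, 5.0, 3.0], [2.0, 4.0, 10.0, 6.0]], index=["a", "b"],
            columns=list("wxyz"),
        )
        tom, _ = compute_tom(em, beta=6)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_invariants_on_random_input(self, rng):
        em = pd.DataFrame(rng.normal(size=(40, 12)))
        em.columns = [f"s{i}" for i in range(12)]
        tom, dis = compute_tom(em, beta=6)
        t = tom.to_numpy()
        assert np.allclose(t, t.T)
        assert (t >= 0).all() and (t <= 1).all()
        np.testing.assert_allclose(np.diag(t), 1.0)
        np.testing.assert_allclose(np.diag(dis.to_numpy()), 0.0)

    def test_independent_genes_have_small_overlap(self, rng):
        em = pd.DataFrame(rng.normal(size=(60, 100)))
        em.columns = [f"s{i}" for i in range(100)]
        tom, _ = compute_tom(em, beta=6)
        off = tom.to_numpy()[~np.eye(60, dtype=bool)]
        assert np.median(off) < 0.05

    def test_constant_gene_dropped_with_warning(self, rng):
        em = pd.DataFrame(rng.normal(size=(5, 8)))
        em.columns = [f"s{i}" for i in range(8)]
        em.iloc[2] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            tom, _ = compute_tom(em, beta=2)
        assert tom.shape == (4, 4)


class TestSoftThreshold:
    def test_power_law_degrees_fit_well(self, rng):
        # degree sequence drawn from a discrete power law: the log-log
        # frequency fit must be close to linear with negative slope
        k = np.round(rng.pareto(2.0, 3000) * 5 + 1)
        assert _scale_free_r2(k) > 0.8

    def test_uniform_degrees_fit_poorly(self, rng):
        k = rng.uniform(10, 12, 3000)
        assert _scale_free_r2(k) < 0.5

    def test_independent_genes_trigger_argmax_fallback(self, rng):
        em = pd.DataFrame(rng.normal(size=(200, 20)))
        em.columns = [f"s{i}" for i in range(20)]
        power, table = pick_soft_threshold(em, powers=range(1, 7))
        assert (table["sft_r2"] < 0.8).all()
        assert power == int(table.loc[table["sft_r2"].idxmax(), "power"])

    def test_needs_three_candidates(self, rng):
        em = pd.DataFrame(rng.normal(size=(10, 5)))
        em.columns = [f"s{i}" for i in range(5)]
        with pytest.raises(ValueError):
            pick_soft_threshold(em, powers=[1, 2])

    def test_selection_contract(self, small_sim):
        # smallest power reaching the target when one exists, else argmax
        from plastevo.expression import normalize, tmm_factors

        cfg, counts, samples, truth = small_sim
        em = normalize(counts, tmm_factors(counts), log=True)
        power, table = pick_soft_threshold(em, powers=range(1, 15))
        reaching = table.loc[table["sft_r2"] >= 0.8, "power"]
        if len(reaching):
            assert power == reaching.iloc[0]
        else:
            assert power == int(table.loc[table["sft_r2"].idxmax(), "power"])


class TestDetectModules:
    def make_blocks(self, rng, n_noise=100, block=50, n_samples=18, rho_latent=0.0):
        z1 = rng.normal(size=n_samples)
        e = rng.normal(size=n_samples)
        z2 = rho_latent * z1 + np.sqrt(1 - rho_latent**2) * e
        rows = []
        for _ in range(block):
            rows.append(z1 * rng.uniform(0.8, 1.2) + rng.normal(0, 0.3, n_samples))
        for _ in range(block):
            rows.append(z2 * rng.uniform(0.8, 1.2) + rng.normal(0, 0.3, n_samples))
        for _ in range(n_noise):
            rows.append(rng.normal(size=n_samples))
        em = pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * block + n_noise)])
        em.columns = [f"s{i}" for i in range(n_samples)]
        return em

    def test_two_orthogonal_blocks_recovered(self, rng):
        em = self.make_blocks(rng)
        tom, _ = compute_tom(em, beta=6)
        labels, mes = detect_modules(tom, em, min_size=30)
        modules = [m for m in labels.unique() if m != "grey"]
        assert len(modules) == 2
        b1 = labels.iloc[:50]
        b2 = labels.iloc[50:100]
        assert (b1 == b1.mode()[0]).mean() >= 0.95
        assert (b2 == b2.mode()[0]).mean() >= 0.95
        assert b1.mode()[0] != b2.mode()[0]

    def test_highly_correlated_blocks_merge(self, rng):
        # eigengene correlation ~0.95 -> dissimilarity < 0.25 merges them
        em = self.make_blocks(rng, rho_latent=0.95, n_noise=20)
        tom, _ = compute_tom(em, beta=6)
        labels, mes = detect_modules(tom, em, min_size=30, merge_threshold=0.25)
        modules = [m for m in labels.unique() if m != "grey"]
        assert len(modules) == 1

    def test_min_size_larger_than_blocks_gives_all_grey(self, rng):
        em = self.make_blocks(rng, n_noise=20)
        tom, _ = compute_tom(em, beta=6)
        with pytest.warns(UserWarning, match="grey"):
            labels, mes = detect_modules(tom, em, min_size=60)
        assert (labels == "grey").all()
        assert mes.empty

    def test_labels_invariant_under_gene_permutation(self, rng):
        em = self.make_blocks(rng, n_noise=40)
        tom, _ = compute_tom(em, beta=6)
        labels, _ = detect_modules(tom, em, min_size=30)
        perm = rng.permutation(len(em))
        em_p, tom_p = em.iloc[perm], tom.iloc[perm, perm]
        labels_p, _ = detect_modules(tom_p, em_p, min_size=30)
        # same partition: module of each gene maps one-to-one
        joined = pd.DataFrame({"a": labels.sort_index(), "b": labels_p.sort_index()})
        mapping = joined.groupby("a")["b"].nunique()
        assert (mapping == 1).all()

    def test_eigengene_first_pc_optimality(self, rng):
        em = self.make_blocks(rng, n_noise=0)
        genes = em.index[:50]
        me = module_eigengene(em, genes)
        x = em.loc[genes].to_numpy()
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        var_me = ((x @ me.to_numpy() / np.linalg.norm(me)) ** 2).sum()
        for row in x:
            unit = row / np.linalg.norm(row)
            assert var_me >= ((x @ unit) ** 2).sum() - 1e-8


class TestTraitStats:
    def test_eigengene_equal_to_negative_ctmin_selected(self, rng):
        n = 20
        me = rng.normal(size=n)
        em = pd.DataFrame(
            [me + rng.normal(0, 0.01, n) for _ in range(10)],
            index=[f"g{i}" for i in range(10)],
        )
        em.columns = [f"s{i}" for i in range(n)]
        traits = pd.DataFrame({"CT_min": -me, "CT_max": rng.normal(size=n)},
                              index=em.columns)
        labels = pd.Series("turquoise", index=em.index)
        mes = pd.DataFrame({"turquoise": me}, index=em.columns)
        st = module_trait_stats(em, labels, mes, traits)
        assert st["module_trait_r"].loc["turquoise", "CT_min"] == pytest.approx(-1.0)
        assert bool(st["selected"].loc["turquoise", "cold_tolerance"])

    def test_permutation_calibration_of_selection_rate(self, rng):
        n = 20
        me = rng.normal(size=n)
        hits = 0
        n_perm = 1000
        from scipy import stats as sps

        for _ in range(n_perm):
            perm = rng.permutation(n)
            r, p = sps.pearsonr(me, me[perm])
            hits += p < 0.05
        assert 0.03 <= hits / n_perm <= 0.07

    def test_zero_variance_trait_rejected(self, rng):
        em = pd.DataFrame(rng.normal(size=(5, 8)))
        em.columns = [f"s{i}" for i in range(8)]
        traits = pd.DataFrame({"CT_min": np.ones(8)}, index=em.columns)
        labels = pd.Series("blue", index=em.index)
        mes = pd.DataFrame({"blue": rng.normal(size=8)}, index=em.columns)
        with pytest.raises(ValueError, match="zero-variance"):
            module_trait_stats(em, labels, mes, traits)

    def test_make_trait_table_binary_coding(self):
        meta = pd.DataFrame(
            {
                "region": ["S", "N", "N"],
                "acclimation": ["CK", "Cold", "Warm"],
            },
            index=["a", "b", "c"],
        )
        tt = make_trait_table(meta)
        assert list(tt["Region"]) == [0.0, 1.0, 1.0]
        assert list(tt["Normal"]) == [1.0, 0.0, 0.0]
        assert list(tt["Cold"]) == [0.0, 1.0, 0.0]
        assert list(tt["Warm"]) == [0.0, 0.0, 1.0]


class TestHubsAndExport:
    def make_stats(self):
        genes = pd.Index(["a", "b", "c", "d"])
        labels = pd.Series(["blue"] * 3 + ["grey"], index=genes)
        mm = pd.DataFrame({"blue": [0.9, 0.8, 0.95, 0.1]}, index=genes)
        gs = pd.DataFrame({"CT_min": [0.85, 0.9, 0.8, 0.2]}, index=genes)
        return {"labels": labels, "MM": mm, "GS": gs}

    def test_strict_inequalities(self):
        # b has MM exactly 0.8, c has GS exactly 0.8: both excluded
        hubs = hub_genes(self.make_stats(), "blue")
        assert list(hubs) == ["a"]

    def test_empty_module_empty_hub_set(self):
        assert len(hub_genes(self.make_stats(), "red")) == 0

    def test_export_network_respects_tom_cut(self):
        tom = pd.DataFrame(
            [[1.0, 0.5, 0.05], [0.5, 1.0, 0.09], [0.05, 0.09, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        edges = export_network(tom, ["a", "b", "c"], tom_cut=0.08)
        pairs = set(map(tuple, edges[["source", "target"]].to_numpy()))
        assert pairs == {("a", "b"), ("b", "c")}
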