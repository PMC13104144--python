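import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from plastevo.expression import (
    cpm,
    filter_low_expression,
    normalize,
    pca,
    tmm_factors,
)


class TestFilterLowExpression:
    def test_gene_above_threshold_everywhere_kept(self):
        counts = pd.DataFrame(
            {"s1": [500, 0], "s2": [500, 0]}, index=["hi", "zero"]
        )
        kept = filter_low_expression(counts)
        assert "hi" in kept.index and "zero" not in kept.index

    def test_exactly_half_low_is_removed(self):
        # gene "edge" has CPM >= 1 in exactly 2 of 4 samples: the "at least
        # half below threshold" wording removes it
        lib = 1_000_000
        counts = pd.DataFrame(
            {
                "s1": [lib - 2, 2],
                "s2": [lib - 2, 2],
                "s3": [lib, 0],
                "s4": [lib, 0],
            },
            index=["filler", "edge"],
        )
        kept = filter_low_expression(counts, cpm_threshold=1.0, min_fraction=0.5)
        assert "edge" not in kept.index

    def test_matches_bruteforce_cpm_table(self, toy_counts):
        kept = filter_low_expression(toy_counts, cpm_threshold=1.0, min_fraction=0.5)
        lib = toy_counts.sum(axis=0)
        expected = []
        for g in toy_counts.index:
            n_ok = sum(
                toy_counts.loc[g, s] / lib[s] * 1e6 >= 1.0 for s in toy_counts.columns
            )
            if n_ok > 0.5 * toy_counts.shape[1]:
                expected.append(g)
        assert list(kept.index) == expected

    def test_idempotent(self, toy_counts):
        once = filter_low_expression(toy_counts)
        twice = filter_low_expression(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_removed_is_loud(self):
        counts = pd.DataFrame({"s1": [1, 1], "s2": [10_000_000, 10_000_000]})
        with pytest.raises(ValueError, match="every gene"):
            filter_low_expression(counts, cpm_threshold=1e6)

    def test_preserves_gene_order(self, toy_counts):
        kept = filter_low_expression(toy_counts)
        assert list(kept.index) == [g for g in toy_counts.index if g in kept.index]


def tmm_oracle_pair(obs, ref):
    """Independent step-by-step evaluation of the trim-and-weight recipe,
    written with explicit sorting rather than rank arithmetic."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    n_obs, n_ref = obs.sum(), ref.sum()
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    from scipy.stats import rankdata

    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 2.0**f


class TestTMM:
    def test_identical_samples_factor_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.factors, 1.0)

    def test_scalar_depth_difference_factor_one(self):
        a = np.array([11, 25, 30, 47, 120])
        counts = pd.DataFrame({"a": a, "b": 3 * a})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.factors, 1.0, atol=1e-12)

    def test_eight_gene_worked_example_matches_oracle(self):
        # one inflated gene in sample b; factor computed independently above
        a = np.array([100, 200, 300, 400, 500, 150, 250, 350])
        b = np.array([100, 200, 300, 400, 500, 150, 250, 9000])
        counts = pd.DataFrame({"a": a, "b": b})
        f = tmm_factors(counts, ref="a")
        raw_b = tmm_oracle_pair(b, a)
        # factors are rescaled to geometric mean one from (1, raw_b)
        expected_b = raw_b / np.sqrt(raw_b)
        expected_a = 1.0 / np.sqrt(raw_b)
        assert f.factors["b"] == pytest.approx(expected_b, abs=1e-6)
        assert f.factors["a"] == pytest.approx(expected_a, abs=1e-6)

    def test_near_invariant_to_scaling_one_sample(self, rng):
        # the M ratios and both trims are exactly unchanged by a scalar
        # depth change; only the precision weights shift, so the factors
        # move by at most a small amount
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(50, 4)), columns=list("abcd")
        )
        f1 = tmm_factors(counts, ref="a")
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 7
        f2 = tmm_factors(scaled, ref="a")
        np.testing.assert_allclose(f1.factors, f2.factors, rtol=0.02)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 800, size=(80, 5)))
        counts.columns = [f"s{i}" for i in range(5)]
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_matches_edger_calcnormfactors(self, rng, tmp_path):
        counts = pd.DataFrame(
            rng.integers(0, 2000, size=(120, 4)),
            index=[f"g{i}" for i in range(120)],
            columns=[f"s{i}" for i in range(4)],
        )
        counts.iloc[:5, 0] *= 30  # some composition bias
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(edgeR))
                x <- as.matrix(read.delim("{path}", row.names = 1))
                f <- calcNormFactors(x, method = "TMM")
                cat(sprintf("%.10f\\n", f))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        got = tmm_factors(counts).factors.to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-6)


class TestNormalize:
    def test_direct_formula(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(5, 3)), columns=["a", "b", "c"]
        )
        f = tmm_factors(counts)
        em = normalize(counts, f)
        eff = counts.sum(axis=0) * f.factors
        for s in counts.columns:
            np.testing.assert_allclose(em[s], counts[s] / eff[s] * 1e6)

    def test_cpm_ten_in_million(self):
        counts = pd.DataFrame({"a": [10, 1_000_000 - 10], "b": [10, 999_990]})
        em = normalize(counts)
        assert em.iloc[0, 0] == pytest.approx(10.0)

    def test_log_of_zero_with_unit_pseudocount(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 100]})
        em = normalize(counts, log=True, pseudocount=1.0)
        assert em.iloc[0, 0] == pytest.approx(0.0)

    def test_column_sums_are_one_million_without_factors(self, toy_counts):
        em = normalize(toy_counts)
        np.testing.assert_allclose(em.sum(axis=0), 1e6, rtol=1e-9)


class TestPCA:
    def test_two_blocks_separate_on_pc1(self, rng):
        base = rng.normal(8, 1, 100)
        block = np.r_[np.zeros(50), np.ones(50) * 4]
        data = {}
        for i in range(6):
            shift = block if i < 3 else -block
            data[f"s{i}"] = base + shift + rng.normal(0, 0.2, 100)
        em = pd.DataFrame(data)
        scores, _, var = pca(em, 2)
        group = scores["PC1"].to_numpy()
        assert var[0] > 0.5
        assert (group[:3] > 0).all() != (group[3:] > 0).all()  # separated

    def test_duplicated_sample_identical_scores(self, rng):
        em = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        em["e"] = em["a"]
        scores, _, _ = pca(em, 2)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["e"], atol=1e-10)

    def test_score_orthogonality(self, rng):
        em = pd.DataFrame(rng.normal(size=(40, 8)))
        em.columns = [f"s{i}" for i in range(8)]
        scores, _, _ = pca(em, 3)
        s = scores.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(np.dot(s[:, i], s[:, j])) < 1e-8

    def test_constant_matrix_rejected(self):
        em = pd.DataFrame(np.ones((10, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            pca(em, 2)
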