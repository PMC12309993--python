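"""NB-GLM differential expression: filtering, normalization, inference."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import compshift as cs


def counts_frame(arr, genes=None):
    arr = np.atleast_2d(np.asarray(arr))
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cols)


class TestFilterGenes:
    def test_boundary_counts(self):
        counts = counts_frame([
            [11, 11, 11, 11, 0, 0],   # kept: four samples above 10
            [10, 10, 10, 10, 10, 10],  # dropped: strict inequality
            [50, 50, 50, 0, 0, 0],     # dropped: only three samples
        ])
        kept = cs.filter_genes(counts)
        assert kept.index.tolist() == ["g0"]

    def test_toy_matrix_against_hand_enumeration(self):
        rng = np.random.default_rng(0)
        counts = counts_frame(rng.integers(0, 30, size=(6, 8)))
        expected = [g for g in counts.index
                    if sum(v > 10 for v in counts.loc[g]) >= 4]
        assert cs.filter_genes(counts).index.tolist() == expected

    def test_nothing_surviving_raises(self):
        with pytest.raises(ValueError, match="filter"):
            cs.filter_genes(counts_frame([[1, 1, 1, 1]]))


class TestSizeFactors:
    def test_identical_columns_are_unit(self):
        counts = counts_frame([[10, 10], [20, 20], [5, 5]])
        assert np.allclose(cs.size_factors(counts), 1.0)

    def test_doubled_column_doubles_factor(self):
        c1 = np.array([10, 20, 40, 5])
        counts = counts_frame(np.column_stack([c1, 2 * c1]))
        sf = cs.size_factors(counts)
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)

    def test_three_by_three_matches_hand_computation(self):
        counts = counts_frame([[4, 8, 16], [9, 3, 27], [25, 5, 5]])
        expected = []
        C = counts.to_numpy(float)
        geo = np.exp(np.log(C).mean(axis=1))
        for j in range(3):
            expected.append(np.median(C[:, j] / geo))
        assert np.allclose(cs.size_factors(counts), expected)

    def test_matches_independent_deseq_implementation(self):
        from pydeseq2.dds import DeseqDataSet
        rng = np.random.default_rng(1)
        counts = counts_frame(rng.poisson(60, size=(50, 6)))
        lib = rng.uniform(0.5, 2.0, size=6)
        counts = (counts * lib).round().astype(int)
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.fit_size_factors()
        assert np.allclose(cs.size_factors(counts),
                           dds.obs["size_factors"], rtol=1e-6)

    def test_fallback_when_no_gene_always_positive(self):
        counts = counts_frame([[10, 0], [0, 10]])
        with pytest.warns(UserWarning, match="library-size"):
            sf = cs.size_factors(counts)
        assert np.allclose(sf, 1.0)


def brute_force_bh(p):
    """Independent BH oracle: padj_(i) = min over j>=i of m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [min(1.0, m * p[order[j]] / (j + 1))
                      for j in range(rank_pos, m)]
        adj[idx] = min(candidates)
    return adj


class TestBHAdjust:
    def test_equal_pvalues_unchanged(self):
        assert np.allclose(cs.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_step_up(self):
        assert np.allclose(cs.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_pvalue_identity(self):
        assert cs.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_passthrough(self):
        out = cs.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], brute_force_bh([0.01, 0.04]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_enumeration_and_statsmodels(self, p):
        ours = cs.bh_adjust(p)
        assert np.allclose(ours, brute_force_bh(p), atol=1e-12)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


class TestFitDE:
    def _two_group(self, n=8):
        groups = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2),
                           index=[f"s{j}" for j in range(n)])
        return cs.cell_means_design(groups, "A")

    def test_high_count_log2fc_matches_normalized_mean_ratio(self):
        # Poisson limit: the group contrast is log2 of the ratio of
        # size-factor-normalized means
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.poisson(5000, 4), rng.poisson(10000, 4)])
        counts = counts_frame([y, rng.poisson(3000, 8)])
        X, contrasts = self._two_group()
        X.index = counts.columns
        res = cs.fit_de(counts, X, contrasts)
        sf = res.size_factors.to_numpy()
        norm = y / sf
        expected = np.log2(norm[4:].mean() / norm[:4].mean())
        assert res.results["B"].loc["g0", "log2FC"] == pytest.approx(
            expected, abs=1e-3)

    def test_matches_statsmodels_poisson_on_equicounts(self):
        # dispersion collapses to the Poisson boundary on Poisson data;
        # coefficients then agree with a statsmodels Poisson GLM
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.poisson(800, 4), rng.poisson(1600, 4)])
        counts = counts_frame([y])
        X, contrasts = self._two_group()
        X.index = counts.columns
        sf = pd.Series(1.0, index=counts.columns)
        res = cs.fit_de(counts, X, contrasts, sf=sf)
        glm = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson()).fit()
        ours = res.results["B"].loc["g0", "log2FC"] * np.log(2)
        theirs = glm.params[1] - glm.params[0]
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_twofold_change_recovered_within_three_se(self):
        rng = np.random.default_rng(4)
        mu = np.array([500] * 4 + [1000] * 4)
        counts = counts_frame(rng.poisson(mu).reshape(1, 8))
        X, contrasts = self._two_group()
        X.index = counts.columns
        res = cs.fit_de(counts, X, contrasts,
                        sf=pd.Series(1.0, index=counts.columns))
        row = res.results["B"].loc["g0"]
        assert abs(row["log2FC"] - 1.0) < 3 * row["lfcSE"]

    def test_orthogonal_covariate_leaves_group_estimates_unchanged(self):
        y = np.array([50, 50, 50, 50, 80, 80, 80, 80])
        counts = counts_frame([y, y * 2])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
        cov = pd.DataFrame({"c": [1, -1, 1, -1, 2, -2, 2, -2]},
                           index=counts.columns, dtype=float)
        X0, contrasts0 = cs.cell_means_design(groups, "A")
        X1, contrasts1 = cs.cell_means_design(groups, "A", cov)
        sf = pd.Series(1.0, index=counts.columns)
        r0 = cs.fit_de(counts, X0, contrasts0, sf=sf)
        r1 = cs.fit_de(counts, X1, contrasts1, sf=sf)
        assert np.allclose(r0.results["B"]["log2FC"],
                           r1.results["B"]["log2FC"], atol=1e-6)

    def test_rank_deficient_design_raises(self):
        counts = counts_frame([[20, 30, 25, 40]])
        X = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [2.0, 2, 2, 2]},
                         index=counts.columns)
        with pytest.raises(ValueError, match="rank"):
            cs.fit_de(counts, X)

    def test_null_pvalues_approximately_uniform(self, fixture_reference):
        d = cs.MixtureDesign(n_replicates=8, seed=31)
        truth = cs.simulate_experiment(fixture_reference, d, conditions=[0.50])
        counts = cs.filter_genes(truth.bulk_counts)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
        X, contrasts = cs.cell_means_design(groups, "A")
        res = cs.fit_de(counts, X, contrasts)
        p = res.results["B"]["pvalue"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.001


class TestCompareModels:
    def test_none_representation_equals_plain_fit(self, fixture_reference):
        d = cs.MixtureDesign(n_replicates=3, total_reads=30_000, seed=9)
        truth = cs.simulate_experiment(fixture_reference, d,
                                       conditions=[0.45, 0.50])
        counts = cs.filter_genes(truth.bulk_counts)
        out = cs.compare_models(counts, truth.condition, truth.baseline_label,
                                {"none": None})
        X, contrasts = cs.cell_means_design(truth.condition,
                                            truth.baseline_label)
        direct = cs.fit_de(counts, X, contrasts,
                           sf=cs.size_factors(counts))
        key = next(iter(out["none"].results))
        assert out["none"].results[key].equals(direct.results[key])

    def test_deterministic_across_repeat_runs(self, fixture_reference):
        d = cs.MixtureDesign(n_replicates=3, total_reads=30_000, seed=10)
        truth = cs.simulate_experiment(fixture_reference, d,
                                       conditions=[0.45, 0.50])
        counts = cs.filter_genes(truth.bulk_counts)
        runs = [cs.compare_models(counts, truth.condition,
                                  truth.baseline_label, {"none": None})
                for _ in range(2)]
        key = next(iter(runs[0]["none"].results))
        assert runs[0]["none"].results[key].equals(runs[1]["none"].results[key])
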