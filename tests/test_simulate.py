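"""Mixture simulator: grids, proportion perturbation, spiking, sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import compshift as cs


class TestDesignSweep:
    def test_default_grid_has_81_conditions(self):
        conds = cs.design_sweep(cs.MixtureDesign())
        assert len(conds) == 81
        assert conds[0] == pytest.approx(0.30)
        assert conds[-1] == pytest.approx(0.70)

    def test_coarse_grid(self):
        d = cs.MixtureDesign(cm_grid=cs.make_grid(0.4, 0.6, 0.1))
        assert len(cs.design_sweep(d)) == 3

    def test_step_not_dividing_range_raises(self):
        with pytest.raises(ValueError, match="does not divide"):
            cs.make_grid(0.3, 0.7, 0.03)

    def test_baseline_off_grid_raises(self):
        d = cs.MixtureDesign(cm_grid=np.array([0.4, 0.6]))
        with pytest.raises(ValueError, match="baseline"):
            cs.design_sweep(d)


class TestPerturbProportions:
    baseline = pd.Series({"cardiomyocyte": 0.50, "endothelial": 0.22,
                          "fibroblast": 0.14, "macrophage": 0.08,
                          "pericyte_smc": 0.06})

    def test_noiseless_identity_at_baseline(self):
        d = cs.MixtureDesign(noise_sd=0.0)
        out = cs.perturb_proportions(0.50, d, self.baseline,
                                     np.random.default_rng(0))
        assert np.allclose(out, self.baseline)

    def test_anticorrelated_absorption_of_cm_change(self):
        # dCM = -0.10 with split 0.6/0.4 -> FB +0.06, Mac +0.04
        d = cs.MixtureDesign(noise_sd=0.0)
        out = cs.perturb_proportions(0.40, d, self.baseline,
                                     np.random.default_rng(0))
        assert out["fibroblast"] == pytest.approx(0.20)
        assert out["macrophage"] == pytest.approx(0.12)
        assert out["endothelial"] == pytest.approx(0.22)
        assert out["pericyte_smc"] == pytest.approx(0.06)

    @settings(derandomize=True, max_examples=30)
    @given(cm=st.floats(0.30, 0.70), noise=st.floats(0.0, 0.05),
           seed=st.integers(0, 1000))
    def test_output_always_sums_to_one(self, cm, noise, seed):
        d = cs.MixtureDesign(noise_sd=noise)
        out = cs.perturb_proportions(cm, d, self.baseline,
                                     np.random.default_rng(seed))
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert (out >= 0).all()


class TestSpikeFoldChanges:
    profiles = pd.DataFrame({"t1": [0.5, 0.5], "t2": [0.3, 0.7]},
                            index=["gA", "gB"])

    def test_empty_spike_set_is_identity(self):
        d = cs.MixtureDesign()
        out, z = cs.spike_fold_changes(self.profiles, [], d,
                                       np.random.default_rng(0))
        assert out.equals(self.profiles)
        assert len(z) == 0

    def test_doubling_one_gene_renormalizes(self):
        # z=1 on gA in a [0.5, 0.5] profile -> [2/3, 1/3]
        d = cs.MixtureDesign(spike_mode="double")
        out, z = cs.spike_fold_changes(self.profiles, ["gA"], d,
                                       np.random.default_rng(0))
        assert np.allclose(out["t1"], [2 / 3, 1 / 3])
        assert z["gA"] == 1.0
        assert np.abs(out.sum(axis=0) - 1.0).max() < 1e-12

    def test_lognormal_mean_matches_configured_parameter(self):
        d = cs.MixtureDesign()
        genes = [f"g{i}" for i in range(10_000)]
        prof = pd.DataFrame({"t1": np.full(10_000, 1e-4)}, index=genes)
        _, z = cs.spike_fold_changes(prof, genes, d, np.random.default_rng(9))
        se = d.spike_sd_log2 / np.sqrt(len(z))
        assert abs(z.mean() - d.spike_mu_log2) < 3 * se


class TestSampleBulk:
    def test_degenerate_profile(self):
        out = cs.sample_bulk(np.array([1.0, 0.0, 0.0]), 100,
                             np.random.default_rng(0))
        assert out.tolist() == [100, 0, 0]

    def test_read_total_is_exact(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(50))
        for _ in range(5):
            assert cs.sample_bulk(pi, 10_000, rng).sum() == 10_000

    def test_expected_counts_match_clt(self):
        rng = np.random.default_rng(2)
        pi = np.array([0.5, 0.3, 0.2])
        n, reps = 1000, 1000
        draws = np.array([cs.sample_bulk(pi, n, rng) for _ in range(reps)])
        se = np.sqrt(n * pi * (1 - pi) / reps)
        assert (np.abs(draws.mean(axis=0) - n * pi) < 3 * se).all()

    def test_nonpositive_reads_raise(self):
        with pytest.raises(ValueError, match="positive"):
            cs.sample_bulk(np.array([1.0]), 0, np.random.default_rng(0))


class TestClusterProfile:
    def test_tiny_profile(self):
        from conftest import make_reference
        ref = make_reference([[1], [1], [2]], ["a", "b", "c"], ["ct"], ["s"])
        prof = cs.cluster_profile(ref, "ct")
        assert np.allclose(prof, [0.25, 0.25, 0.5])

    def test_matches_brute_force_summation(self, fixture_reference):
        prof = cs.cluster_profile(fixture_reference, "cardiomyocyte")
        dense = fixture_reference.counts.toarray()
        mask = (fixture_reference.nucleus_meta["cluster"]
                == "cardiomyocyte").to_numpy()
        expected = dense[:, mask].sum(axis=1)
        expected = expected / expected.sum()
        assert np.allclose(prof.to_numpy(), expected)

    def test_missing_cluster_raises(self, fixture_reference):
        with pytest.raises(ValueError, match="no nuclei"):
            cs.cluster_profile(fixture_reference, "neuron")


class TestSimulateExperiment:
    def test_bookkeeping_and_exact_column_sums(self, fixture_reference):
        d = cs.MixtureDesign(n_replicates=3, total_reads=20_000, seed=4)
        truth = cs.simulate_experiment(fixture_reference, d,
                                       conditions=[0.45, 0.50, 0.55])
        assert truth.bulk_counts.shape[1] == 9
        assert (truth.bulk_counts.sum(axis=0) == 20_000).all()
        assert np.abs(truth.true_proportions.sum(axis=1) - 1).max() < 1e-12
        assert set(truth.spiked_log2fc.index) == truth.spiked_genes
        assert len(truth.spiked_genes) == round(0.10 * fixture_reference.n_genes)

    def test_deterministic_under_seed(self, fixture_reference):
        d = cs.MixtureDesign(n_replicates=2, total_reads=5_000, seed=12)
        a = cs.simulate_experiment(fixture_reference, d, conditions=[0.4, 0.5])
        b = cs.simulate_experiment(fixture_reference, d, conditions=[0.4, 0.5])
        assert a.bulk_counts.equals(b.bulk_counts)
        assert a.true_proportions.equals(b.true_proportions)
        assert a.spiked_log2fc.equals(b.spiked_log2fc)

    def test_noiseless_replicates_share_exact_proportions(self, fixture_reference):
        d = cs.MixtureDesign(n_replicates=3, noise_sd=0.0, spike_fraction=0.0,
                             total_reads=5_000, seed=2)
        truth = cs.simulate_experiment(fixture_reference, d,
                                       conditions=[0.45, 0.50])
        for cond, sub in truth.true_proportions.groupby(truth.condition):
            assert (sub.nunique() == 1).all()

    def test_spiked_mixture_probability_ratio_equals_fold_change(
            self, fixture_reference):
        # with composition held at baseline, a spiked gene's mixture
        # probability changes by 2^z over the profile renormalization
        d = cs.MixtureDesign(noise_sd=0.0, seed=3)
        truth = cs.simulate_experiment(fixture_reference, d,
                                       conditions=[0.40, 0.50])
        base = pd.Series(d.baseline_proportions)
        profiles = pd.concat([cs.cluster_profile(fixture_reference, ct)
                              for ct in base.index], axis=1)
        spiked_prof, z = cs.spike_fold_changes(
            profiles, sorted(truth.spiked_genes), d,
            np.random.default_rng(0))
        g = z.index[0]
        col = profiles.columns[0]
        fold = np.where(profiles.index.isin(z.index),
                        2.0 ** z.reindex(profiles.index).fillna(0.0), 1.0)
        scale = float((profiles[col] * fold).sum())
        expected = profiles.loc[g, col] * 2.0 ** z[g] / scale
        assert spiked_prof.loc[g, col] == pytest.approx(expected, rel=1e-12)
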