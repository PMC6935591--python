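import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from clinekit.config import ClineGroup, TraitSpec, TruthConfig
from clinekit.io import MISSING
from clinekit.simulate import (generate_climate, generate_dataset,
                               sample_genotypes, simulate_cline_frequencies,
                               simulate_field_heights,
                               simulate_neutral_frequencies,
                               simulate_phenotypes)

RW = ClineGroup("rw", 5, "rangewide", center=0.0, width=2.5,
                p_lo=0.02, p_hi=0.98)


class TestClineFrequencies:
    def test_midpoint_is_halfway(self):
        p = simulate_cline_frequencies(np.array([0.0]), RW)
        assert p[0] == pytest.approx(0.5 * (0.02 + 0.98))

    def test_matches_logistic_oracle(self):
        env = np.linspace(-4, 8, 50)
        p = simulate_cline_frequencies(env, RW, center=2.0, width=0.5,
                                       p_lo=0.1, p_hi=0.9)
        oracle = 0.1 + 0.8 * expit((env - 2.0) / 0.5)
        np.testing.assert_allclose(p, oracle, rtol=0, atol=1e-12)

    def test_monotone_increasing(self):
        env = np.linspace(-4, 8, 100)
        p = simulate_cline_frequencies(env, RW)
        assert (np.diff(p) > 0).all()

    def test_equal_levels_constant(self):
        env = np.linspace(-4, 8, 20)
        p = simulate_cline_frequencies(env, RW, p_lo=0.4, p_hi=0.4)
        np.testing.assert_allclose(p, 0.4)

    def test_saturates_to_levels(self):
        p = simulate_cline_frequencies(np.array([-100.0, 100.0]), RW)
        assert p[0] == pytest.approx(0.02, abs=1e-9)
        assert p[1] == pytest.approx(0.98, abs=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_cline_frequencies(np.array([0.0, np.nan]), RW)
        with pytest.raises(ValueError):
            simulate_cline_frequencies(np.array([0.0]), RW, width=0.0)


class TestNeutralFrequencies:
    def test_fst_recovered_by_moment_estimator(self):
        # For Balding-Nichols, Var(p_k) = fst * pbar (1 - pbar): the
        # across-population moment estimate should recover the planted fst.
        fst = 0.1
        f = simulate_neutral_frequencies(3000, 60, fst, seed=11)
        anc_hat = f.mean(axis=0)
        ratio = f.var(axis=0, ddof=1) / (anc_hat * (1 - anc_hat))
        assert np.mean(ratio) == pytest.approx(fst, rel=0.1)

    def test_weak_fst_means_tiny_differentiation(self):
        f = simulate_neutral_frequencies(200, 40, 1e-5, seed=0)
        assert f.std(axis=0).max() < 0.02

    def test_deterministic_and_shape(self):
        a = simulate_neutral_frequencies(10, 7, 0.02, seed=3)
        b = simulate_neutral_frequencies(10, 7, 0.02, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (7, 10)
        assert ((a >= 0) & (a <= 1)).all()

    def test_spatial_correlation_increases_adjacent_similarity(self):
        smooth = simulate_neutral_frequencies(400, 50, 0.1, seed=5,
                                              spatial_corr=0.95)
        rough = simulate_neutral_frequencies(400, 50, 0.1, seed=5,
                                             spatial_corr=0.0)
        d_smooth = np.abs(np.diff(smooth, axis=0)).mean()
        d_rough = np.abs(np.diff(rough, axis=0)).mean()
        assert d_smooth < d_rough

    def test_rejects_bad_fst(self):
        for fst in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                simulate_neutral_frequencies(5, 5, fst, seed=0)


class TestSampleGenotypes:
    def test_extreme_frequencies_are_fixed(self):
        freqs = np.array([[0.0, 1.0]])
        g, _ = sample_genotypes(freqs, 50, seed=1)
        assert (g.codes[:, 0] == 0).all()
        assert (g.codes[:, 1] == 2).all()

    def test_binomial_mean(self):
        freqs = np.full((1, 200), 0.5)
        g, _ = sample_genotypes(freqs, 500, seed=2)
        # mean ALT count per locus is 2p = 1; SE of the grand mean is tiny
        assert g.codes.mean() == pytest.approx(1.0, abs=0.01)

    def test_missing_rate(self):
        freqs = np.full((4, 100), 0.5)
        g, _ = sample_genotypes(freqs, 50, missing_rate=0.1, seed=3)
        assert (g.codes == MISSING).mean() == pytest.approx(0.1, abs=0.01)

    def test_pop_map_structure(self):
        g, pop_map = sample_genotypes(np.full((3, 2), 0.5), 4, seed=0)
        assert g.n_individuals == 12
        assert pop_map.value_counts().eq(4).all()
        assert list(pop_map.index) == g.individuals

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sample_genotypes(np.array([[1.2]]), 2)
        with pytest.raises(ValueError):
            sample_genotypes(np.array([[0.5]]), 2, missing_rate=1.0)


class TestSimulatePhenotypes:
    def _geno(self, n_pops=6, n_per=10, n_loci=3, seed=0):
        freqs = np.random.default_rng(seed).uniform(0.2, 0.8, (n_pops, n_loci))
        return sample_genotypes(freqs, n_per, seed=seed + 1)

    def test_noiseless_equals_additive_score(self):
        g, pop_map = self._geno()
        eff = {"L00000": 0.5, "L00002": -0.2}
        pheno = simulate_phenotypes(g, pop_map, {"t": eff}, 4, 2,
                                    {"t": (0.0, 0.0, 0.0)}, seed=7)
        oracle = 0.5 * g.codes[:, 0] - 0.2 * g.codes[:, 2]
        np.testing.assert_allclose(pheno["t"].to_numpy(), oracle, atol=1e-12)

    def test_pure_noise_variance(self):
        g, pop_map = self._geno(n_pops=40, n_per=50)
        pheno = simulate_phenotypes(g, pop_map, {"t": {}}, 4, 2,
                                    {"t": (0.0, 0.0, 2.0)}, seed=8)
        assert pheno["t"].std() == pytest.approx(2.0, rel=0.1)
        assert pheno["t"].mean() == pytest.approx(0.0, abs=0.2)

    def test_block_effects_shared_within_block(self):
        g, pop_map = self._geno(n_pops=20, n_per=20)
        pheno = simulate_phenotypes(g, pop_map, {"t": {}}, 5, 2,
                                    {"t": (3.0, 0.0, 0.1)}, seed=9)
        between = pheno.groupby("block")["t"].mean().var(ddof=1)
        within = pheno.groupby("block")["t"].var(ddof=1).mean()
        assert between > 10 * within

    def test_unknown_causal_locus_raises(self):
        g, pop_map = self._geno()
        with pytest.raises(KeyError):
            simulate_phenotypes(g, pop_map, {"t": {"nope": 1.0}}, 2, 2,
                                {"t": (0, 0, 1)}, seed=0)

    def test_design_columns_balanced(self):
        g, pop_map = self._geno(n_pops=10, n_per=10)
        pheno = simulate_phenotypes(g, pop_map, {"t": {}}, 5, 2,
                                    {"t": (1, 1, 1)}, seed=1)
        assert pheno["block"].nunique() == 5
        assert pheno["location"].nunique() == 10
        counts = pheno["block"].value_counts()
        assert counts.max() - counts.min() <= 2


class TestClimateAndHeights:
    def test_noiseless_climate_perfectly_collinear(self):
        env = np.linspace(-4, 8, 30)
        clim, driver = generate_climate(env, n_vars=5, climate_noise_sd=0.0,
                                        seed=4)
        assert driver == "MAT"
        corr = clim.drop(columns="population").corr().abs()
        np.testing.assert_allclose(corr.to_numpy(), 1.0, atol=1e-12)

    def test_driver_tracks_env_most_tightly(self):
        env = np.linspace(-4, 8, 200)
        clim, driver = generate_climate(env, n_vars=19, seed=5)
        corrs = {v: abs(np.corrcoef(env, clim[v])[0, 1])
                 for v in clim.columns if v != "population"}
        assert corrs[driver] == max(corrs.values())

    def test_climate_deterministic(self):
        env = np.linspace(0, 1, 10)
        a, _ = generate_climate(env, seed=6)
        b, _ = generate_climate(env, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_too_few_vars(self):
        with pytest.raises(ValueError):
            generate_climate(np.linspace(0, 1, 5), n_vars=1)

    def test_heights_peak_near_site_optimum(self):
        env = np.linspace(-4, 8, 100)
        h = simulate_field_heights(env, n_sites=3, seed=7, noise_sd=0.0)
        for s, q in zip(("site1", "site2", "site3"), (0.25, 0.5, 0.75)):
            peak_env = env[h[s].to_numpy().argmax()]
            assert peak_env == pytest.approx(np.quantile(env, q), abs=0.2)


class TestGenerateDataset:
    def test_truth_labels_partition(self, small_dataset):
        ds = small_dataset
        t = ds.truth_loci
        assert len(t) == ds.genotypes.n_loci
        assert t["klass"].value_counts()["control"] == 300
        assert (t.loc[t["causal"], "klass"] == "candidate").all()
        assert set(t.loc[t["causal"], "group_id"]) == {"rw1", "loc1"}
        assert (t.loc[t["causal"], "group_id"].value_counts() == 12).all()

    def test_causal_effects_match_spec(self, small_dataset):
        eff = small_dataset.truth_effects
        assert len(eff["cold_injury"]) == 24      # rw1 + loc1
        assert len(eff["shoot_mass"]) == 12       # rw1 only
        assert all(v == 0.3 for v in eff["cold_injury"].values())

    def test_planted_clines_track_env(self, small_dataset):
        ds = small_dataset
        from clinekit.structure import pop_allele_frequencies
        freqs, _ = pop_allele_frequencies(ds.genotypes, ds.pop_map)
        rw = ds.truth_loci.loc[ds.truth_loci["group_id"] == "rw1", "locus"]
        corr = np.array([np.corrcoef(ds.env, freqs[l])[0, 1] for l in rw])
        assert np.median(corr) > 0.9

    def test_localized_transition_is_narrow(self, small_dataset):
        # 10%-to-90% transition width 2*w*ln(9): narrow for the localized
        # group, wider than half the span for the rangewide group.
        ds = small_dataset
        span = ds.env.max() - ds.env.min()
        t = ds.truth_loci[ds.truth_loci["causal"]]
        trans = 2 * t["width"].astype(float) * np.log(9.0)
        assert (trans[t["kind"] == "localized"] < 0.5 * span).all()
        assert (trans[t["kind"] == "rangewide"] > 0.5 * span).all()

    def test_deterministic(self, small_dataset):
        ds2 = generate_dataset(small_dataset.config)
        np.testing.assert_array_equal(ds2.genotypes.codes,
                                      small_dataset.genotypes.codes)
        pd.testing.assert_frame_equal(ds2.phenotypes,
                                      small_dataset.phenotypes)

    def test_different_seeds_differ(self, small_dataset):
        import dataclasses
        cfg = dataclasses.replace(small_dataset.config, seed=43)
        ds2 = generate_dataset(cfg)
        assert (ds2.genotypes.codes != small_dataset.genotypes.codes).any()

    def test_missing_rate_applied(self):
        cfg = TruthConfig(n_pops=10, n_per_pop=5, n_control_loci=50,
                          n_neutral_candidate_loci=50, cline_groups=[],
                          traits=[TraitSpec("t", [])], n_blocks=2,
                          n_locs_per_block=2, missing_rate=0.2, seed=1)
        ds = generate_dataset(cfg)
        assert (ds.genotypes.codes == MISSING).mean() == pytest.approx(0.2,
                                                                       abs=0.03)
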