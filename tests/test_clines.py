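import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import adjusted_rand_score

from clinekit.clines import (classify_extent, cluster_snps,
                             expected_heterozygosity,
                             proportional_polymorphism, restore_variance)


def _freq_table(cols: dict, n_pops=40):
    idx = pd.Index([f"p{k}" for k in range(n_pops)], name="population")
    return pd.DataFrame(cols, index=idx)


def _planted_two_groups(rng, n_pops=40, n_per_group=8, offset=0.5,
                        base=0.1):
    env = np.linspace(-3, 3, n_pops)
    cols, labels = {}, {}
    for j in range(n_per_group):
        cols[f"lo{j}"] = np.clip(base + 0.05 * env
                                 + rng.normal(0, 0.01, n_pops), 0, 1)
        labels[f"lo{j}"] = 0
        cols[f"hi{j}"] = np.clip(base + offset + 0.05 * env
                                 + rng.normal(0, 0.01, n_pops), 0, 1)
        labels[f"hi{j}"] = 1
    return _freq_table(cols, n_pops), labels


class TestClusterSnps:
    def test_recovers_planted_groups(self, rng):
        freqs, labels = _planted_two_groups(rng)
        model = cluster_snps(freqs, k=2, seed=0, n_init=10)
        truth = [labels[l] for l in model.assignment.index]
        assert adjusted_rand_score(truth, model.assignment) == 1.0

    def test_relabeled_by_ascending_mean(self, rng):
        freqs, _ = _planted_two_groups(rng)
        model = cluster_snps(freqs, k=2, seed=1, n_init=10)
        grand = model.cluster_mean.mean(axis=1)
        assert grand[0] < grand[1]

    def test_k_one_mean_is_column_average(self, rng):
        freqs, _ = _planted_two_groups(rng)
        model = cluster_snps(freqs, k=1, seed=2, n_init=5)
        np.testing.assert_allclose(model.cluster_mean.loc[0].to_numpy(),
                                   freqs.mean(axis=1).to_numpy(), atol=1e-12)
        assert model.silhouette is None

    def test_duplicated_loci_share_cluster(self, rng):
        freqs, _ = _planted_two_groups(rng)
        freqs = freqs.copy()
        freqs["dup"] = freqs["lo0"]
        model = cluster_snps(freqs, k=2, seed=3, n_init=10)
        assert model.assignment["dup"] == model.assignment["lo0"]

    def test_too_few_loci_raises(self, rng):
        freqs = _freq_table({"a": rng.uniform(size=40)})
        with pytest.raises(ValueError):
            cluster_snps(freqs, k=2)

    def test_deterministic(self, rng):
        freqs, _ = _planted_two_groups(rng)
        m1 = cluster_snps(freqs, k=2, seed=4, n_init=10)
        m2 = cluster_snps(freqs, k=2, seed=4, n_init=10)
        pd.testing.assert_series_equal(m1.assignment, m2.assignment)


class TestRestoreVariance:
    def test_restored_sd_equals_member_mean_sd(self, rng):
        # The algebraic identity the restoration exists for: before
        # clipping, each restored cline's across-population SD equals the
        # mean across-population SD of the cluster's member SNPs.
        freqs, _ = _planted_two_groups(rng, offset=0.3, base=0.35)
        model = cluster_snps(freqs, k=2, seed=5, n_init=10)
        restored = restore_variance(model)
        # offsets keep everything inside [0, 1], so clipping is inactive
        for c in range(2):
            got = restored.loc[c].std(ddof=0)
            assert got == pytest.approx(model.member_sd[c], abs=1e-10)

    def test_level_preserved(self, rng):
        freqs, _ = _planted_two_groups(rng, offset=0.3, base=0.35)
        model = cluster_snps(freqs, k=2, seed=6, n_init=10)
        restored = restore_variance(model)
        for c in range(2):
            assert restored.loc[c].mean() == pytest.approx(
                model.cluster_mean.loc[c].mean(), abs=1e-10)

    def test_identical_members_identity(self):
        idx = pd.Index([f"p{k}" for k in range(10)], name="population")
        col = np.linspace(0.2, 0.8, 10)
        freqs = pd.DataFrame({"a": col, "b": col, "c": col}, index=idx)
        model = cluster_snps(freqs, k=1, seed=7, n_init=5)
        restored = restore_variance(model)
        np.testing.assert_allclose(restored.loc[0].to_numpy(), col,
                                   atol=1e-10)

    def test_literal_method_formula(self, rng):
        freqs, _ = _planted_two_groups(rng)
        model = cluster_snps(freqs, k=2, seed=8, n_init=10)
        lit = restore_variance(model, method="literal")
        expect = model.cluster_mean.mul(model.member_sd, axis=0).clip(0, 1)
        pd.testing.assert_frame_equal(lit, expect)
        with pytest.raises(ValueError):
            restore_variance(model, method="nope")

    def test_output_bounded(self, rng):
        freqs, _ = _planted_two_groups(rng, offset=0.85)
        model = cluster_snps(freqs, k=2, seed=9, n_init=10)
        restored = restore_variance(model)
        assert (restored.to_numpy() >= 0).all()
        assert (restored.to_numpy() <= 1).all()


class TestStandingVariation:
    def test_he_grid(self):
        p = pd.DataFrame({"L": [0.0, 0.1, 0.25, 0.5, 0.75, 1.0]})
        he = expected_heterozygosity(p)["L"]
        np.testing.assert_allclose(he, [0.0, 0.18, 0.375, 0.5, 0.375, 0.0],
                                   atol=1e-12)

    def test_he_maximal_at_half_and_nan_propagates(self):
        p = pd.DataFrame({"L": [0.5, np.nan]})
        he = expected_heterozygosity(p)["L"]
        assert he.iloc[0] == 0.5
        assert np.isnan(he.iloc[1])

    def test_proportional_polymorphism_counting(self, rng):
        idx = pd.Index(["pA", "pB"], name="population")
        freqs = pd.DataFrame({"a": [0.5, 0.0], "b": [0.2, 0.0],
                              "c": [0.0, 0.0], "d": [1.0, np.nan]},
                             index=idx)
        model = cluster_snps(
            pd.DataFrame(rng.uniform(size=(10, 4)),
                         columns=["a", "b", "c", "d"]), k=1, seed=0, n_init=2)
        he = expected_heterozygosity(freqs)
        prop = proportional_polymorphism(he, model)
        assert prop.loc["pA", 0] == pytest.approx(2 / 4)   # a, b polymorphic
        assert prop.loc["pB", 0] == pytest.approx(0 / 3)   # d missing excluded


class TestClassifyExtent:
    def _restored(self, rows, env):
        return pd.DataFrame(rows, index=pd.RangeIndex(len(rows),
                                                      name="cluster"),
                            columns=[f"p{k}" for k in range(env.size)])

    def test_labels_planted_shapes(self):
        env = np.linspace(-4, 8, 60)
        span = env.max() - env.min()
        rangewide = 0.05 + 0.9 * expit((env - 2.0) / (0.2 * span))
        localized = 0.05 + 0.9 * expit((env - 2.0) / (0.02 * span))
        flat = np.full(60, 0.42)
        restored = self._restored([rangewide, localized, flat], env)
        out = classify_extent(restored, env, span_fraction=0.5)
        assert [e.label for e in out] == ["rangewide", "localized", "flat"]
        assert [e.cluster for e in out] == [0, 1, 2]

    def test_small_total_change_is_flat(self):
        env = np.linspace(-4, 8, 50)
        subtle = 0.40 + 0.08 * expit((env - 1.0) / 0.3)  # |p1-p0| < 0.1
        out = classify_extent(self._restored([subtle], env), env)
        assert out[0].label == "flat"

    def test_fit_recovers_parameters(self):
        env = np.linspace(-4, 8, 80)
        truth = 0.1 + 0.8 * expit((env - 1.5) / 0.8)
        out = classify_extent(self._restored([truth], env), env)[0]
        assert out.center == pytest.approx(1.5, abs=0.05)
        assert out.width == pytest.approx(0.8, abs=0.05)
        assert out.p0 == pytest.approx(0.1, abs=0.02)
        assert out.p1 == pytest.approx(0.9, abs=0.02)
        lo, hi = out.active_range
        assert lo == pytest.approx(1.5 - 0.8 * np.log(9), abs=0.1)
        assert hi == pytest.approx(1.5 + 0.8 * np.log(9), abs=0.1)

    def test_decreasing_cline_supported(self):
        env = np.linspace(-4, 8, 60)
        dec = 0.9 - 0.8 * expit((env - 2.0) / 0.4)
        out = classify_extent(self._restored([dec], env), env)[0]
        assert out.label == "localized"
        assert out.p0 > out.p1

    def test_too_few_populations_raises(self):
        env = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            classify_extent(self._restored([[0.1, 0.5, 0.9]], env), env)
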