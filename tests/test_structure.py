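import numpy as np
import pandas as pd
import pytest

from clinekit.io import MISSING, GenotypeMatrix
from clinekit.simulate import sample_genotypes, simulate_neutral_frequencies
from clinekit.structure import (compute_grm, estimate_pop_covariance,
                                pop_allele_frequencies, principal_components,
                                standardize_frequencies)


def _matrix(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n_ind, n_loci = codes.shape
    loci = pd.DataFrame({"locus": [f"L{j}" for j in range(n_loci)],
                         "contig": [f"c{j}" for j in range(n_loci)],
                         "klass": "control", "ref": "A", "alt": "G"})
    return GenotypeMatrix(codes, [f"i{k}" for k in range(n_ind)], loci)


class TestGrm:
    def test_hand_computed_three_by_two(self):
        # codes [[0,2],[1,1],[2,0]]: both loci have p = 0.5, so
        # Z = (g - 1)/sqrt(0.5) and K = ZZ'/2 = [[2,0,-2],[0,0,0],[-2,0,2]].
        g = _matrix([[0, 2], [1, 1], [2, 0]])
        K = compute_grm(g).to_numpy()
        np.testing.assert_allclose(K, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]],
                                   atol=1e-12)

    def test_identical_individuals_maximal_kinship(self):
        g = _matrix([[0, 2, 1, 1], [0, 2, 1, 1], [2, 0, 1, 0]])
        K = compute_grm(g).to_numpy()
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 2] < K[0, 1]

    def test_symmetric_with_unit_mean_diagonal(self):
        freqs = simulate_neutral_frequencies(500, 20, 0.05, seed=1)
        g, _ = sample_genotypes(freqs, 5, seed=2)
        K = compute_grm(g).to_numpy()
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.diag(K).mean() == pytest.approx(1.0, rel=0.1)

    def test_fixed_loci_excluded(self):
        # Appending a fixed column changes nothing.
        g1 = _matrix([[0, 2], [1, 1], [2, 0]])
        g2 = _matrix([[0, 2, 2], [1, 1, 2], [2, 0, 2]])
        np.testing.assert_allclose(compute_grm(g1).to_numpy(),
                                   compute_grm(g2).to_numpy(), atol=1e-12)

    def test_too_few_polymorphic_raises(self):
        with pytest.raises(ValueError):
            compute_grm(_matrix([[2, 2], [2, 2]]))


class TestPopFrequencies:
    def test_counting_oracle(self):
        g = _matrix([[0, 1], [1, 2], [2, MISSING], [0, 0]])
        pop_map = pd.Series(["a", "a", "b", "b"], index=g.individuals)
        freqs, n = pop_allele_frequencies(g, pop_map)
        assert freqs.loc["a", "L0"] == pytest.approx(1 / 4)   # 0+1 of 4
        assert freqs.loc["a", "L1"] == pytest.approx(3 / 4)
        assert freqs.loc["b", "L0"] == pytest.approx(2 / 4)
        assert freqs.loc["b", "L1"] == pytest.approx(0.0)     # missing skipped
        assert n.loc["b", "L1"] == 1

    def test_all_missing_cell_is_nan(self):
        g = _matrix([[MISSING], [1]])
        pop_map = pd.Series(["a", "b"], index=g.individuals)
        freqs, n = pop_allele_frequencies(g, pop_map)
        assert np.isnan(freqs.loc["a", "L0"])
        assert n.loc["a", "L0"] == 0

    def test_matches_brute_force(self, rng):
        codes = rng.integers(-1, 3, size=(30, 8)).astype(np.int8)
        g = _matrix(codes)
        pop_map = pd.Series(rng.choice(["x", "y", "z"], 30),
                            index=g.individuals)
        freqs, _ = pop_allele_frequencies(g, pop_map)
        for pop in ("x", "y", "z"):
            rows = (pop_map == pop).to_numpy()
            for j in range(8):
                col = codes[rows, j]
                col = col[col != MISSING]
                expect = col.sum() / (2 * len(col)) if len(col) else np.nan
                got = freqs.loc[pop, f"L{j}"]
                assert (np.isnan(got) and np.isnan(expect)) or \
                    got == pytest.approx(expect)


class TestStandardize:
    def test_formula(self):
        f = pd.DataFrame({"L0": [0.2, 0.4, 0.6]})
        x = standardize_frequencies(f)
        pbar = 0.4
        expect = (np.array([0.2, 0.4, 0.6]) - pbar) / np.sqrt(pbar * 0.6)
        np.testing.assert_allclose(x["L0"], expect, atol=1e-12)

    def test_drops_fixed_and_fills_nan(self):
        f = pd.DataFrame({"fixed": [1.0, 1.0], "ok": [0.2, np.nan]})
        x = standardize_frequencies(f)
        assert list(x.columns) == ["ok"]
        assert not x.isna().any().any()


class TestOmega:
    def test_panmictic_is_near_diagonal(self):
        # fst ~ 0: populations are exchangeable draws, so Omega is close to
        # a scaled identity (off-diagonal covariance ~ 0).
        freqs = simulate_neutral_frequencies(4000, 12, 1e-4, seed=3)
        g, pop_map = sample_genotypes(freqs, 20, seed=4)
        f, n = pop_allele_frequencies(g, pop_map)
        omega, runs = estimate_pop_covariance(f, n, n_runs=3, seed=5)
        om = omega.to_numpy()
        off = om[~np.eye(len(om), dtype=bool)]
        assert np.abs(off).max() < 0.25 * np.diag(om).min()
        assert len(runs) == 3

    def test_hierarchical_structure_detected(self):
        # Two population groups sharing drift: within-group covariance must
        # exceed between-group covariance.
        rng = np.random.default_rng(6)
        n_loci = 3000
        anc = rng.uniform(0.2, 0.8, n_loci)
        out = np.empty((10, n_loci))
        for grp in range(2):
            grp_dev = rng.normal(0, 0.08, n_loci)
            for k in range(5):
                p = anc + grp_dev + rng.normal(0, 0.03, n_loci)
                out[5 * grp + k] = np.clip(p, 0.01, 0.99)
        f = pd.DataFrame(out, index=[f"p{k}" for k in range(10)],
                         columns=[f"L{j}" for j in range(n_loci)])
        n = pd.DataFrame(10.0, index=f.index, columns=f.columns)
        omega, _ = estimate_pop_covariance(f, n, n_runs=2, seed=7)
        om = omega.to_numpy()
        within = np.concatenate([om[:5, :5][~np.eye(5, dtype=bool)],
                                 om[5:, 5:][~np.eye(5, dtype=bool)]])
        between = om[:5, 5:].ravel()
        # per-locus standardization centers across populations, so shared
        # within-group drift shows up as positive within-group covariance
        # balanced by negative between-group covariance
        assert within.mean() > 0 > between.mean()
        assert within.mean() - between.mean() > 0.02

    def test_deterministic_and_positive_definite(self):
        freqs = simulate_neutral_frequencies(500, 8, 0.05, seed=8)
        g, pop_map = sample_genotypes(freqs, 10, seed=9)
        f, n = pop_allele_frequencies(g, pop_map)
        o1, _ = estimate_pop_covariance(f, n, seed=10)
        o2, _ = estimate_pop_covariance(f, n, seed=10)
        pd.testing.assert_frame_equal(o1, o2)
        assert np.linalg.eigvalsh(o1.to_numpy()).min() > 0


class TestPrincipalComponents:
    def test_matches_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 4)))
        res = principal_components(X, standardize=False)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
        score_ss = (res.scores.to_numpy() ** 2).sum(axis=0)
        np.testing.assert_allclose(np.sort(score_ss)[::-1], evals, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)))
        s = principal_components(X).scores.to_numpy()
        gram = s.T @ s
        off = gram[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 1e-8

    def test_perfectly_correlated_pair_one_component(self, rng):
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": 2 * a - 1})
        res = principal_components(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_sign_deterministic_and_m_cap(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        r1 = principal_components(X, m=3)
        r2 = principal_components(X, m=3)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        assert r1.scores.shape == (10, 3)
        # largest-|loading| entry positive per component
        for c in r1.loadings.columns:
            col = r1.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_zero_variance_column_dropped(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=8), "const": 1.0})
        res = principal_components(X)
        assert list(res.loadings.index) == ["a"]
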