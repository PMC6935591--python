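"""Seeded recovery experiments on synthetic data.

Each function builds a fresh simulated dataset at a documented scale, runs
one stage of the pipeline against the planted truth, and returns the
recovery statistic. They serve two purposes: validating the implementation
(the test suite calls them) and characterizing what the method can and
cannot detect under the generator's assumptions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import clines as clines_mod
from . import gea as gea_mod
from . import gpa as gpa_mod
from . import structure as structure_mod
from .config import ClineGroup, TraitSpec, TruthConfig
from .simulate import generate_dataset, sample_genotypes, simulate_neutral_frequencies


def _spawn(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def gpa_null_calibration(seed: int, n_pops: int = 280, n_per_pop: int = 10,
                         n_control: int = 2000, n_scan: int = 4000,
                         fst: float = 0.016, h2: float = 0.3) -> float:
    """KS p-value of MLMA p-values against U(0,1) on a null simulation.

    Structured populations, a polygenic phenotype built from the control
    loci (so the GRM is the correct structure model), and no causal locus
    among the scanned candidates. Returns the Kolmogorov-Smirnov p-value;
    large values mean the scan is well calibrated.
    """
    s = _spawn(seed, 4)
    freqs = simulate_neutral_frequencies(n_control + n_scan, n_pops, fst,
                                         seed=s[0])
    genotypes, _ = sample_genotypes(freqs, n_per_pop, seed=s[1])
    loci = genotypes.loci
    loci.loc[: n_control - 1, "klass"] = "control"
    control = genotypes.by_class("control")
    candidates = genotypes.by_class("candidate")

    grm = structure_mod.compute_grm(control)
    rng = np.random.default_rng(s[2])
    Xc, p = structure_mod._impute_mean(control.codes)
    keep = (p > 0) & (p < 1)
    Z = (Xc[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    u = rng.normal(0.0, np.sqrt(h2 / Z.shape[1]), size=Z.shape[1])
    y_vals = Z @ u + rng.normal(0.0, np.sqrt(1.0 - h2), size=Z.shape[0])
    y = pd.Series(y_vals, index=genotypes.individuals)

    res = gpa_mod.mlma_scan(candidates, y, grm)
    pvals = res.loc[~res["monomorphic"], "p_value"].to_numpy()
    return float(stats.kstest(pvals, "uniform").pvalue)


def _cline_dataset(seed: int, groups: list[ClineGroup],
                   n_pops: int = 280, n_per_pop: int = 10,
                   n_control: int = 2000, n_neutral: int = 2000,
                   trait_groups: list[str] | None = None,
                   effect_size: float = 0.25) -> "SyntheticDataset":
    gids = [g.group_id for g in groups]
    cfg = TruthConfig(
        n_pops=n_pops, n_per_pop=n_per_pop, n_control_loci=n_control,
        n_neutral_candidate_loci=n_neutral, cline_groups=groups,
        traits=[TraitSpec("trait", trait_groups or gids,
                          effect_size=effect_size)],
        n_blocks=10, n_locs_per_block=4, seed=seed)
    return generate_dataset(cfg)


def gea_cline_recovery(seed: int, group_size: int = 40,
                       k_factor: float = 1.5, n_pops: int = 280,
                       n_per_pop: int = 10, n_control: int = 2000,
                       n_neutral: int = 2000) -> float:
    """Fraction of a planted climate-driven cline group recovered by the
    dual-rank GEA filter at K = k_factor x group size."""
    group = ClineGroup("rw", group_size, "rangewide", center=2.0, width=2.5,
                       p_lo=0.05, p_hi=0.95)
    ds = _cline_dataset(seed, [group], n_pops, n_per_pop, n_control, n_neutral)
    freqs, n_tab = structure_mod.pop_allele_frequencies(ds.genotypes, ds.pop_map)
    ctrl = ds.truth_loci.loc[ds.truth_loci["klass"] == "control", "locus"]
    _, chains = structure_mod.estimate_pop_covariance(
        freqs[list(ctrl)], n_tab[list(ctrl)], n_runs=3, seed=seed + 1)
    cand = ds.truth_loci.loc[ds.truth_loci["klass"] == "candidate", "locus"]
    clim = ds.climate.set_index("population")
    scores = gea_mod.score_env_associations(
        freqs[list(cand)], chains, clim[ds.driver_variable])
    k = int(round(k_factor * group_size))
    cand_set = gea_mod.dual_rank_filter(scores, k=k, variable=ds.driver_variable)
    planted = set(ds.truth_loci.loc[ds.truth_loci["group_id"] == "rw", "locus"])
    return len(planted & set(cand_set.loci)) / len(planted)


def driver_identification(seed: int, n_pops: int = 280, n_per_pop: int = 10,
                          n_control: int = 1000, n_neutral: int = 1880,
                          top_n: int = 300) -> bool:
    """Whether the planted driving climate variable attains the maximum
    genomic-mode driver R^2 among all simulated variables."""
    from . import drivers as drivers_mod

    groups = [ClineGroup("rw1", 40, "rangewide", 0.0, 2.5, 0.02, 0.98),
              ClineGroup("rw2", 40, "rangewide", 4.0, 2.5, 0.02, 0.98),
              ClineGroup("loc1", 40, "localized", 2.0, 0.4, 0.02, 0.98)]
    ds = _cline_dataset(seed, groups, n_pops, n_per_pop, n_control, n_neutral)
    freqs, n_tab = structure_mod.pop_allele_frequencies(ds.genotypes, ds.pop_map)
    ctrl = list(ds.truth_loci.loc[ds.truth_loci["klass"] == "control", "locus"])
    cand = list(ds.truth_loci.loc[ds.truth_loci["klass"] == "candidate", "locus"])
    _, chains = structure_mod.estimate_pop_covariance(
        freqs[ctrl], n_tab[ctrl], n_runs=3, seed=seed + 1)
    variables = [c for c in ds.climate.columns if c != "population"]
    scores = gea_mod.score_env_associations_multi(
        freqs[cand], chains, ds.climate, variables)
    overall = freqs[cand].mean(axis=0)
    rows = []
    for v in variables:
        top = gea_mod.top_n_by_rank(scores[v], n=top_n)
        f = freqs[top]
        flip = (overall[top] > 0.5).to_numpy()
        minor = f.copy()
        minor.loc[:, flip] = 1.0 - minor.loc[:, flip]
        clim_v = ds.climate.set_index("population")[v]
        rows.append((v, drivers_mod.driver_r2(clim_v, minor, n_pcs=4,
                                              seed=seed + 2)))
    best = max(rows, key=lambda r: r[1])[0]
    return best == ds.driver_variable


def cline_recovery(seed: int, n_pops: int = 280, n_per_pop: int = 10,
                   k: int = 3) -> tuple[float, bool]:
    """Recover planted 2-rangewide + 1-localized groups by k-means.

    Clusters the planted loci's population PEA-frequency profiles at k=3,
    then labels each cluster's restored cline. Returns (adjusted Rand index
    vs. the planted partition, whether every planted group's majority
    cluster received the correct extent label).
    """
    groups = [ClineGroup("rw1", 40, "rangewide", 0.0, 2.5, 0.02, 0.98),
              ClineGroup("rw2", 40, "rangewide", 4.0, 2.5, 0.02, 0.98),
              ClineGroup("loc1", 40, "localized", 2.0, 0.4, 0.02, 0.98)]
    ds = _cline_dataset(seed, groups, n_pops, n_per_pop,
                        n_control=200, n_neutral=200)
    freqs, _ = structure_mod.pop_allele_frequencies(ds.genotypes, ds.pop_map)
    planted = ds.truth_loci[ds.truth_loci["causal"]]
    pea = freqs[list(planted["locus"])]  # PEA = ALT allele in simulation
    model = clines_mod.cluster_snps(pea, k=k, seed=seed + 3, n_init=20)
    truth_labels = planted.set_index("locus")["group_id"]
    ari = adjusted_rand_score(truth_labels.loc[model.assignment.index],
                              model.assignment)
    restored = clines_mod.restore_variance(model)
    extents = {e.cluster: e.label for e in
               clines_mod.classify_extent(restored, ds.env)}
    ok = True
    for gid, kind in planted.groupby("group_id")["kind"].first().items():
        members = truth_labels.index[truth_labels == gid]
        clusters = model.assignment.loc[members]
        majority = clusters.value_counts().idxmax()
        if extents[majority] != kind:
            ok = False
    return float(ari), ok


def reml_component_recovery(seed: int, sigma2: tuple[float, float, float] =
                            (1.0, 0.5, 1.0), n_blocks: int = 20,
                            n_locs: int = 5, n_per_loc: int = 16
                            ) -> tuple[float, float, float]:
    """Relative errors of REML estimates of (block, location, residual)
    variances on a balanced nested design."""
    from .pheno import fit_block_model

    rng = np.random.default_rng(seed)
    sb, sl, se = (np.sqrt(v) for v in sigma2)
    rows = []
    i = 0
    for b in range(n_blocks):
        bj = rng.normal(0, sb)
        for l in range(n_locs):
            lk = rng.normal(0, sl)
            for _ in range(n_per_loc):
                rows.append((f"i{i}", "pop0", f"B{b}", f"B{b}_L{l}",
                             bj + lk + rng.normal(0, se)))
                i += 1
    df = pd.DataFrame(rows, columns=["individual", "population", "block",
                                     "location", "y"])
    fit = fit_block_model(df, "y")
    c = fit.components
    est = (c.sigma2_block, c.sigma2_loc, c.sigma2_e)
    return tuple(abs(e - t) / t for e, t in zip(est, sigma2))
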