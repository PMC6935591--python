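"""Synthetic data with the statistical structure the pipeline assumes.

The generator plants known truth: neutral loci drifted under a
Balding-Nichols model with weak differentiation, groups of adaptive loci
with logistic allele-frequency clines along a one-dimensional environmental
gradient (rangewide transitions vs. localized ones confined to a narrow
sub-interval), additive polygenic phenotypes measured in a blocked common
garden, and a panel of mutually correlated climate variables driven by the
same gradient. Truth labels are returned so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import CLIMATE_VARS, ClineGroup, TruthConfig
from .io import (MISSING, LOCUS_META_COLS, GenotypeMatrix,
                 write_genotype_matrix)


def simulate_cline_frequencies(env: np.ndarray, group: ClineGroup,
                               center: float | None = None,
                               width: float | None = None,
                               p_lo: float | None = None,
                               p_hi: float | None = None) -> np.ndarray:
    """Four-parameter logistic cline evaluated at each population's env value.

    p(env) = p_lo + (p_hi - p_lo) * expit((env - center) / width)

    Explicit keyword overrides allow per-locus jitter around the group's
    shared parameters.
    """
    env = np.asarray(env, dtype=float)
    if not np.isfinite(env).all():
        raise ValueError("environmental gradient contains non-finite values")
    c = group.center if center is None else center
    w = group.width if width is None else width
    lo = group.p_lo if p_lo is None else p_lo
    hi = group.p_hi if p_hi is None else p_hi
    if w <= 0:
        raise ValueError("cline width must be positive")
    return lo + (hi - lo) * expit((env - c) / w)


def simulate_neutral_frequencies(n_loci: int, n_pops: int, fst: float,
                                 seed: int, spatial_corr: float = 0.0,
                                 ancestral_lo: float = 0.05,
                                 ancestral_hi: float = 0.95) -> np.ndarray:
    """Balding-Nichols population frequencies, shape (n_pops, n_loci).

    Ancestral frequencies are Uniform(ancestral_lo, ancestral_hi); each
    population draws Beta(p(1-fst)/fst, (1-p)(1-fst)/fst) independently.
    With ``spatial_corr`` > 0, draws are coupled along the population order
    through an AR(1) Gaussian copula, inducing spatial autocorrelation.
    """
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(ancestral_lo, ancestral_hi, size=n_loci)
    a = anc * (1.0 - fst) / fst
    b = (1.0 - anc) * (1.0 - fst) / fst
    if spatial_corr <= 0.0:
        return rng.beta(a[None, :], b[None, :], size=(n_pops, n_loci))
    # AR(1) copula along the gradient: z_k = rho z_{k-1} + sqrt(1-rho^2) eps
    z = np.empty((n_pops, n_loci))
    z[0] = rng.standard_normal(n_loci)
    innov = rng.standard_normal((n_pops - 1, n_loci))
    for k in range(1, n_pops):
        z[k] = spatial_corr * z[k - 1] + np.sqrt(1 - spatial_corr**2) * innov[k - 1]
    u = stats.norm.cdf(z)
    return stats.beta.ppf(u, a[None, :], b[None, :])


def sample_genotypes(pop_frequencies: np.ndarray, n_per_pop: int,
                     missing_rate: float = 0.0, seed: int = 0,
                     pop_ids: list[str] | None = None,
                     loci: pd.DataFrame | None = None) -> tuple[GenotypeMatrix, pd.Series]:
    """Binomial(2, p) genotypes per individual; returns matrix + pop map.

    ``pop_frequencies`` has shape (n_pops, n_loci). The second return value
    maps individual id -> population id.
    """
    pop_frequencies = np.asarray(pop_frequencies, dtype=float)
    if ((pop_frequencies < 0) | (pop_frequencies > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_pops, n_loci = pop_frequencies.shape
    if pop_ids is None:
        pop_ids = [f"pop{k:04d}" for k in range(n_pops)]
    reps = np.repeat(np.arange(n_pops), n_per_pop)
    codes = rng.binomial(2, pop_frequencies[reps, :]).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = MISSING
    individuals = [f"{pop_ids[k]}_i{j}" for k in range(n_pops)
                   for j in range(n_per_pop)]
    if loci is None:
        loci = pd.DataFrame({
            "locus": [f"L{j:05d}" for j in range(n_loci)],
            "contig": [f"ctg{j:05d}" for j in range(n_loci)],
            "klass": "candidate", "ref": "A", "alt": "G",
        })
    pop_map = pd.Series([pop_ids[k] for k in reps],
                        index=pd.Index(individuals, name="individual"),
                        name="population")
    return GenotypeMatrix(codes, individuals, loci), pop_map


def simulate_phenotypes(genotypes: GenotypeMatrix, pop_map: pd.Series,
                        effects: dict[str, dict[str, float]],
                        n_blocks: int, n_locs_per_block: int,
                        sigmas: dict[str, tuple[float, float, float]],
                        seed: int = 0) -> pd.DataFrame:
    """Additive polygenic phenotypes in a blocked common garden.

    y = sum(effect * PEA count) + B_j + L(B)_jk + e, with the block,
    location-within-block, and residual terms drawn from centered normals
    whose SDs come from ``sigmas[trait] = (sigma_block, sigma_loc, sigma_e)``.
    Individuals are randomly assigned to blocks and locations within block.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    locus_pos = {l: j for j, l in enumerate(genotypes.locus_ids)}

    order = rng.permutation(n)
    block_idx = np.empty(n, dtype=int)
    loc_idx = np.empty(n, dtype=int)
    n_cells = n_blocks * n_locs_per_block
    block_idx[order] = (np.arange(n) % n_cells) // n_locs_per_block
    loc_idx[order] = np.arange(n) % n_cells

    out = pd.DataFrame({
        "individual": genotypes.individuals,
        "population": pop_map.loc[genotypes.individuals].to_numpy(),
        "block": [f"B{b:02d}" for b in block_idx],
        "location": [f"B{b:02d}_L{l % n_locs_per_block}" for b, l in
                     zip(block_idx, loc_idx)],
    })
    for trait, eff in effects.items():
        sb, sl, se = sigmas[trait]
        g = np.zeros(n)
        for locus, beta in eff.items():
            if locus not in locus_pos:
                raise KeyError(f"unknown causal locus {locus!r}")
            col = genotypes.codes[:, locus_pos[locus]].astype(float)
            obs = col != MISSING
            fill = col[obs].mean() if obs.any() else 0.0
            col = np.where(obs, col, fill)
            g += beta * col
        b_eff = rng.normal(0.0, sb, size=n_blocks)
        l_eff = rng.normal(0.0, sl, size=n_cells)
        out[trait] = g + b_eff[block_idx] + l_eff[loc_idx] + rng.normal(0, se, n)
    return out


def generate_climate(env: np.ndarray, n_vars: int = 19,
                     climate_noise_sd: float = 1.0, seed: int = 0,
                     pop_ids: list[str] | None = None) -> tuple[pd.DataFrame, str]:
    """Correlated climate variables, each an affine function of env plus noise.

    The first variable (MAT) is the designated driver: it carries the
    largest slope-to-noise ratio. Because all variables share the same
    underlying gradient, many pairs are highly correlated, as in real
    bioclimatic panels. Returns (table, driver name).
    """
    if n_vars < 2:
        raise ValueError("need at least 2 climate variables")
    env = np.asarray(env, dtype=float)
    rng = np.random.default_rng(seed)
    names = list(CLIMATE_VARS[:n_vars])
    names += [f"VAR{j}" for j in range(len(names), n_vars)]
    n_pops = env.size
    if pop_ids is None:
        pop_ids = [f"pop{k:04d}" for k in range(n_pops)]
    table = {"population": pop_ids}
    signs = rng.choice([-1.0, 1.0], size=n_vars)
    scales = rng.uniform(0.5, 3.0, size=n_vars)
    offsets = rng.uniform(-5.0, 5.0, size=n_vars)
    noise_mult = rng.uniform(1.0, 3.0, size=n_vars)
    # Driver: MAT tracks env directly with the smallest relative noise.
    signs[0], scales[0], offsets[0], noise_mult[0] = 1.0, 1.0, 0.0, 0.4
    env_sd = env.std() if env.std() > 0 else 1.0
    for j, name in enumerate(names):
        b = signs[j] * scales[j]
        noise = rng.normal(0.0, climate_noise_sd * noise_mult[j]
                           * abs(b) * env_sd / 3.0, size=n_pops)
        table[name] = offsets[j] + b * env + noise
    return pd.DataFrame(table), names[0]


def simulate_field_heights(env: np.ndarray, n_sites: int = 3, seed: int = 0,
                           pop_ids: list[str] | None = None,
                           noise_sd: float = 1.0) -> pd.DataFrame:
    """Provenance-trial heights at several sites with quadratic transfer functions.

    Each site has a climatic optimum; population-mean height declines
    quadratically with transfer distance from that optimum, emulating
    long-term field performance.
    """
    env = np.asarray(env, dtype=float)
    rng = np.random.default_rng(seed)
    if pop_ids is None:
        pop_ids = [f"pop{k:04d}" for k in range(env.size)]
    optima = np.quantile(env, np.linspace(0.25, 0.75, n_sites))
    out = {"population": pop_ids}
    span = env.max() - env.min() or 1.0
    for s, opt in enumerate(optima):
        h = 20.0 - 8.0 * ((env - opt) / span) ** 2 * 4.0
        out[f"site{s + 1}"] = h + rng.normal(0.0, noise_sd, env.size)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Full dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    panel: pd.DataFrame
    genotypes: GenotypeMatrix
    pop_map: pd.Series               # individual -> population
    climate: pd.DataFrame
    driver_variable: str
    phenotypes: pd.DataFrame
    field_heights: pd.DataFrame
    truth_loci: pd.DataFrame         # per-locus labels (class, group, cline params)
    truth_effects: dict[str, dict[str, float]]
    env: np.ndarray                  # per-population gradient
    config: TruthConfig

    @property
    def pop_ids(self) -> list[str]:
        return list(self.panel["population"])


def generate_dataset(cfg: TruthConfig) -> SyntheticDataset:
    """Generate a complete labelled dataset from a :class:`TruthConfig`."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    env = cfg.env
    n_pops = cfg.n_pops
    pop_ids = [f"pop{k:04d}" for k in range(n_pops)]
    rng = np.random.default_rng(seeds[0])

    # --- population panel: colder env at higher latitude -------------------
    lat = 60.0 - 12.0 * (env - env.min()) / (env.max() - env.min() or 1.0)
    panel = pd.DataFrame({
        "population": pop_ids,
        "latitude": lat + rng.normal(0, 0.3, n_pops),
        "longitude": rng.uniform(-130.0, -110.0, n_pops),
        "elevation": np.clip(1200.0 - 60.0 * env + rng.normal(0, 150.0, n_pops),
                             0.0, None),
        "n": cfg.n_per_pop,
    })

    # --- allele frequencies -------------------------------------------------
    n_neutral = cfg.n_control_loci + cfg.n_neutral_candidate_loci
    neutral = simulate_neutral_frequencies(n_neutral, n_pops, cfg.fst_neutral,
                                           seed=seeds[1])
    cline_cols, truth_rows = [], []
    jrng = np.random.default_rng(seeds[2])
    for grp in cfg.cline_groups:
        for m in range(grp.n_loci):
            j = jrng.uniform(-grp.jitter, grp.jitter, size=4)
            c = grp.center + j[0] * (env.max() - env.min())
            w = grp.width * (1.0 + j[1])
            lo = float(np.clip(grp.p_lo * (1.0 + j[2]), 0.0, 1.0))
            hi = float(np.clip(grp.p_hi * (1.0 + j[3]), lo + 1e-6, 1.0))
            cline_cols.append(simulate_cline_frequencies(env, grp, center=c,
                                                         width=w, p_lo=lo, p_hi=hi))
            truth_rows.append({"group_id": grp.group_id, "kind": grp.kind,
                               "center": c, "width": w, "p_lo": lo, "p_hi": hi})
    freqs = np.column_stack([neutral] + cline_cols) if cline_cols else neutral
    n_loci = freqs.shape[1]

    loci = pd.DataFrame({
        "locus": [f"L{j:05d}" for j in range(n_loci)],
        "contig": [f"ctg{j:05d}" for j in range(n_loci)],
        "klass": (["control"] * cfg.n_control_loci
                  + ["candidate"] * (n_loci - cfg.n_control_loci)),
        "ref": "A", "alt": "G",
    })
    genotypes, pop_map = sample_genotypes(freqs, cfg.n_per_pop,
                                          missing_rate=0.0, seed=seeds[3],
                                          pop_ids=pop_ids, loci=loci)

    # --- truth labels -------------------------------------------------------
    truth_loci = loci[["locus", "contig", "klass"]].copy()
    truth_loci["causal"] = False
    truth_loci["group_id"] = ""
    for col in ("kind",):
        truth_loci[col] = ""
    for col in ("center", "width", "p_lo", "p_hi"):
        truth_loci[col] = np.nan
    base = n_neutral
    for i, row in enumerate(truth_rows):
        idx = base + i
        truth_loci.loc[idx, "causal"] = True
        for k, v in row.items():
            truth_loci.loc[idx, k] = v

    # --- phenotypes (PEA = ALT allele: effects are positive per ALT copy) ---
    effects: dict[str, dict[str, float]] = {}
    sigmas: dict[str, tuple[float, float, float]] = {}
    members = {g.group_id: truth_loci.index[truth_loci["group_id"] == g.group_id]
               for g in cfg.cline_groups}
    for t in cfg.traits:
        eff = {}
        for gid in t.causal_group_ids:
            for idx in members[gid]:
                eff[truth_loci.loc[idx, "locus"]] = t.effect_size
        effects[t.name] = eff
        sigmas[t.name] = (t.sigma_block, t.sigma_loc, t.sigma_e)
    phenotypes = simulate_phenotypes(genotypes, pop_map, effects,
                                     cfg.n_blocks, cfg.n_locs_per_block,
                                     sigmas, seed=seeds[4])

    if cfg.missing_rate > 0:  # mask after phenotypes so truth is exact
        mrng = np.random.default_rng(seeds[5])
        mask = mrng.random(genotypes.codes.shape) < cfg.missing_rate
        genotypes.codes[mask] = MISSING

    climate, driver = generate_climate(env, cfg.n_climate_vars,
                                       cfg.climate_noise_sd, seed=seeds[6],
                                       pop_ids=pop_ids)
    heights = simulate_field_heights(env, seed=seeds[7], pop_ids=pop_ids)

    return SyntheticDataset(panel=panel, genotypes=genotypes, pop_map=pop_map,
                            climate=climate, driver_variable=driver,
                            phenotypes=phenotypes, field_heights=heights,
                            truth_loci=truth_loci, truth_effects=effects,
                            env=env, config=cfg)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write all tables in the formats the io module reads, plus truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_matrix(ds.genotypes, out / "genotypes.tsv",
                          out / "genotypes.loci.tsv")
    ds.panel.to_csv(out / "panel.csv", index=False)
    ds.climate.to_csv(out / "climate.csv", index=False)
    ds.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    ds.field_heights.to_csv(out / "field_heights.csv", index=False)
    truth = {
        "driver_variable": ds.driver_variable,
        "effects": ds.truth_effects,
        "loci": ds.truth_loci.to_dict(orient="records"),
        "env": ds.env.tolist(),
        "config": ds.config.to_dict(),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
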