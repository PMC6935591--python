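"""End-to-end orchestration of the analysis stages, in paper order:

simulate/load -> MAF filter -> phenotype adjustment -> structure objects ->
GPA scan -> GEA scan -> predictor-set variance comparison -> climate-driver
ranking/congruence -> cline clustering and standing variation.

Each stage is a thin composition of the module functions so the same code
path serves the CLI, the tests, and scripted use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clines as clines_mod
from . import drivers as drivers_mod
from . import gea as gea_mod
from . import gpa as gpa_mod
from . import pheno as pheno_mod
from . import structure as structure_mod
from . import varexp as varexp_mod
from .config import RunConfig, StageParams
from .io import (GenotypeMatrix, filter_maf, read_climate_table,
                 read_genotype_matrix, read_phenotype_table,
                 read_population_panel, validate_dataset)
from .simulate import SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)

DESIGN_COLS = {"individual", "population", "block", "location"}


@dataclass
class PipelineState:
    """Accumulated artifacts; stages fill their own slots."""

    genotypes: GenotypeMatrix
    panel: pd.DataFrame
    climate: pd.DataFrame
    phenotypes: pd.DataFrame
    pop_map: pd.Series
    field_heights: pd.DataFrame | None = None
    truth: SyntheticDataset | None = None
    seed: int = 0
    params: StageParams = field(default_factory=StageParams)

    # stage outputs
    adjusted: pd.DataFrame | None = None
    block_fits: dict = field(default_factory=dict)
    pop_means: pd.DataFrame | None = None
    grm: pd.DataFrame | None = None
    freqs: pd.DataFrame | None = None          # ALT-allele frequencies
    freq_n: pd.DataFrame | None = None
    omega: pd.DataFrame | None = None
    omega_chains: list = field(default_factory=list)
    gpa_results: dict = field(default_factory=dict)      # trait -> results df
    gpa_candidates: dict = field(default_factory=dict)   # trait -> CandidateSet
    gea_scores: dict = field(default_factory=dict)       # var -> scores df
    gea_candidates: dict = field(default_factory=dict)   # var -> GEACandidateSet
    gea_top: dict = field(default_factory=dict)          # var -> top-N loci
    curves: pd.DataFrame | None = None
    threshold: varexp_mod.ClimateAssocThreshold | None = None
    climate_associated: dict = field(default_factory=dict)  # trait -> loci
    driver_rankings: dict = field(default_factory=dict)
    congruence: dict = field(default_factory=dict)
    cline_models: dict = field(default_factory=dict)
    cline_extents: dict = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c not in DESIGN_COLS]

    @property
    def climate_variables(self) -> list[str]:
        return [c for c in self.climate.columns if c != "population"]

    def minor_freqs(self, loci: list[str]) -> pd.DataFrame:
        """Minor-allele view of the population frequency table."""
        f = self.freqs[loci]
        flip = (f.mean(axis=0) > 0.5).to_numpy()
        out = f.copy()
        out.loc[:, flip] = 1.0 - out.loc[:, flip]
        return out

    def pea_freqs(self, trait: str, loci: list[str]) -> pd.DataFrame:
        """PEA view: flip columns where the PEA is the REF allele."""
        res = self.gpa_results[trait].set_index("locus")
        f = self.freqs[loci]
        # unscanned loci (NaN) keep the ALT orientation
        flip = res["pea_is_alt"].reindex(loci).eq(False).to_numpy()
        out = f.copy()
        out.loc[:, flip] = 1.0 - out.loc[:, flip]
        return out


def build_state(cfg: RunConfig) -> PipelineState:
    """Simulate (if a truth config is given) or load inputs from disk."""
    cfg.validate()
    if cfg.truth is not None:
        ds = generate_dataset(cfg.truth)
        state = PipelineState(genotypes=ds.genotypes, panel=ds.panel,
                              climate=ds.climate, phenotypes=ds.phenotypes,
                              pop_map=ds.pop_map,
                              field_heights=ds.field_heights, truth=ds,
                              seed=cfg.seed, params=cfg.params)
    else:
        d = Path(cfg.input_dir)
        genotypes = read_genotype_matrix(d / "genotypes.tsv")
        panel = read_population_panel(d / "panel.csv")
        climate = read_climate_table(d / "climate.csv")
        phenotypes = read_phenotype_table(d / "phenotypes.csv")
        heights_path = d / "field_heights.csv"
        heights = pd.read_csv(heights_path) if heights_path.exists() else None
        pop_map = pd.Series(phenotypes["population"].to_numpy(),
                            index=phenotypes["individual"].astype(str),
                            name="population")
        state = PipelineState(genotypes=genotypes, panel=panel,
                              climate=climate, phenotypes=phenotypes,
                              pop_map=pop_map, field_heights=heights,
                              seed=cfg.seed, params=cfg.params)
    report = validate_dataset(state.genotypes, state.panel, state.climate,
                              state.phenotypes)
    if not report.ok:
        raise ValueError("dataset validation failed: " + "; ".join(report.errors))
    state.genotypes = filter_maf(state.genotypes, cfg.params.maf_threshold)
    return state


def stage_adjust(state: PipelineState) -> PipelineState:
    state.adjusted, state.block_fits = pheno_mod.adjust_all_traits(
        state.phenotypes, state.traits)
    means = {}
    for t in state.traits:
        sub = state.adjusted[state.adjusted["trait"] == t]
        means[t] = pheno_mod.population_means(sub, state.panel)
    state.pop_means = pd.DataFrame(means)
    state.pop_means.index.name = "population"
    return state


def stage_structure(state: PipelineState) -> PipelineState:
    p = state.params
    control = state.genotypes.by_class("control")
    state.grm = structure_mod.compute_grm(control)
    state.freqs, state.freq_n = structure_mod.pop_allele_frequencies(
        state.genotypes, state.pop_map)
    ctrl_ids = [l for l in control.locus_ids]
    state.omega, state.omega_chains = structure_mod.estimate_pop_covariance(
        state.freqs[ctrl_ids], state.freq_n[ctrl_ids],
        n_runs=p.n_chains, seed=state.seed + 101)
    return state


def stage_gpa(state: PipelineState) -> PipelineState:
    p = state.params
    cand = state.genotypes.by_class("candidate")
    for t in state.traits:
        sub = state.adjusted[state.adjusted["trait"] == t]
        y = pd.Series(sub["residual"].to_numpy(),
                      index=sub["individual"].astype(str))
        res = gpa_mod.mlma_scan(cand, y, state.grm)
        res = gpa_mod.polarize_pea(res)
        dedup = gpa_mod.reduce_one_per_contig(res)
        state.gpa_results[t] = res
        state.gpa_candidates[t] = gpa_mod.select_candidates(
            dedup, fraction=p.gpa_fraction, trait=t)
    return state


def stage_gea(state: PipelineState) -> PipelineState:
    p = state.params
    cand = state.genotypes.by_class("candidate")
    cand_ids = [l for l in cand.locus_ids]
    contig_of = cand.loci.set_index("locus")["contig"]
    scores = gea_mod.score_env_associations_multi(
        state.freqs[cand_ids], state.omega_chains, state.climate,
        state.climate_variables, tau_grid=p.tau_grid)
    for v, sc in scores.items():
        dedup = gea_mod.reduce_one_per_contig_gea(sc, contig_of)
        state.gea_scores[v] = dedup
        state.gea_candidates[v] = gea_mod.dual_rank_filter(
            dedup, k=p.gea_top_k, variable=v)
        state.gea_top[v] = gea_mod.top_n_by_rank(dedup, n=p.gea_top_n)
    return state


def stage_varexp(state: PipelineState) -> PipelineState:
    p = state.params
    geo = state.panel.set_index("population")[["latitude", "longitude",
                                               "elevation"]]
    clim = state.climate.set_index("population")
    control_ids = [l for l in state.genotypes.by_class("control").locus_ids]
    cand_ids = [l for l in state.genotypes.by_class("candidate").locus_ids]
    gea_pool = sorted({l for locs in state.gea_top.values() for l in locs})

    state.threshold = varexp_mod.calibrate_threshold(
        state.freqs[control_ids], state.climate,
        percentile=p.threshold_percentile, n_pcs=p.climate_pcs)

    curves = []
    for t in state.traits:
        y = state.pop_means[t]
        gpa_loci = state.gpa_candidates[t].loci
        state.climate_associated[t] = varexp_mod.select_climate_associated(
            gpa_loci, state.freqs, state.climate,
            threshold=state.threshold.threshold, n_pcs=p.climate_pcs)
        sets = {
            "geography": geo,
            "climate": clim,
            "full_array": state.minor_freqs(cand_ids),
            "control": state.minor_freqs(control_ids),
            "gpa": state.minor_freqs(gpa_loci),
            "gea": state.minor_freqs(gea_pool) if gea_pool else None,
            "gpa_climate_associated":
                (state.minor_freqs(state.climate_associated[t])
                 if len(state.climate_associated[t]) >= 2 else None),
        }
        for label, table in sets.items():
            if table is None:
                continue
            m_max = min(10, min(table.shape))
            curves.append(varexp_mod.cv_r2_curve(
                y, table, m_max=m_max, folds=p.cv_folds,
                seed=state.seed + 7, label=label, trait=t).as_frame())
        for s, subset in enumerate(varexp_mod.rarefy_control(
                control_ids, subsample_size=min(p.rarefaction_size,
                                                len(control_ids)),
                seed=state.seed + 13)):
            curves.append(varexp_mod.cv_r2_curve(
                y, state.minor_freqs(subset), m_max=6, folds=p.cv_folds,
                seed=state.seed + 7, label=f"control_rarefied_{s}",
                trait=t).as_frame())
    state.curves = pd.concat(curves, ignore_index=True)
    return state


def stage_drivers(state: PipelineState) -> PipelineState:
    p = state.params
    variables = state.climate_variables
    genomic_pred = {v: state.minor_freqs(state.gea_top[v])
                    for v in variables}
    state.driver_rankings["genomic"] = drivers_mod.rank_drivers(
        state.climate, variables, genomic_pred, n_pcs=p.driver_pcs,
        folds=p.cv_folds, seed=state.seed + 23, source="genomic")
    state.driver_rankings["seedling_phenotypes"] = drivers_mod.rank_drivers(
        state.climate, variables, state.pop_means, n_pcs=None,
        folds=p.cv_folds, seed=state.seed + 23, source="seedling_phenotypes")
    if state.field_heights is not None:
        heights = state.field_heights.set_index("population")
        state.driver_rankings["field_heights"] = drivers_mod.rank_drivers(
            state.climate, variables, heights, n_pcs=None,
            folds=p.cv_folds, seed=state.seed + 23, source="field_heights")
        state.driver_rankings["field_heights_quadratic"] = (
            drivers_mod.rank_drivers_quadratic(
                state.climate, variables, state.field_heights))
    pairs = [("genomic", "seedling_phenotypes"),
             ("genomic", "field_heights")]
    for a, b in pairs:
        if a in state.driver_rankings and b in state.driver_rankings:
            state.congruence[f"{a}_vs_{b}"] = drivers_mod.congruence(
                state.driver_rankings[a], state.driver_rankings[b])
    return state


def stage_clines(state: PipelineState, trait: str | None = None) -> PipelineState:
    p = state.params
    traits = [trait] if trait else state.traits
    env = (state.truth.env if state.truth is not None
           else state.climate.set_index("population").iloc[:, 0]
           .reindex(state.freqs.index).to_numpy())
    for t in traits:
        loci = state.climate_associated.get(t) or state.gpa_candidates[t].loci
        k = min(p.kmeans_k, max(1, len(loci)))
        if len(loci) < 2:
            log.warning("trait %s has %d climate-associated loci; skipping "
                        "cline clustering", t, len(loci))
            continue
        pea = state.pea_freqs(t, loci)
        model = clines_mod.cluster_snps(pea, k=k, seed=state.seed + 31,
                                        n_init=p.kmeans_n_init)
        restored = clines_mod.restore_variance(model)
        he = clines_mod.expected_heterozygosity(pea)
        prop = clines_mod.proportional_polymorphism(he, model)
        extents = clines_mod.classify_extent(restored, env,
                                             span_fraction=p.span_fraction)
        state.cline_models[t] = {"model": model, "restored": restored,
                                 "he": he, "prop_poly": prop}
        state.cline_extents[t] = extents
    return state


STAGES = ["adjust", "structure", "gpa", "gea", "varexp", "drivers", "clines"]


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> PipelineState:
    """Run the requested stages (all by default) in order."""
    state = build_state(cfg)
    todo = STAGES if stages is None else stages
    fns = {"adjust": stage_adjust, "structure": stage_structure,
           "gpa": stage_gpa, "gea": stage_gea, "varexp": stage_varexp,
           "drivers": stage_drivers, "clines": stage_clines}
    done = set()
    requires = {"structure": [], "adjust": [], "gpa": ["adjust", "structure"],
                "gea": ["structure"], "varexp": ["adjust", "structure",
                                                 "gpa", "gea"],
                "drivers": ["adjust", "structure", "gea", "varexp"],
                "clines": ["adjust", "structure", "gpa", "varexp"]}
    for name in STAGES:
        if name not in todo:
            continue
        missing = [r for r in requires[name] if r not in done and r not in todo]
        if missing:
            raise ValueError(f"stage {name!r} requires prior stage(s) {missing}; "
                             "run them first or use 'all'")
        fns[name](state)
        done.add(name)
    return state


def write_artifacts(state: PipelineState, out_dir: str | Path,
                    config_hash: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash, "seed": state.seed,
                "n_individuals": state.genotypes.n_individuals,
                "n_loci": state.genotypes.n_loci, "artifacts": []}

    def _save(df: pd.DataFrame, name: str, **kw):
        df.to_csv(out / name, sep="\t", **kw)
        manifest["artifacts"].append(name)

    if state.adjusted is not None:
        _save(state.adjusted, "adjusted_phenotypes.tsv", index=False)
        _save(state.pop_means, "population_means.tsv")
    if state.grm is not None:
        _save(state.grm, "grm.tsv")
        _save(state.omega, "omega.tsv")
    for t, res in state.gpa_results.items():
        cand = set(state.gpa_candidates[t].loci)
        res = res.assign(candidate=res["locus"].isin(cand))
        _save(res, f"gpa_{t}.tsv", index=False)
    for v, sc in state.gea_scores.items():
        cand = set(state.gea_candidates[v].loci)
        sc = sc.assign(candidate=sc["locus"].isin(cand))
        _save(sc, f"gea_{v}.tsv", index=False)
    if state.curves is not None:
        _save(state.curves, "varexp_curves.tsv", index=False)
        with open(out / "climate_threshold.json", "w") as fh:
            json.dump(state.threshold.summary(), fh, indent=1)
        manifest["artifacts"].append("climate_threshold.json")
    if state.driver_rankings:
        _save(pd.concat(state.driver_rankings.values(), ignore_index=True),
              "driver_rankings.tsv", index=False)
        with open(out / "congruence.json", "w") as fh:
            json.dump({k: vars(v) for k, v in state.congruence.items()},
                      fh, indent=1)
        manifest["artifacts"].append("congruence.json")
    for t, bundle in state.cline_models.items():
        _save(bundle["model"].assignment.to_frame(), f"clusters_{t}.tsv")
        _save(bundle["restored"], f"restored_clines_{t}.tsv")
        _save(bundle["prop_poly"], f"prop_poly_{t}.tsv")
        with open(out / f"cline_extent_{t}.json", "w") as fh:
            json.dump([vars(e) for e in state.cline_extents[t]], fh, indent=1)
        manifest["artifacts"].append(f"cline_extent_{t}.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
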