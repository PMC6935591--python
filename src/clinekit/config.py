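"""Configuration objects for simulation and pipeline runs.

Everything that introduces randomness carries an explicit seed; everything
tunable is a dataclass field so runs are reproducible from a single YAML
file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

#: The 19 bioclimatic variables used throughout (ClimateNA abbreviations).
CLIMATE_VARS = [
    "MAT", "MWMT", "MCMT", "TD", "MAP", "MSP", "AHM", "SHM", "DD_0",
    "DD5", "NFFD", "FFP", "bFFP", "eFFP", "PAS", "EMT", "EXT", "Eref",
    "CMD",
]


@dataclass
class ClineGroup:
    """A group of loci sharing a planted logistic allele-frequency cline.

    ``kind`` is ``"rangewide"`` when the frequency transition spans most of
    the environmental gradient and ``"localized"`` when it is confined to a
    narrow sub-interval.
    """

    group_id: str
    n_loci: int
    kind: str  # "rangewide" | "localized"
    center: float
    width: float
    p_lo: float
    p_hi: float
    # Relative jitter applied per locus to center/width/levels so member
    # loci are similar but not identical clines.
    jitter: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lo < self.p_hi <= 1.0):
            raise ValueError("require 0 <= p_lo < p_hi <= 1")
        if self.width <= 0:
            raise ValueError("cline width must be positive")
        if self.kind not in ("rangewide", "localized"):
            raise ValueError(f"unknown cline kind {self.kind!r}")


@dataclass
class TraitSpec:
    """An additive polygenic trait measured in the common garden."""

    name: str
    causal_group_ids: list[str]
    effect_size: float = 0.2  # per PEA copy, trait units
    sigma_block: float = 0.7  # SD of block random effect
    sigma_loc: float = 0.5    # SD of location-within-block effect
    sigma_e: float = 1.0      # residual SD


@dataclass
class TruthConfig:
    """Ground truth for a synthetic common-garden + genotyping study.

    Defaults emulate the study conditions the pipeline targets: ~280
    populations spread along a one-dimensional thermal gradient (a proxy
    for mean annual temperature, in deg C), weak neutral structure, a few
    thousand control and candidate SNPs, and blocked common-garden
    phenotypes.
    """

    n_pops: int = 280
    n_per_pop: int = 10
    env_lo: float = -4.0
    env_hi: float = 8.0
    n_control_loci: int = 4000
    n_neutral_candidate_loci: int = 3880
    cline_groups: list[ClineGroup] = field(default_factory=lambda: [
        ClineGroup("rw1", 40, "rangewide", center=0.0, width=2.5,
                   p_lo=0.02, p_hi=0.98),
        ClineGroup("rw2", 40, "rangewide", center=4.0, width=2.5,
                   p_lo=0.02, p_hi=0.98),
        ClineGroup("loc1", 40, "localized", center=2.0, width=0.4,
                   p_lo=0.02, p_hi=0.98),
    ])
    traits: list[TraitSpec] = field(default_factory=lambda: [
        TraitSpec("growth_initiation", ["rw1"]),
        TraitSpec("growth_cessation", ["rw1", "rw2"]),
        TraitSpec("cold_injury", ["rw1", "rw2", "loc1"]),
        TraitSpec("shoot_mass", ["rw2", "loc1"]),
    ])
    n_blocks: int = 20
    n_locs_per_block: int = 5
    fst_neutral: float = 0.016
    n_climate_vars: int = 19
    climate_noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 3:
            raise ValueError("need at least 3 populations")
        if not (0.0 < self.fst_neutral < 1.0):
            raise ValueError("fst_neutral must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_climate_vars < 2:
            raise ValueError("need at least 2 climate variables")
        for t in self.traits:
            if min(t.sigma_block, t.sigma_loc, t.sigma_e) < 0:
                raise ValueError("trait variance parameters must be >= 0")
        ids = [g.group_id for g in self.cline_groups]
        if len(set(ids)) != len(ids):
            raise ValueError("cline group ids must be unique")

    @property
    def env(self) -> np.ndarray:
        """Per-population environmental gradient (monotone, evenly spaced)."""
        return np.linspace(self.env_lo, self.env_hi, self.n_pops)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthConfig":
        d = dict(d)
        d["cline_groups"] = [ClineGroup(**g) for g in d.get("cline_groups", [])]
        d["traits"] = [TraitSpec(**t) for t in d.get("traits", [])]
        return cls(**d)


@dataclass
class StageParams:
    """Tunables for the analysis stages, in paper order."""

    maf_threshold: float = 0.01
    gpa_fraction: float = 0.01          # bottom-1% candidate rule
    gea_top_k: int = 300                # dual-rank filter depth
    gea_top_n: int = 300                # top-N loci fed to driver PCs
    n_chains: int = 3                   # Omega bootstrap "chains"
    tau_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    cv_folds: int = 5
    climate_pcs: int = 5                # PCs for the climate-association filter
    driver_pcs: int = 4                 # PCs of GEA frequencies per variable
    threshold_percentile: float = 99.7  # control-calibrated R2 percentile
    rarefaction_size: int = 186
    kmeans_k: int = 6
    kmeans_n_init: int = 50
    span_fraction: float = 0.5          # localized/rangewide boundary

    def validate(self) -> None:
        if not (0.0 < self.gpa_fraction < 1.0):
            raise ValueError("gpa_fraction must lie in (0, 1)")
        if not (0.0 <= self.maf_threshold <= 0.5):
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if self.cv_folds < 1 or self.kmeans_k < 1 or self.gea_top_k < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.threshold_percentile <= 100.0):
            raise ValueError("percentile must lie in [0, 100]")


@dataclass
class RunConfig:
    """A full pipeline run: simulation truth (or input paths) + stage params."""

    truth: Optional[TruthConfig] = None
    input_dir: Optional[str] = None
    params: StageParams = field(default_factory=StageParams)
    seed: int = 0
    out_dir: str = "clinekit_out"

    def validate(self) -> None:
        self.params.validate()
        if self.truth is None and self.input_dir is None:
            raise ValueError("need either a simulation truth config or input_dir")

    def config_hash(self) -> str:
        payload = {
            "truth": self.truth.to_dict() if self.truth else None,
            "input_dir": self.input_dir,
            "params": asdict(self.params),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        truth = TruthConfig.from_dict(raw["truth"]) if raw.get("truth") else None
        params = StageParams(**raw.get("params", {}))
        cfg = cls(truth=truth, input_dir=raw.get("input_dir"), params=params,
                  seed=int(raw.get("seed", 0)),
                  out_dir=raw.get("out_dir", "clinekit_out"))
        cfg.validate()
        return cfg
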