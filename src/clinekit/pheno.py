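"""Removal of common-garden design effects from raw phenotypes.

Raw trait values are modelled with a linear mixed model in which the
experimental block and the seedling location nested within block are
random intercepts:

    Y_ijk = mu + B_j + L(B)_jk + e_ijk

Variance components are estimated by REML and the design effects are
removed by subtracting the BLUPs; the residuals are then z-standardized
across all measured individuals of the trait, which is the phenotype
representation every downstream association uses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    mu: float
    sigma2_block: float
    sigma2_loc: float
    sigma2_e: float

    def __post_init__(self) -> None:
        for v in (self.sigma2_block, self.sigma2_loc, self.sigma2_e):
            if v < -1e-12:
                raise ValueError("variance components must be non-negative")


@dataclass
class BlockModelResults:
    """Fitted design-effect model for one trait."""

    trait: str
    components: VarianceComponents
    block_blup: pd.Series          # block id -> predicted random effect
    loc_blup: pd.Series            # location id -> predicted random effect
    converged: bool
    degenerate: bool = False       # single-block fallback used


class BlockEffectsModel:
    """Two-level nested random-intercept model for one trait.

    Parameters
    ----------
    phenotypes : DataFrame with columns individual, block, location and the
        trait column; rows with a missing trait value are dropped (traits
        measured on a subset of seedlings are fitted on available rows).
    trait : name of the trait column.
    """

    def __init__(self, phenotypes: pd.DataFrame, trait: str) -> None:
        cols = {"individual", "block", "location", trait}
        missing = cols - set(phenotypes.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
        self.data = phenotypes.dropna(subset=[trait]).copy()
        self.trait = trait

    def fit(self, maxiter: int = 200) -> BlockModelResults:
        df = self.data
        trait = self.trait
        if df["block"].nunique() < 2:
            log.warning("singular design (<2 blocks) for %s: residual-only model",
                        trait)
            mu = float(df[trait].mean())
            comp = VarianceComponents(mu, 0.0, 0.0, float(df[trait].var(ddof=1)))
            return BlockModelResults(trait, comp, pd.Series(dtype=float),
                                     pd.Series(dtype=float), True, degenerate=True)
        df = df.rename(columns={trait: "_y"})
        model = smf.mixedlm("_y ~ 1", df, groups="block", re_formula="1",
                            vc_formula={"loc": "0 + C(location)"})
        # Gradient-based fits can stall off the optimum when a variance
        # component is near its zero boundary; also try a derivative-free
        # optimizer and keep whichever restricted likelihood is higher.
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, "powell"):
                kw = {"method": method} if method else {}
                try:
                    cand = model.fit(reml=True, maxiter=maxiter, **kw)
                except Exception:  # noqa: BLE001 - fall through to next method
                    continue
                if res is None or float(cand.llf) > float(res.llf):
                    res = cand
        if res is None:
            raise RuntimeError(f"mixed-model fit failed for trait {trait!r}")
        comp = VarianceComponents(
            mu=float(res.params["Intercept"]),
            sigma2_block=max(float(res.cov_re.iloc[0, 0]), 0.0),
            sigma2_loc=max(float(res.vcomp[0]), 0.0) if len(res.vcomp) else 0.0,
            sigma2_e=float(res.scale),
        )
        block_blup, loc_blup = {}, {}
        for blk, re in res.random_effects.items():
            block_blup[blk] = float(re.iloc[0])
            for label, val in re.iloc[1:].items():
                # label looks like "loc[C(location)[<id>]]"
                loc_id = label.split("[")[-1].rstrip("]")
                loc_blup[loc_id] = float(val)
        return BlockModelResults(trait, comp,
                                 pd.Series(block_blup, dtype=float),
                                 pd.Series(loc_blup, dtype=float),
                                 bool(res.converged))


def fit_block_model(phenotypes: pd.DataFrame, trait: str) -> BlockModelResults:
    """Convenience wrapper: build and fit :class:`BlockEffectsModel`."""
    return BlockEffectsModel(phenotypes, trait).fit()


def adjusted_phenotypes(phenotypes: pd.DataFrame,
                        fit: BlockModelResults) -> pd.DataFrame:
    """Design-corrected, z-standardized residuals for one trait.

    residual = Y - mu - BLUP(block) - BLUP(location), standardized to mean
    0 / SD 1 across all measured individuals.
    """
    trait = fit.trait
    df = phenotypes.dropna(subset=[trait])
    y = df[trait].to_numpy(dtype=float)
    b = df["block"].map(fit.block_blup).fillna(0.0).to_numpy()
    l = df["location"].map(fit.loc_blup).fillna(0.0).to_numpy()
    resid = y - fit.components.mu - b - l
    sd = resid.std(ddof=0)
    z = (resid - resid.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame({"individual": df["individual"].to_numpy(),
                         "population": df["population"].to_numpy()
                         if "population" in df else None,
                         "trait": trait, "residual": z})


def population_means(adjusted: pd.DataFrame,
                     panel: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of adjusted residuals per population for one trait.

    Populations with no phenotyped individuals are absent (NaN), never zero.
    """
    means = adjusted.groupby("population")["residual"].mean()
    return means.reindex(panel["population"].astype(str).to_numpy())


def adjust_all_traits(phenotypes: pd.DataFrame,
                      traits: list[str]) -> tuple[pd.DataFrame, dict]:
    """Fit, residualize, and stack all traits; returns (long table, fits)."""
    frames, fits = [], {}
    for t in traits:
        fit = fit_block_model(phenotypes, t)
        fits[t] = fit
        frames.append(adjusted_phenotypes(phenotypes, fit))
    return pd.concat(frames, ignore_index=True), fits
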