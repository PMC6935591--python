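"""Ranking climatic drivers of local adaptation and source congruence.

For each climate variable the roles reverse relative to the
variance-explained analysis: the climate variable is the response, and the
predictors come from one of three sources — principal components of the
population-mean minor-allele frequencies of that variable's top GEA loci
(genomic mode), population-mean standardized seedling phenotypes
(phenotypic mode, used directly without PCA), or provenance-trial heights
at several field sites. Congruence between two sources is the correlation
of their per-variable R^2 vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .structure import principal_components
from .varexp import cv_r2


def driver_r2(climate_values: pd.Series, predictors: pd.DataFrame,
              n_pcs: int | None = None, folds: int = 5, seed: int = 0) -> float:
    """CV R^2 of one climate variable against a predictor table.

    With ``n_pcs`` set, the predictors are reduced to that many principal
    components first (genomic mode); with ``n_pcs=None`` the columns are
    used directly (phenotypic / field-height mode).
    """
    common = climate_values.index.intersection(predictors.index)
    y = climate_values.loc[common].to_numpy(dtype=float)
    tab = predictors.loc[common]
    if n_pcs is not None:
        pcs = principal_components(tab, standardize=False, m=n_pcs)
        X = pcs.scores.to_numpy()
    else:
        X = tab.to_numpy(dtype=float)
    return cv_r2(y, X, folds=folds, seed=seed)


def rank_drivers(climate: pd.DataFrame, variables: list[str],
                 predictors_for: dict[str, pd.DataFrame] | pd.DataFrame,
                 n_pcs: int | None = 4, folds: int = 5,
                 seed: int = 0, source: str = "") -> pd.DataFrame:
    """Per-variable driver R^2 for one data source.

    ``predictors_for`` is either a single table shared by all variables
    (phenotype or height mode) or a dict mapping variable -> table (genomic
    mode, where each variable has its own top GEA loci).
    """
    clim = climate.set_index("population") if "population" in climate else climate
    rows = []
    for v in variables:
        tab = (predictors_for[v] if isinstance(predictors_for, dict)
               else predictors_for)
        r2 = driver_r2(clim[v], tab, n_pcs=n_pcs, folds=folds, seed=seed)
        rows.append({"variable": v, "source": source, "r2_cv": r2})
    out = pd.DataFrame(rows)
    out["rank"] = out["r2_cv"].rank(ascending=False, method="first").astype(int)
    return out


def quadratic_height_r2(heights: pd.DataFrame, climate_values: pd.Series,
                        sites: list[str] | None = None) -> float:
    """Mean adjusted R^2 of quadratic height~climate fits across trial sites.

    Per site: OLS of population-mean height on [x, x^2];
    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 3). The reported value is the
    mean over sites; sites with n <= 3 populations are an error because the
    adjustment's denominator vanishes.
    """
    h = heights.set_index("population") if "population" in heights else heights
    sites = sites or list(h.columns)
    vals = []
    for site in sites:
        sub = pd.concat([h[site], climate_values], axis=1, join="inner").dropna()
        n = len(sub)
        if n <= 3:
            raise ValueError(f"site {site!r} has n={n} <= 3 populations; "
                             "adjusted R^2 undefined")
        x = sub.iloc[:, 1].to_numpy(dtype=float)
        y = sub.iloc[:, 0].to_numpy(dtype=float)
        A = np.column_stack([np.ones(n), x, x**2])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = np.sum((y - A @ coef) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        vals.append(1.0 - (1.0 - r2) * (n - 1) / (n - 3))
    return float(np.mean(vals))


def rank_drivers_quadratic(climate: pd.DataFrame, variables: list[str],
                           heights: pd.DataFrame,
                           source: str = "field_heights") -> pd.DataFrame:
    """Per-variable mean adjusted quadratic R^2 across field sites."""
    clim = climate.set_index("population") if "population" in climate else climate
    rows = [{"variable": v, "source": source,
             "r2_cv": quadratic_height_r2(heights, clim[v])}
            for v in variables]
    out = pd.DataFrame(rows)
    out["rank"] = out["r2_cv"].rank(ascending=False, method="first").astype(int)
    return out


@dataclass
class CongruenceStats:
    source_a: str
    source_b: str
    pearson_r: float
    spearman_r: float
    n_variables: int


def congruence(ranking_a: pd.DataFrame,
               ranking_b: pd.DataFrame) -> CongruenceStats:
    """Correlation of two per-variable R^2 vectors across climate variables."""
    a = ranking_a.set_index("variable")["r2_cv"]
    b = ranking_b.set_index("variable")["r2_cv"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared climate variables")
    av, bv = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    pear = float(stats.pearsonr(av, bv).statistic)
    spear = float(stats.spearmanr(av, bv).statistic)
    return CongruenceStats(
        source_a=str(ranking_a["source"].iloc[0]) if "source" in ranking_a else "a",
        source_b=str(ranking_b["source"].iloc[0]) if "source" in ranking_b else "b",
        pearson_r=pear, spearman_r=spear, n_variables=len(common))
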