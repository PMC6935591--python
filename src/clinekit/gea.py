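"""Genotype-environment association under an allele-frequency covariance model.

Each locus's standardized population-frequency vector x is scored against a
centered/standardized environmental variable e with a Gaussian
marginal-likelihood ratio: the alternative adds an environmental effect
beta ~ N(0, tau^2), so

    BF = N(x; 0, Omega + tau^2 e e') / N(x; 0, Omega),

averaged over a grid of prior scales tau, which is exact and closed-form
once both sides are whitened by the Cholesky factor of Omega. A
nonparametric rank correlation (rho) between the whitened frequency vector
and the whitened environment accompanies the BF. "Chains" are independent
bootstrap estimates of Omega; candidates must rank in the top K for BF and
for |rho| in every chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import logsumexp

log = logging.getLogger(__name__)

DEFAULT_TAU_GRID = (0.01, 0.1, 1.0)


def _whiten(omega: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Solve L z = v for the lower Cholesky factor L of omega."""
    try:
        L = linalg.cholesky(omega, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(
            "population covariance is not positive definite; "
            "re-estimate Omega with a larger ridge") from err
    return linalg.solve_triangular(L, vectors, lower=True)


def _standardize_env(values: pd.Series, pops: pd.Index) -> np.ndarray:
    e = values.loc[pops].to_numpy(dtype=float)
    if e.std(ddof=0) == 0:
        raise ValueError("climate variable has zero variance across populations")
    return (e - e.mean()) / e.std(ddof=0)


def bf_closed_form(x: np.ndarray, e: np.ndarray, omega: np.ndarray,
                   tau: float) -> float:
    """Exact Bayes factor N(x; 0, Omega + tau^2 e e') / N(x; 0, Omega).

    This is the marginal-likelihood ratio of x = beta*e + eta with
    beta ~ N(0, tau^2) against beta = 0, integrated in closed form. No
    scaling convention is applied to ``e`` here; callers choose one.
    """
    xw = _whiten(omega, np.asarray(x, dtype=float))
    ew = _whiten(omega, np.asarray(e, dtype=float))
    ee = float(ew @ ew)
    proj = float(ew @ xw)
    log_bf = (0.5 * tau**2 * proj**2 / (1.0 + tau**2 * ee)
              - 0.5 * np.log1p(tau**2 * ee))
    return float(np.exp(log_bf))


def _chain_scores(Xw: np.ndarray, ew: np.ndarray, taus: np.ndarray,
                  loci: np.ndarray, rx: np.ndarray, chain: int) -> pd.DataFrame:
    # Prior scales are per unit-norm whitened environment, so the BF's
    # null calibration does not depend on the number of populations.
    ew = ew / np.linalg.norm(ew)
    ee = float(ew @ ew)
    proj = ew @ Xw                               # e'_w x_w per locus
    with np.errstate(over="ignore"):
        lbf = (0.5 * (taus[:, None]**2 * proj[None, :]**2)
               / (1.0 + taus[:, None]**2 * ee)
               - 0.5 * np.log1p(taus[:, None]**2 * ee))
    log_bf = logsumexp(lbf, axis=0) - np.log(len(taus))
    re = stats.rankdata(ew)
    re = re - re.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (re**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, re @ rx / denom, 0.0)
    with np.errstate(over="ignore"):
        bf = np.exp(log_bf)
    return pd.DataFrame({"locus": loci, "chain": chain,
                         "log10_bf": log_bf / np.log(10.0),
                         "bf": bf, "rho": rho})


def score_env_associations_multi(freqs: pd.DataFrame,
                                 omegas: list[pd.DataFrame],
                                 climate: pd.DataFrame,
                                 variables: list[str],
                                 tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID,
                                 ) -> dict[str, pd.DataFrame]:
    """Score every climate variable, whitening the frequency table once per
    chain (the expensive step is shared across variables)."""
    from .structure import standardize_frequencies

    clim = climate.set_index("population") if "population" in climate else climate
    x = standardize_frequencies(freqs)
    loci = x.columns.to_numpy()
    X = x.to_numpy()
    taus = np.asarray(tau_grid, dtype=float)
    per_var: dict[str, list[pd.DataFrame]] = {v: [] for v in variables}
    for chain, omega in enumerate(omegas, start=1):
        om = omega.loc[freqs.index, freqs.index].to_numpy()
        Xw = _whiten(om, X)
        rx = stats.rankdata(Xw, axis=0)
        rx = rx - rx.mean(axis=0)
        for v in variables:
            e = _standardize_env(clim[v], freqs.index)
            ew = _whiten(om, e)
            per_var[v].append(_chain_scores(Xw, ew, taus, loci, rx, chain))
    return {v: pd.concat(frames, ignore_index=True)
            for v, frames in per_var.items()}


def score_env_associations(freqs: pd.DataFrame, omegas: list[pd.DataFrame],
                           climate_values: pd.Series,
                           tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID,
                           ) -> pd.DataFrame:
    """Per-locus x per-chain Bayes factor and whitened Spearman rho.

    Parameters
    ----------
    freqs : population x locus allele-frequency table.
    omegas : one population-covariance matrix per chain.
    climate_values : raw climate values indexed by population; standardized
        internally (constant variables are rejected).

    Returns a long DataFrame: locus, chain, log10_bf, bf, rho.
    """
    clim = climate_values.to_frame("_env")
    return score_env_associations_multi(freqs, omegas, clim, ["_env"],
                                        tau_grid)["_env"]


def rank_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-locus ranks: BF and |rho| per chain (1 = strongest) + their mean.

    Ranks are dense by construction because ties are broken by locus id.
    """
    chains = sorted(scores["chain"].unique())
    out = pd.DataFrame(index=pd.Index(sorted(scores["locus"].unique()),
                                      name="locus"))
    for ch in chains:
        sub = scores[scores["chain"] == ch]
        for col, label in (("log10_bf", "bf"), ("rho", "rho")):
            vals = sub[col].abs() if col == "rho" else sub[col]
            order = (pd.DataFrame({"locus": sub["locus"].to_numpy(),
                                   "v": vals.to_numpy()})
                     .sort_values(["v", "locus"], ascending=[False, True],
                                  kind="mergesort"))
            ranks = pd.Series(np.arange(1, len(order) + 1),
                              index=order["locus"].to_numpy())
            out[f"{label}_rank_c{ch}"] = ranks.reindex(out.index)
    out["mean_rank"] = out.mean(axis=1)
    return out


@dataclass
class GEACandidateSet:
    variable: str
    loci: list[str]          # ordered by mean rank
    k: int
    ranks: pd.DataFrame

    def __len__(self) -> int:
        return len(self.loci)


def dual_rank_filter(scores: pd.DataFrame, k: int = 300,
                     variable: str = "") -> GEACandidateSet:
    """Loci in the top-k for BF AND for |rho| in every chain.

    The intersection runs over 2 x n_chains top-k lists (BF and |rho| per
    chain); with k at or above the pool size every locus passes.
    """
    ranks = rank_table(scores)
    rank_cols = [c for c in ranks.columns if c != "mean_rank"]
    passing = (ranks[rank_cols] <= k).all(axis=1)
    sel = ranks[passing].sort_values(["mean_rank", "locus"], kind="mergesort")
    return GEACandidateSet(variable=variable, loci=sel.index.tolist(), k=k,
                           ranks=ranks)


def reduce_one_per_contig_gea(scores: pd.DataFrame,
                              contig_of: pd.Series) -> pd.DataFrame:
    """Keep, per contig, the locus with the best (smallest) mean of its
    2 x n_chains ranks; ties broken by locus id. Returns the score subset."""
    ranks = rank_table(scores)
    ranks = ranks.assign(contig=contig_of.reindex(ranks.index).to_numpy())
    ordered = ranks.sort_values(["mean_rank", "locus"], kind="mergesort")
    keep = set(ordered.reset_index().drop_duplicates("contig")["locus"])
    return scores[scores["locus"].isin(keep)].reset_index(drop=True)


def top_n_by_rank(scores: pd.DataFrame, n: int = 300) -> list[str]:
    """First ``n`` loci ordered by mean rank (deterministic tie-break)."""
    ranks = rank_table(scores).sort_values(["mean_rank", "locus"],
                                           kind="mergesort")
    if n > len(ranks):
        log.warning("requested top %d of a pool of %d loci", n, len(ranks))
    return ranks.index[:n].tolist()
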