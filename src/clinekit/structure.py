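"""Population-structure objects shared by the association scans.

Four primitives: a VanRaden genomic relationship matrix (GRM) from control
loci, population allele-frequency tables, the covariance of standardized
population allele frequencies (Omega, the null model of the environment
scan), and principal components of arbitrary predictor tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def _impute_mean(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Float copy with per-locus mean fill for missing; returns (X, alt freq)."""
    X = codes.astype(float)
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    sums = np.where(obs, X, 0.0).sum(axis=0)
    mean = np.divide(sums, n_obs, out=np.zeros_like(sums), where=n_obs > 0)
    X = np.where(obs, X, mean[None, :])
    p = mean / 2.0
    return X, p


def compute_grm(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden GRM: standardize each locus to variance 2p(1-p), GRM = ZZ'/L.

    Fixed loci (p in {0,1}) carry no information and are excluded; missing
    genotypes are mean-imputed per locus.
    """
    X, p = _impute_mean(genotypes.codes)
    keep = (p > 0.0) & (p < 1.0)
    if keep.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci for a GRM")
    X, p = X[:, keep], p[keep]
    Z = (X - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    K = Z @ Z.T / Z.shape[1]
    ids = list(genotypes.individuals)
    return pd.DataFrame(K, index=ids, columns=ids)


def pop_allele_frequencies(genotypes: GenotypeMatrix, pop_map: pd.Series,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population x locus ALT-allele frequencies and non-missing sample sizes.

    Returns (freqs, n) where ``freqs[pop, locus]`` = alt count / (2 x
    non-missing individuals), NaN when every individual is missing, and
    ``n`` counts non-missing individuals per cell. The ALT allele is the
    counted allele; the PEA or minor-allele view is obtained by flipping
    columns (p -> 1 - p) as needed.
    """
    pops = pop_map.loc[genotypes.individuals].to_numpy()
    codes = genotypes.codes
    obs = codes != MISSING
    upops = pd.unique(pops)
    freq = np.empty((len(upops), codes.shape[1]))
    nobs = np.empty_like(freq)
    for i, pop in enumerate(upops):
        rows = pops == pop
        c = codes[rows]
        o = obs[rows]
        n_k = o.sum(axis=0)
        alt = np.where(o, c, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq[i] = np.where(n_k > 0, alt / (2.0 * np.maximum(n_k, 1)), np.nan)
        nobs[i] = n_k
    idx = pd.Index(upops, name="population")
    cols = pd.Index(genotypes.locus_ids, name="locus")
    return (pd.DataFrame(freq, index=idx, columns=cols),
            pd.DataFrame(nobs, index=idx, columns=cols))


def standardize_frequencies(freqs: pd.DataFrame) -> pd.DataFrame:
    """x_l = (p_l - pbar_l) / sqrt(pbar_l (1 - pbar_l)) per locus.

    pbar is the across-population mean; loci fixed across all populations
    (pbar in {0,1}) are dropped. NaN cells are filled with the locus mean
    (i.e., standardized value 0).
    """
    pbar = freqs.mean(axis=0, skipna=True)
    keep = (pbar > 0) & (pbar < 1)
    f = freqs.loc[:, keep]
    pb = pbar[keep]
    x = (f - pb) / np.sqrt(pb * (1.0 - pb))
    return x.fillna(0.0)


def estimate_pop_covariance(freqs: pd.DataFrame, sample_sizes: pd.DataFrame,
                            n_runs: int = 3, n_boot_loci: int | None = None,
                            seed: int = 0, ridge: float | None = None,
                            ) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Omega: covariance of standardized control-locus frequencies.

    Each "run" (the analogue of an independent MCMC chain) recomputes the
    moment estimate on a bootstrap resample of control loci; the reported
    Omega is the average over runs. The diagonal is augmented by the mean
    binomial sampling variance 1/(2 n_k) on the standardized scale, plus a
    ridge for positive semi-definiteness.

    Returns (averaged Omega, per-run Omegas).
    """
    x = standardize_frequencies(freqs)
    P, L = x.shape
    if L < 50:
        log.warning("only %d usable control loci for Omega; estimate is noisy", L)
    if L < P:
        log.warning("fewer control loci (%d) than populations (%d); "
                    "raising ridge", L, P)
    rng = np.random.default_rng(seed)
    n_boot = L if n_boot_loci is None else min(n_boot_loci, L)
    X = x.to_numpy()
    # mean sampling variance of a standardized frequency per population
    with np.errstate(divide="ignore", invalid="ignore"):
        samp = (1.0 / (2.0 * sample_sizes.to_numpy(dtype=float)))
    samp_diag = np.nanmean(np.where(np.isfinite(samp), samp, np.nan), axis=1)
    runs = []
    for _ in range(n_runs):
        take = rng.integers(0, L, size=n_boot)
        Xi = X[:, take]
        omega = Xi @ Xi.T / n_boot
        omega[np.diag_indices_from(omega)] += samp_diag
        eps = ridge if ridge is not None else 1e-6 * np.trace(omega) / P
        if L < P:
            eps = max(eps, 1e-3 * np.trace(omega) / P)
        omega[np.diag_indices_from(omega)] += eps
        runs.append(pd.DataFrame(omega, index=freqs.index, columns=freqs.index))
    avg = sum(r.to_numpy() for r in runs) / n_runs
    return pd.DataFrame(avg, index=freqs.index, columns=freqs.index), runs


@dataclass
class PCResult:
    scores: pd.DataFrame                # observations x m
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame              # variables x m


def principal_components(table: pd.DataFrame, standardize: bool = True,
                         m: int | None = None) -> PCResult:
    """Column-centered (optionally unit-scaled) SVD principal components.

    Missing cells are mean-imputed; zero-variance columns are dropped with
    a warning. Sign convention: within each PC the loading of largest
    magnitude is made positive, so scores are deterministic.
    """
    X = table.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d zero-variance columns before PCA",
                    int((~keep).sum()))
    X = X[:, keep]
    cols = table.columns[keep]
    X = X - X.mean(axis=0)
    if standardize:
        X = X / X.std(axis=0, ddof=0)
    max_m = min(X.shape)
    m = max_m if m is None else min(m, max_m)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| element positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2 / max(X.shape[0] - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    names = [f"PC{j + 1}" for j in range(m)]
    scores = pd.DataFrame(U[:, :m] * s[:m], index=table.index, columns=names)
    loadings = pd.DataFrame(Vt[:m].T, index=cols, columns=names)
    return PCResult(scores, ratio[:m], loadings)
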