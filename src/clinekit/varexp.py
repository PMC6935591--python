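"""Cross-validated PC-regression comparison of predictor sets.

Population-mean phenotypes are regressed on increasing numbers of
principal components of a predictor table (geography, climate, or a
population x locus allele-frequency table). The PCs are computed once on
the full table; the reported statistic is the fivefold cross-validated R^2
pooled over held-out folds, R^2 = 1 - sum(SSE_heldout) / SST. With
``folds=1`` the same routine returns the training R^2, which at full PC
rank equals an ordinary least-squares fit on the original variables.

Also here: rarefaction of the control set into mutually exclusive
subsamples, and the control-calibrated climate-association threshold used
to pick the climate-associated subset of GPA candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import principal_components

log = logging.getLogger(__name__)


def _ols_predict(X_train, y_train, X_test) -> np.ndarray:
    A = np.column_stack([np.ones(len(X_train)), X_train])
    coef, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    return np.column_stack([np.ones(len(X_test)), X_test]) @ coef


def cv_r2(y: np.ndarray, X: np.ndarray, folds: int = 5,
          seed: int = 0) -> float:
    """Pooled k-fold cross-validated R^2 of an OLS fit of y on X.

    folds=1 is training mode: fit and evaluate on all observations.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    ok = np.isfinite(y)
    y, X = y[ok], X[ok]
    n = y.size
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return 0.0
    if folds <= 1:
        pred = _ols_predict(X, y, X)
        return 1.0 - np.sum((y - pred) ** 2) / sst
    if n < folds:
        log.warning("only %d observations; reducing folds from %d", n, folds)
        folds = n
    rng = np.random.default_rng(seed)
    assign = rng.permutation(n) % folds
    sse = 0.0
    for f in range(folds):
        test = assign == f
        pred = _ols_predict(X[~test], y[~test], X[test])
        sse += np.sum((y[test] - pred) ** 2)
    return 1.0 - sse / sst


@dataclass
class ExplainedVarianceCurve:
    label: str
    trait: str
    m: list[int] = field(default_factory=list)
    r2_cv: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"set": self.label, "trait": self.trait,
                             "m": self.m, "r2_cv": self.r2_cv})


def cv_r2_curve(response: pd.Series, predictors: pd.DataFrame,
                m_max: int | None = None, folds: int = 5, seed: int = 0,
                standardize: bool = True, label: str = "",
                trait: str = "") -> ExplainedVarianceCurve:
    """CV R^2 of the response against the first m PCs, for m = 1..m_max.

    ``response`` is a population-indexed series (population-mean
    phenotype); ``predictors`` rows must align with the same populations.
    """
    common = response.index.intersection(predictors.index)
    y = response.loc[common].to_numpy(dtype=float)
    pcs = principal_components(predictors.loc[common], standardize=standardize)
    scores = pcs.scores.to_numpy()
    rank = scores.shape[1]
    m_max = rank if m_max is None else min(m_max, rank)
    curve = ExplainedVarianceCurve(label=label, trait=trait)
    for m in range(1, m_max + 1):
        curve.m.append(m)
        curve.r2_cv.append(cv_r2(y, scores[:, :m], folds=folds, seed=seed))
    return curve


def rarefy_control(control_loci: list[str], subsample_size: int = 186,
                   seed: int = 0) -> list[list[str]]:
    """floor(pool/size) mutually exclusive subsets drawn without replacement."""
    pool = list(control_loci)
    if subsample_size > len(pool):
        raise ValueError("subsample size exceeds the control pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    n_sub = len(pool) // subsample_size
    return [[pool[i] for i in order[s * subsample_size:(s + 1) * subsample_size]]
            for s in range(n_sub)]


@dataclass
class ClimateAssocThreshold:
    threshold: float
    percentile: float
    control_r2: np.ndarray

    def summary(self) -> dict:
        q = np.percentile(self.control_r2, [50, 90, 99])
        return {"threshold": self.threshold, "percentile": self.percentile,
                "n_control": int(self.control_r2.size),
                "control_r2_median": float(q[0]),
                "control_r2_p90": float(q[1]), "control_r2_p99": float(q[2])}


def per_locus_climate_r2(freqs: pd.DataFrame, climate: pd.DataFrame,
                         n_pcs: int = 5) -> pd.Series:
    """Training R^2 of each locus's population frequency on climate PCs.

    The regression is an ordinary multiple linear regression of the
    population-mean allele frequency on the first ``n_pcs`` principal
    components of the climate table.
    """
    clim = climate.set_index("population") if "population" in climate else climate
    common = freqs.index.intersection(clim.index)
    pcs = principal_components(clim.loc[common], standardize=True,
                               m=n_pcs).scores.to_numpy()
    A = np.column_stack([np.ones(len(common)), pcs])
    F = freqs.loc[common].to_numpy(dtype=float)
    col_mean = np.nanmean(F, axis=0)
    inds = np.where(np.isnan(F))
    F[inds] = np.take(col_mean, inds[1])
    coef, *_ = np.linalg.lstsq(A, F, rcond=None)
    resid = F - A @ coef
    sse = (resid**2).sum(axis=0)
    sst = ((F - F.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    return pd.Series(r2, index=freqs.columns)


def calibrate_threshold(control_freqs: pd.DataFrame, climate: pd.DataFrame,
                        percentile: float = 99.7,
                        n_pcs: int = 5) -> ClimateAssocThreshold:
    """Climate-association R^2 threshold from the control-locus distribution.

    The threshold is the stated percentile of per-control-locus R^2 values
    against the first five climate PCs (the quantity the fixed 0.35 cutoff
    calibrates to).
    """
    if control_freqs.shape[1] < 100:
        log.warning("threshold calibrated on only %d control loci",
                    control_freqs.shape[1])
    r2 = per_locus_climate_r2(control_freqs, climate, n_pcs=n_pcs).to_numpy()
    return ClimateAssocThreshold(float(np.percentile(r2, percentile)),
                                 percentile, r2)


def select_climate_associated(candidate_loci: list[str], freqs: pd.DataFrame,
                              climate: pd.DataFrame, threshold: float = 0.35,
                              n_pcs: int = 5) -> list[str]:
    """GPA candidates whose frequency~climate-PC regression R^2 exceeds threshold."""
    present = [l for l in candidate_loci if l in freqs.columns]
    r2 = per_locus_climate_r2(freqs[present], climate, n_pcs=n_pcs)
    return [l for l in present if r2[l] > threshold]
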