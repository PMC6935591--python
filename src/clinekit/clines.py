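"""Allele-frequency cline structure: clustering, variance restoration,
standing variation, and rangewide-vs-localized classification.

SNPs are clustered by k-means on their absolute population PEA-frequency
profiles (loci are the observations, populations the variables), so
clusters gather SNPs with similar frequencies across populations — which is
deliberately different from correlation/LD clustering. Averaging member
clines shrinks their spread, so the cluster-mean cline is rescaled to the
mean across-population SD of its member SNPs. Standing variation is
summarized as expected heterozygosity He = 2p(1-p) and the proportion of
polymorphic member SNPs per population. Finally a 4-parameter logistic fit
labels each cluster cline rangewide, localized, or flat, depending on how
much of the environmental gradient its transition occupies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

log = logging.getLogger(__name__)

LN9 = float(np.log(9.0))  # expit moves 10% -> 90% over +-ln(9) widths


@dataclass
class ClineClusterModel:
    k: int
    assignment: pd.Series            # locus -> cluster id (0..k-1)
    cluster_mean: pd.DataFrame       # cluster x population mean PEA frequency
    member_sd: pd.Series             # cluster -> mean across-pop SD of members
    inertia: float
    silhouette: float | None = None

    def members(self, cluster: int) -> list[str]:
        return self.assignment.index[self.assignment == cluster].tolist()


def cluster_snps(pea_freqs: pd.DataFrame, k: int = 6, seed: int = 0,
                 n_init: int = 50) -> ClineClusterModel:
    """Euclidean k-means on loci-as-observations absolute frequency profiles.

    ``pea_freqs`` is population x locus; it is transposed internally so each
    SNP is one observation. Best of ``n_init`` seeded restarts by
    within-cluster SSE; cluster ids are relabeled by ascending grand-mean
    frequency so the labeling is deterministic.
    """
    mat = pea_freqs.T  # loci x populations
    if mat.isna().all(axis=1).any():
        raise ValueError("a locus has no observed frequency in any population")
    X = mat.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} loci to form k clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    # relabel by ascending grand-mean frequency of the cluster centroid
    order = np.argsort([c.mean() for c in km.cluster_centers_], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    assignment = pd.Series(labels, index=mat.index, name="cluster")
    mean = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(k)],
        index=pd.RangeIndex(k, name="cluster"), columns=pea_freqs.index)
    member_sd = pd.Series(
        [X[labels == c].std(axis=1, ddof=0).mean() for c in range(k)],
        index=mean.index, name="member_sd")
    sil = (float(silhouette_score(X, labels)) if 1 < k < X.shape[0] else None)
    return ClineClusterModel(k=k, assignment=assignment, cluster_mean=mean,
                             member_sd=member_sd, inertia=float(km.inertia_),
                             silhouette=sil)


def restore_variance(model: ClineClusterModel,
                     method: str = "deviation") -> pd.DataFrame:
    """Rescale cluster-mean clines to the spread of their member SNPs.

    ``deviation`` (default) rescales deviations from the cluster-mean's own
    across-population mean so the restored cline keeps the cluster's level
    but regains the members' mean across-population SD; the result is
    clipped to [0, 1]. ``literal`` multiplies the cluster-mean frequency by
    the mean member SD directly (kept as an option; it collapses the scale
    of the frequencies and is not the default).
    """
    m = model.cluster_mean
    if method == "literal":
        return (m.mul(model.member_sd, axis=0)).clip(0.0, 1.0)
    if method != "deviation":
        raise ValueError(f"unknown restoration method {method!r}")
    level = m.mean(axis=1)
    spread = m.std(axis=1, ddof=0)
    scale = model.member_sd / spread.where(spread > 0, np.inf)
    scale = scale.where(spread > 0, 1.0)  # flat mean cline: leave unchanged
    restored = m.sub(level, axis=0).mul(scale, axis=0).add(level, axis=0)
    return restored.clip(0.0, 1.0)


def expected_heterozygosity(freqs: pd.DataFrame) -> pd.DataFrame:
    """He = 2p(1-p) per population per locus; NaN frequencies stay NaN."""
    return 2.0 * freqs * (1.0 - freqs)


def proportional_polymorphism(he: pd.DataFrame,
                              model: ClineClusterModel) -> pd.DataFrame:
    """Fraction of a cluster's member SNPs with He > 0, per population.

    Missing He values are excluded from the denominator; a population where
    every member locus is missing gets a missing value.
    """
    out = {}
    for c in range(model.k):
        members = model.members(c)
        sub = he[members]
        poly = (sub > 0).sum(axis=1)
        denom = sub.notna().sum(axis=1)
        out[c] = poly / denom.replace(0, np.nan)
    res = pd.DataFrame(out)
    res.columns.name = "cluster"
    return res


@dataclass
class ClineExtent:
    cluster: int
    p0: float
    p1: float
    center: float
    width: float
    active_range: tuple[float, float]
    label: str                      # rangewide | localized | flat


def _logistic4(env, p0, p1, c, w):
    return p0 + (p1 - p0) * expit((env - c) / w)


def classify_extent(restored: pd.DataFrame, env: np.ndarray,
                    span_fraction: float = 0.5,
                    min_change: float = 0.1) -> list[ClineExtent]:
    """Fit a 4-parameter logistic to each cluster cline and label its extent.

    The active range is where the logistic moves from 10% to 90% of its
    total change (center +- width*ln 9), intersected with the observed env
    span. A cline is ``flat`` when its total change |p1 - p0| <= min_change,
    ``localized`` when the active range covers less than ``span_fraction``
    of the env span, otherwise ``rangewide``. Non-convergent fits are
    labeled flat with a warning.
    """
    env = np.asarray(env, dtype=float)
    if env.size < 4:
        raise ValueError("need at least 4 populations to fit a cline")
    lo, hi = float(env.min()), float(env.max())
    span = hi - lo
    out = []
    for cluster, row in restored.iterrows():
        y = row.to_numpy(dtype=float)
        ok = np.isfinite(y)
        try:
            guess_c = float(env[ok][np.argmin(np.abs(y[ok] - y[ok].mean()))])
            popt, _ = curve_fit(
                _logistic4, env[ok], y[ok],
                p0=[max(y[ok].min(), 0.0), min(y[ok].max(), 1.0),
                    guess_c, span / 4.0],
                bounds=([-0.5, -0.5, lo - span, 1e-3 * span],
                        [1.5, 1.5, hi + span, 10.0 * span]),
                maxfev=20000)
            p0_, p1_, c_, w_ = (float(v) for v in popt)
        except RuntimeError:
            log.warning("logistic fit did not converge for cluster %s; "
                        "labeling flat", cluster)
            m = float(np.nanmean(y))
            out.append(ClineExtent(int(cluster), m, m, 0.5 * (lo + hi), span,
                                   (lo, hi), "flat"))
            continue
        a_lo = max(c_ - w_ * LN9, lo)
        a_hi = min(c_ + w_ * LN9, hi)
        if a_hi <= a_lo:  # transition entirely outside the observed span
            a_lo, a_hi = lo, lo
        if abs(p1_ - p0_) <= min_change:
            label = "flat"
        elif (a_hi - a_lo) < span_fraction * span:
            label = "localized"
        else:
            label = "rangewide"
        out.append(ClineExtent(int(cluster), p0_, p1_, c_, w_,
                               (a_lo, a_hi), label))
    return out
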