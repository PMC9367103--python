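"""Multi-sample clonal clustering of mutation cellular prevalences.

Mutations are clustered jointly across timepoints on their clamped rVAF
(cellular prevalence) vectors with a finite binomial-mixture model fit
by expectation-maximization: cluster k has a prevalence parameter per
timepoint, and a mutation observed at depth d with prevalence x
contributes a binomial likelihood with x*d pseudo-successes.  The
number of clusters is selected by BIC over K = 1..k_max with random
restarts.  This is a deliberately desk-scale, deterministic stand-in
for Dirichlet-process samplers (PyClone-style) — sufficient for short
prevalence vectors over a handful of timepoints, and documented as a
stand-in rather than a reproduction.

Post-processing implements two display rules used for clonal-evolution
figures: single-mutation clusters are merged into the nearest
non-singleton cluster when every per-timepoint standardized distance
(z-score against the cluster's binomial standard error) lies within
[-1, +1], and clusters with fewer than three mutations are pruned from
display output while being retained in a removed list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

__all__ = [
    "BinomialMixtureClusterer",
    "ClusterModel",
    "cluster_mutations",
    "merge_singletons",
    "prune_small_clusters",
    "build_fishplot_table",
]

_EPS = 1e-6


class BinomialMixtureClusterer(BaseEstimator, ClusterMixin):
    """Finite binomial-mixture clustering of prevalence vectors.

    Parameters
    ----------
    k_max : int
        Largest number of clusters considered; the fit selects K in
        1..k_max by Bayesian information criterion (ties to smaller K).
    n_restarts : int
        EM restarts per K; the best log-likelihood is kept.
    max_iter, tol : EM stopping rule.
    random_state : int, Generator-compatible seed, or None.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (n,) int array of cluster assignments.
    cluster_prevalence_ : (K, T) array of per-timepoint cluster
        prevalences (depth- and posterior-weighted means).
    weights_ : (K,) mixing proportions.
    n_clusters_ : selected number of (non-empty) clusters.
    bic_ : BIC of the selected model; ``bic_by_k_`` maps K -> BIC.
    log_likelihood_ : final log-likelihood (binomial kernel, constants
        in the data dropped).
    """

    def __init__(self, k_max=10, n_restarts=10, max_iter=300, tol=1e-7,
                 random_state=None):
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _validate(X, depths):
        X = np.asarray(X, dtype=float)
        D = np.asarray(depths, dtype=float)
        if X.ndim != 2 or D.shape != X.shape:
            raise ValueError("X and depths must be 2-D arrays of identical shape")
        if len(X) == 0:
            raise ValueError("need at least one mutation")
        if np.any(D < 0):
            raise ValueError("depths must be non-negative")
        if not np.any(D > 0):
            raise ValueError("all-zero depth matrix")
        X = np.clip(X, 0.0, 1.0)
        return X, D

    @staticmethod
    def _log_components(S, D, theta):
        th = np.clip(theta, _EPS, 1 - _EPS)  # (K, T)
        return S @ np.log(th).T + (D - S) @ np.log1p(-th).T  # (n, K)

    def _em(self, S, D, K, rng):
        n = len(S)
        idx = rng.choice(n, size=K, replace=False)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(D[idx] > 0, S[idx] / np.maximum(D[idx], 1), 0.5)
        theta = np.clip(theta + rng.uniform(-0.01, 0.01, theta.shape), _EPS, 1 - _EPS)
        pi = np.full(K, 1.0 / K)
        ll_old = -np.inf
        for _ in range(self.max_iter):
            logp = self._log_components(S, D, theta) + np.log(pi)
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            resp = np.exp(logp - norm[:, None])
            pi = np.maximum(resp.mean(axis=0), 1e-12)
            pi /= pi.sum()
            denom = resp.T @ D
            theta = np.where(denom > 0, (resp.T @ S) / np.maximum(denom, _EPS), 0.5)
            theta = np.clip(theta, _EPS, 1 - _EPS)
            if ll - ll_old < self.tol * max(1.0, abs(ll)):
                break
            ll_old = ll
        logp = self._log_components(S, D, theta) + np.log(pi)
        ll = float(logsumexp(logp, axis=1).sum())
        return ll, pi, theta

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None, depths=None):
        """Fit the mixture on a mutations-by-timepoints prevalence matrix.

        ``depths`` (same shape as X) carries the sequencing depth behind
        each prevalence value and is required.
        """
        if depths is None:
            raise ValueError("depths is required")
        X, D = self._validate(X, depths)
        rs = check_random_state(self.random_state)
        rng = np.random.default_rng(rs.randint(0, 2**31))
        n, T = X.shape
        S = X * D
        best = None
        self.bic_by_k_ = {}
        for K in range(1, min(self.k_max, n) + 1):
            k_best = None
            for _ in range(self.n_restarts if K > 1 else 1):
                ll, pi, theta = self._em(S, D, K, rng)
                if k_best is None or ll > k_best[0]:
                    k_best = (ll, pi, theta)
            ll, pi, theta = k_best
            n_params = (K - 1) + K * T
            bic = -2.0 * ll + n_params * np.log(n)
            self.bic_by_k_[K] = bic
            if best is None or bic < best[0] - 1e-9:
                best = (bic, ll, pi, theta, K)
        bic, ll, pi, theta, K = best
        logp = self._log_components(S, D, theta) + np.log(pi)
        labels = np.argmax(logp, axis=1)
        # drop empty clusters, relabel contiguously (largest first for stability)
        occupied = np.unique(labels)
        order = occupied[np.argsort([-np.sum(labels == k) for k in occupied])]
        remap = {old: new for new, old in enumerate(order)}
        self.labels_ = np.array([remap[v] for v in labels])
        self.cluster_prevalence_ = theta[order]
        self.weights_ = pi[order] / pi[order].sum()
        self.n_clusters_ = len(order)
        self.bic_ = bic
        self.log_likelihood_ = ll
        return self

    def fit_predict(self, X, y=None, depths=None):
        return self.fit(X, depths=depths).labels_

    def predict(self, X, depths=None):
        if depths is None:
            raise ValueError("depths is required")
        X, D = self._validate(X, depths)
        S = X * D
        logp = self._log_components(S, D, self.cluster_prevalence_) + np.log(self.weights_)
        return np.argmax(logp, axis=1)


@dataclass
class ClusterModel:
    """A fitted clonal-cluster model for one patient.

    ``prevalence`` rows align with contiguous cluster ids 0..K-1;
    ``cluster_ids`` preserves original identities through prune/merge.
    """

    mutation_ids: list[str]
    labels: np.ndarray
    prevalence: np.ndarray  # (K, T)
    timepoints: tuple[str, ...]
    X: np.ndarray  # (n, T) clamped prevalences
    depths: np.ndarray  # (n, T)
    fit_score: float
    cluster_ids: list[int] = field(default_factory=list)
    flagged_singletons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.cluster_ids:
            self.cluster_ids = list(range(len(self.prevalence)))

    @property
    def n_clusters(self) -> int:
        return len(self.prevalence)

    @property
    def assignments(self) -> dict[str, int]:
        return {m: self.cluster_ids[l] for m, l in zip(self.mutation_ids, self.labels)}

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def members(self, row: int) -> list[str]:
        return [m for m, l in zip(self.mutation_ids, self.labels) if l == row]

    def prevalence_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.prevalence, columns=list(self.timepoints))
        df.insert(0, "cluster", self.cluster_ids)
        df.insert(1, "n_mutations", self.cluster_sizes())
        return df


def cluster_mutations(
    prevalence: pd.DataFrame | np.ndarray,
    depths: pd.DataFrame | np.ndarray,
    k_max: int = 10,
    seed: int | None = None,
    n_restarts: int = 10,
) -> ClusterModel:
    """Cluster mutations on clamped-rVAF vectors across timepoints.

    ``prevalence`` may be a DataFrame (index: mutation ids, columns:
    timepoints) or an array; ``depths`` must align with it.
    """
    if isinstance(prevalence, pd.DataFrame):
        mutation_ids = [str(m) for m in prevalence.index]
        timepoints = tuple(str(c) for c in prevalence.columns)
        X = prevalence.to_numpy(dtype=float)
    else:
        X = np.asarray(prevalence, dtype=float)
        mutation_ids = [f"m{i}" for i in range(len(X))]
        timepoints = tuple(f"t{j}" for j in range(X.shape[1]))
    D = depths.to_numpy(dtype=float) if isinstance(depths, pd.DataFrame) else np.asarray(depths, dtype=float)
    est = BinomialMixtureClusterer(
        k_max=k_max, n_restarts=n_restarts, random_state=seed
    ).fit(X, depths=D)
    return ClusterModel(
        mutation_ids=mutation_ids,
        labels=est.labels_,
        prevalence=est.cluster_prevalence_,
        timepoints=timepoints,
        X=np.clip(X, 0.0, 1.0),
        depths=D,
        fit_score=est.bic_,
    )


def _recompute_prevalence(model: ClusterModel) -> np.ndarray:
    K = model.labels.max() + 1
    theta = np.zeros((K, model.X.shape[1]))
    S = model.X * model.depths
    for k in range(K):
        mask = model.labels == k
        denom = model.depths[mask].sum(axis=0)
        theta[k] = np.where(denom > 0, S[mask].sum(axis=0) / np.maximum(denom, _EPS), 0.0)
    return theta


def merge_singletons(model: ClusterModel) -> ClusterModel:
    """Merge single-mutation clusters into their nearest cluster.

    For each singleton, the per-timepoint z-score of its prevalence
    vector against each non-singleton cluster mean is computed using the
    cluster's binomial standard error sqrt(theta (1-theta) / mean
    member depth).  The singleton merges into the cluster minimizing the
    z-vector norm, but only when every per-timepoint z lies within
    [-1, +1]; otherwise it is retained and flagged.  Merged clusters'
    prevalences are recomputed over their new members.  Never increases
    the cluster count.
    """
    sizes = model.cluster_sizes()
    singles = [k for k in range(model.n_clusters) if sizes[k] == 1]
    hosts = [k for k in range(model.n_clusters) if sizes[k] > 1]
    if not singles or not hosts:
        return replace(model, labels=model.labels.copy(),
                       flagged_singletons=list(model.flagged_singletons))
    labels = model.labels.copy()
    flagged = list(model.flagged_singletons)
    host_se = {}
    for k in hosts:
        mask = model.labels == k
        dbar = model.depths[mask].mean(axis=0)
        th = np.clip(model.prevalence[k], _EPS, 1 - _EPS)
        host_se[k] = np.sqrt(th * (1 - th) / np.maximum(dbar, 1.0))
    for k in singles:
        i = int(np.flatnonzero(model.labels == k)[0])
        x = model.X[i]
        best = None
        for h in hosts:
            z = (x - model.prevalence[h]) / host_se[h]
            if np.all(np.abs(z) <= 1.0):
                norm = float(np.linalg.norm(z))
                if best is None or norm < best[0]:
                    best = (norm, h)
        if best is None:
            flagged.append(model.mutation_ids[i])
        else:
            labels[i] = best[1]
    # relabel contiguously, preserving original cluster ids of survivors
    survivors = sorted(set(labels.tolist()))
    remap = {old: new for new, old in enumerate(survivors)}
    new_labels = np.array([remap[v] for v in labels])
    merged = replace(
        model,
        labels=new_labels,
        cluster_ids=[model.cluster_ids[k] for k in survivors],
        flagged_singletons=flagged,
    )
    merged.prevalence = _recompute_prevalence(merged)
    return merged


def prune_small_clusters(
    model: ClusterModel, min_size: int = 3
) -> tuple[ClusterModel, list[tuple[int, list[str]]]]:
    """Split a model into display clusters and a removed list.

    Clusters with fewer than ``min_size`` mutations are excluded from
    the display model but returned, with their members, in the removed
    list — analysis-complete, display-pruned.  Retained clusters'
    prevalences are untouched.
    """
    sizes = model.cluster_sizes()
    keep = [k for k in range(model.n_clusters) if sizes[k] >= min_size]
    removed = [
        (model.cluster_ids[k], model.members(k))
        for k in range(model.n_clusters)
        if sizes[k] < min_size
    ]
    keep_mask = np.isin(model.labels, keep)
    remap = {old: new for new, old in enumerate(keep)}
    display = replace(
        model,
        mutation_ids=[m for m, ok in zip(model.mutation_ids, keep_mask) if ok],
        labels=np.array([remap[v] for v in model.labels[keep_mask]], dtype=int),
        prevalence=model.prevalence[keep].copy(),
        X=model.X[keep_mask],
        depths=model.depths[keep_mask],
        cluster_ids=[model.cluster_ids[k] for k in keep],
    )
    return display, removed


def build_fishplot_table(
    model: ClusterModel, timepoints: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Long-format cluster trajectories with a containment parent guess.

    Cluster A is an ancestor candidate of B when A's prevalence is >= B's
    at every timepoint; the parent guess is the tightest such candidate
    (smallest total prevalence).  Exactly one parentless cluster — the
    one with the largest total prevalence — is the root; any other
    cluster without a containing candidate is marked ``ambiguous``.
    Such tables feed fishplot/timescape-style renderers; the parent is a
    guess, since prevalences alone cannot distinguish a new subclone
    carrying all truncal mutations from one that lost some.
    """
    tps = timepoints or model.timepoints
    K = model.n_clusters
    tol = 1e-9
    prev = model.prevalence
    parents: list[object] = []
    totals = prev.sum(axis=1)
    for b in range(K):
        candidates = []
        for a in range(K):
            if a == b:
                continue
            geq = np.all(prev[a] >= prev[b] - tol)
            if geq and (np.any(prev[a] > prev[b] + tol) or a < b):
                candidates.append(a)
        if candidates:
            parents.append(model.cluster_ids[min(candidates, key=lambda a: totals[a])])
        else:
            parents.append(None)
    root_rows = [b for b in range(K) if parents[b] is None]
    root = max(root_rows, key=lambda b: (totals[b], -b)) if root_rows else None
    rows = []
    for b in range(K):
        parent = parents[b]
        if parent is None:
            parent = "root" if b == root else "ambiguous"
        for j, tp in enumerate(tps):
            rows.append(dict(cluster=model.cluster_ids[b], timepoint=tp,
                             prevalence=float(prev[b, j]), parent=parent))
    return pd.DataFrame(rows, columns=["cluster", "timepoint", "prevalence", "parent"])
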