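"""NMF consensus clustering with stability-driven model selection.

Subtypes are found per omic layer by factorizing the (non-negative-shifted)
feature x sample matrix ``V ~ W H`` many times from random starts, assigning
each sample to the argmax row of ``H`` per run, and accumulating a
sample x sample consensus matrix of co-assignment frequencies. Stability of
a ``(MAD fraction, k)`` combination is scored by the cophenetic correlation
coefficient of ``1 - consensus``; the most stable combination wins. Final
labels come from average-linkage hierarchical clustering of the consensus
dissimilarity, and cluster-characteristic features ("metagenes") from the
basis matrix ``W`` of the best run.

The factorization uses Brunet-style multiplicative updates under the KL
divergence (Frobenius available), with a deterministic seed per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.special import xlogy
from sklearn.base import BaseEstimator, ClusterMixin

from .matrix import OmicsMatrix
from .preprocess import mad_filter

_EPS = 1e-12


# ---------------------------------------------------------------------------
# core factorization


@dataclass
class NMFFactors:
    """One factorization: V (features x samples) ~ W (features x k) H (k x samples)."""

    W: np.ndarray
    H: np.ndarray
    objective: float
    trace: np.ndarray
    n_iter: int
    seed: int
    loss: str = "kl"

    def sample_labels(self) -> np.ndarray:
        """Per-sample cluster label: argmax row of H."""
        return np.argmax(self.H, axis=0)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    return float(np.sum(xlogy(V, V / WH) - V + WH))


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    loss: str = "kl",
    eval_every: int = 10,
) -> NMFFactors:
    """Multiplicative-update NMF of a non-negative matrix.

    The objective is evaluated every ``eval_every`` iterations; the run
    stops when its relative change between evaluations drops below ``tol``
    or at ``max_iter``. The recorded objective trace is monotone
    non-increasing (a property of the update rules).
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V has negative entries; shift it to be non-negative first")
    if np.any(~np.isfinite(V)):
        raise ValueError("V must be complete (impute first)")
    if not 1 <= k < min(V.shape):
        raise ValueError(f"k must satisfy 1 <= k < min(V.shape), got {k}")
    if loss not in ("kl", "frobenius"):
        raise ValueError("loss must be 'kl' or 'frobenius'")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = scale * rng.random((V.shape[0], k)) + _EPS
    H = scale * rng.random((k, V.shape[1])) + _EPS

    trace = []
    prev = np.inf
    n_done = 0
    for it in range(max_iter):
        if loss == "kl":
            WH = W @ H + _EPS
            H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
            WH = W @ H + _EPS
            W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        else:
            H *= (W.T @ V) / (W.T @ W @ H + _EPS)
            W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        n_done = it + 1
        if n_done % eval_every == 0 or n_done == max_iter:
            if loss == "kl":
                obj = _kl_divergence(V, W @ H + _EPS)
            else:
                obj = 0.5 * float(np.sum((V - W @ H) ** 2))
            trace.append(obj)
            if np.isfinite(prev) and abs(prev - obj) <= tol * max(abs(prev), _EPS):
                break
            prev = obj
    return NMFFactors(W=W, H=H, objective=trace[-1], trace=np.array(trace),
                      n_iter=n_done, seed=seed, loss=loss)


# ---------------------------------------------------------------------------
# consensus machinery


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the average-linkage tree of 1 - consensus.

    Pearson correlation between the off-diagonal consensus dissimilarities
    and the cophenetic distances of their dendrogram; NaN when the
    off-diagonal is constant (correlation undefined).
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus must be square")
    if not np.allclose(C, C.T, atol=1e-8, equal_nan=True):
        raise ValueError("consensus must be symmetric")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError("consensus diagonal must be 1")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(np.clip(D, 0.0, None), checks=False)
    if np.allclose(d, d[0]):
        return float("nan")
    Z = average(d)
    c, _ = cophenet(Z, d)
    return float(c)


def silhouette_scores(labels: np.ndarray, dissimilarity: np.ndarray) -> np.ndarray:
    """Classic silhouette s(i) = (b - a) / max(a, b) on a dissimilarity matrix.

    Samples in singleton clusters score 0 by convention.
    """
    labels = np.asarray(labels)
    D = np.asarray(dissimilarity, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


@dataclass
class ConsensusResult:
    """Consensus matrix, stability score, and final labels for one (k, input)."""

    consensus: pd.DataFrame
    cophenetic: float
    labels: pd.Series
    silhouette: pd.Series
    k: int
    n_runs: int
    W: pd.DataFrame | None = None  # basis of the best-objective run


def _labels_from_consensus(C: np.ndarray, k: int) -> np.ndarray:
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(np.clip(D, 0.0, None), checks=False))
    return fcluster(Z, t=k, criterion="maxclust") - 1


class NMFConsensusClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering of samples by repeated NMF from random starts.

    Parameters
    ----------
    n_clusters : int
        Rank k of the factorization and number of subtypes.
    n_runs : int
        Number of random restarts accumulated into the consensus matrix.
    max_iter, tol, loss
        Passed to the multiplicative-update factorization.
    random_state : int or None
        Seeds the per-run seed sequence; fixed value => identical output.

    Attributes
    ----------
    labels_ : (n_samples,) final cluster labels from the consensus tree.
    consensus_matrix_ : (n_samples, n_samples) co-assignment frequencies.
    cophenetic_ : stability score of the consensus dissimilarity.
    silhouette_samples_ : per-sample silhouette on 1 - consensus.
    best_factors_ : :class:`NMFFactors` of the lowest-objective run.
    """

    def __init__(self, n_clusters: int = 3, n_runs: int = 100, max_iter: int = 300,
                 tol: float = 1e-5, loss: str = "kl", random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.loss = loss
        self.random_state = random_state

    def fit(self, X, y=None):
        """Cluster samples; X is (n_samples, n_features), shifted non-negative."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        V = X.T - min(X.min(), 0.0)  # features x samples, non-negative
        n = X.shape[0]
        seeds = np.random.SeedSequence(self.random_state).generate_state(self.n_runs) % (2**31 - 1)
        run_labels = np.empty((self.n_runs, n), dtype=int)
        best = None
        for r, seed in enumerate(seeds):
            fac = nmf_factorize(V, self.n_clusters, seed=int(seed),
                                max_iter=self.max_iter, tol=self.tol, loss=self.loss)
            run_labels[r] = fac.sample_labels()
            if best is None or fac.objective < best.objective:
                best = fac
        same = (run_labels[:, :, None] == run_labels[:, None, :]).mean(axis=0)
        np.fill_diagonal(same, 1.0)
        self.consensus_matrix_ = same
        self.cophenetic_ = cophenetic_coefficient(same)
        self.labels_ = _labels_from_consensus(same, self.n_clusters)
        D = 1.0 - same
        np.fill_diagonal(D, 0.0)
        if len(np.unique(self.labels_)) < 2:
            self.silhouette_samples_ = np.zeros(n)  # degenerate single cluster
        else:
            self.silhouette_samples_ = silhouette_scores(self.labels_, D)
        self.best_factors_ = best
        self.basis_ = self._align_basis(best)
        self.n_features_in_ = X.shape[1]
        return self

    def _align_basis(self, factors: NMFFactors) -> np.ndarray:
        """Reorder W columns so column c matches consensus cluster c.

        Components are matched to consensus clusters by majority vote of the
        best run's argmax-H assignments; if the match is not one-to-one the
        original order is kept.
        """
        run = factors.sample_labels()
        mapping = {}
        for j in range(self.n_clusters):
            mask = run == j
            if mask.any():
                vals, counts = np.unique(self.labels_[mask], return_counts=True)
                mapping[j] = int(vals[np.argmax(counts)])
        if sorted(mapping.values()) != list(range(self.n_clusters)):
            return factors.W
        perm = [j for c in range(self.n_clusters) for j in mapping if mapping[j] == c]
        return factors.W[:, perm]

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cluster_nmf(
    matrix: OmicsMatrix,
    k: int,
    n_runs: int = 100,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    loss: str = "kl",
) -> ConsensusResult:
    """Consensus-cluster an :class:`OmicsMatrix`'s samples at rank ``k``."""
    if not matrix.is_complete():
        raise ValueError("matrix must be complete (impute first)")
    est = NMFConsensusClustering(n_clusters=k, n_runs=n_runs, max_iter=max_iter,
                                 tol=tol, loss=loss, random_state=seed)
    est.fit(matrix.shifted_nonnegative().to_numpy().T)
    ids = matrix.sample_ids
    return ConsensusResult(
        consensus=pd.DataFrame(est.consensus_matrix_, index=ids, columns=ids),
        cophenetic=est.cophenetic_,
        labels=pd.Series(est.labels_, index=ids),
        silhouette=pd.Series(est.silhouette_samples_, index=ids),
        k=k, n_runs=n_runs,
        W=pd.DataFrame(est.basis_, index=matrix.feature_keys, columns=range(k)),
    )


# ---------------------------------------------------------------------------
# model selection over (MAD fraction, k)


@dataclass
class ModelSelection:
    """Winning (MAD fraction, k) with its consensus result and the full grid."""

    fraction: float
    k: int
    result: ConsensusResult
    grid: pd.DataFrame
    best_W: pd.DataFrame = field(default=None)


def select_model(
    matrix: OmicsMatrix,
    mad_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.5, 1.0),
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_runs: int = 100,
    seed: int | None = 0,
    **kwargs,
) -> ModelSelection:
    """Pick the most stable (MAD fraction, k) by cophenetic coefficient.

    Every combination is consensus-clustered; the maximum cophenetic wins,
    ties broken by smaller k then smaller fraction. The full grid of
    cophenetic coefficients is reported.
    """
    if not mad_fractions or not k_range:
        raise ValueError("empty model-selection grid")
    rows = []
    results = {}
    ss = np.random.SeedSequence(seed)
    combos = [(f, k) for f in sorted(mad_fractions) for k in sorted(k_range)]
    child_seeds = ss.generate_state(len(combos)) % (2**31 - 1)
    for (frac, k), cs in zip(combos, child_seeds):
        sub = mad_filter(matrix, frac)
        res = consensus_cluster_nmf(sub, k, n_runs=n_runs, seed=int(cs), **kwargs)
        results[(frac, k)] = (res, sub)
        rows.append({"fraction": frac, "k": k, "cophenetic": res.cophenetic,
                     "mean_silhouette": float(res.silhouette.mean()),
                     "n_features": sub.n_features})
    grid = pd.DataFrame(rows)
    valid = grid.dropna(subset=["cophenetic"])
    if valid.empty:
        raise ValueError("cophenetic undefined on the whole grid")
    best = valid.sort_values(["cophenetic", "k", "fraction"],
                             ascending=[False, True, True]).iloc[0]
    frac, k = float(best["fraction"]), int(best["k"])
    res, _sub = results[(frac, k)]
    return ModelSelection(fraction=frac, k=k, result=res, grid=grid, best_W=res.W)


# ---------------------------------------------------------------------------
# metagene extraction


@dataclass
class MetageneSignature:
    """Per-cluster characteristic features with basis weights, disjoint."""

    per_cluster: dict[int, list[tuple[str, float]]]

    @property
    def all_features(self) -> list[str]:
        return [f for feats in self.per_cluster.values() for f, _ in feats]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cluster": c, "feature": f, "weight": w}
                for c, feats in self.per_cluster.items() for f, w in feats]
        return pd.DataFrame(rows, columns=["cluster", "feature", "weight"])


def extract_metagene(
    W: pd.DataFrame,
    cap_per_cluster: int = 15,
    margin: float = 0.1,
) -> MetageneSignature:
    """Cluster-specific features from a basis matrix.

    A feature's specificity for cluster c is its basis weight there divided
    by its row sum; it is assigned to its argmax cluster when specificity
    exceeds ``1/k + margin``, and each cluster keeps its top
    ``cap_per_cluster`` features by weight (descending). Cluster lists are
    disjoint by construction.
    """
    Wv = W.to_numpy(dtype=float)
    if np.any(Wv < 0):
        raise ValueError("basis matrix must be non-negative")
    k = Wv.shape[1]
    rowsum = Wv.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(rowsum > 0, Wv / rowsum, 0.0)
    per_cluster: dict[int, list[tuple[str, float]]] = {}
    for c in range(k):
        mine = [(str(W.index[i]), float(Wv[i, c]))
                for i in range(Wv.shape[0])
                if spec[i].argmax() == c and spec[i, c] > 1.0 / k + margin]
        mine.sort(key=lambda fw: (-fw[1], fw[0]))
        per_cluster[int(c)] = mine[:cap_per_cluster]
    return MetageneSignature(per_cluster=per_cluster)
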