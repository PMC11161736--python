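"""Integrative subtyping across omic layers via a binary membership table.

Each layer's subtype assignment is one-hot encoded into a (layer, cluster) x
samples 1-0 table; stacking the layers gives an integrative description of
every sample. The samples are then consensus-clustered by repeated
subsampling (Monti-style): per iteration a random 80% of samples is
hierarchically clustered (average linkage, Euclidean distance on the binary
columns) and cut at k; consensus(i, j) is the co-clustered count over the
co-sampled count. Final labels come from the consensus tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .nmf import ConsensusResult, cophenetic_coefficient, silhouette_scores


def build_binary_table(assignments: dict[str, pd.Series],
                       on_missing: str = "error") -> pd.DataFrame:
    """One-hot stack per-layer subtype labels into a 1-0 membership table.

    ``assignments`` maps layer name -> per-sample cluster labels. Rows are
    ``(layer, cluster)`` pairs; within each layer's block every column sums
    to exactly 1. Samples missing from a layer raise unless
    ``on_missing="drop"`` (sample dropped from all layers).
    """
    if not assignments:
        raise ValueError("no assignments given")
    sample_sets = {layer: set(lab.index) for layer, lab in assignments.items()}
    shared = set.intersection(*sample_sets.values())
    union = set.union(*sample_sets.values())
    if shared != union:
        if on_missing != "drop":
            missing = sorted(union - shared)
            raise ValueError(
                f"samples missing from some layer: {missing[:5]}; "
                "pass on_missing='drop' to keep the intersection"
            )
    samples = sorted(shared)
    if not samples:
        raise ValueError("no sample is labeled in every layer")
    blocks = []
    for layer in assignments:
        lab = assignments[layer].loc[samples]
        for cluster in sorted(pd.unique(lab)):
            row = (lab == cluster).astype(int)
            row.name = (layer, str(cluster))
            blocks.append(row)
    table = pd.DataFrame(blocks)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["layer", "cluster"])
    return table


class BinaryConsensusClustering(ClusterMixin, BaseEstimator):
    """Subsampled consensus clustering of samples over binary membership rows.

    Parameters
    ----------
    n_clusters : int, target k for the inner cut and the final labels.
    n_iter : int, number of subsampling iterations (>= 2).
    subsample : float, fraction of samples drawn per iteration.
    linkage_method : inner-loop hierarchical linkage ("average" default).
    metric : "euclidean" or "jaccard" distance between binary columns.
    random_state : seed; fixed value => identical output.

    Attributes
    ----------
    labels_, consensus_matrix_, cophenetic_, silhouette_samples_ ;
    co-sampled-never pairs have NaN consensus (excluded from cophenetic,
    treated as maximally distant when cutting the final tree).
    """

    def __init__(self, n_clusters: int = 2, n_iter: int = 500, subsample: float = 0.8,
                 linkage_method: str = "average", metric: str = "euclidean",
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_iter = n_iter
        self.subsample = subsample
        self.linkage_method = linkage_method
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y=None):
        """X is (n_samples, n_binary_features): transposed membership table."""
        X = np.asarray(X, dtype=float)
        m = X.shape[0]
        if not 2 <= self.n_clusters <= m - 1:
            raise ValueError("need 2 <= n_clusters <= n_samples - 1")
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")
        rng = np.random.default_rng(self.random_state)
        n_draw = math.ceil(self.subsample * m)
        together = np.zeros((m, m))
        sampled = np.zeros((m, m))
        for _ in range(self.n_iter):
            idx = np.sort(rng.choice(m, size=n_draw, replace=False))
            sub = X[idx]
            d = pdist(sub, metric=self.metric)
            if np.all(d == 0):
                labels = np.zeros(len(idx), dtype=int)
            else:
                Z = linkage(d, method=self.linkage_method)
                labels = fcluster(Z, t=self.n_clusters, criterion="maxclust")
            co = labels[:, None] == labels[None, :]
            sampled[np.ix_(idx, idx)] += 1
            together[np.ix_(idx, idx)] += co
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = together / sampled
        np.fill_diagonal(consensus, 1.0)
        self.consensus_matrix_ = consensus

        filled = np.where(np.isnan(consensus), 0.0, consensus)
        np.fill_diagonal(filled, 1.0)
        D = 1.0 - filled
        np.fill_diagonal(D, 0.0)
        Z = average(squareform(np.clip(D, 0, None), checks=False))
        self.labels_ = fcluster(Z, t=self.n_clusters, criterion="maxclust") - 1
        self.cophenetic_ = cophenetic_coefficient(filled)
        if len(np.unique(self.labels_)) < 2:
            self.silhouette_samples_ = np.zeros(m)  # degenerate single cluster
        else:
            self.silhouette_samples_ = silhouette_scores(self.labels_, D)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cluster_binary(
    table: pd.DataFrame,
    k: int = 2,
    n_iter: int = 500,
    subsample: float = 0.8,
    seed: int | None = 0,
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> ConsensusResult:
    """Consensus-cluster the samples (columns) of a binary membership table."""
    est = BinaryConsensusClustering(
        n_clusters=k, n_iter=n_iter, subsample=subsample,
        linkage_method=linkage_method, metric=metric, random_state=seed,
    )
    est.fit(table.to_numpy().T)
    ids = [str(c) for c in table.columns]
    return ConsensusResult(
        consensus=pd.DataFrame(est.consensus_matrix_, index=ids, columns=ids),
        cophenetic=est.cophenetic_,
        labels=pd.Series(est.labels_, index=ids),
        silhouette=pd.Series(est.silhouette_samples_, index=ids),
        k=k, n_runs=n_iter,
    )


@dataclass
class KSweep:
    """Consensus CDF area report over a range of k."""

    results: dict[int, ConsensusResult]
    report: pd.DataFrame


def consensus_k_sweep(
    table: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    **kwargs,
) -> KSweep:
    """Run consensus clustering over k and report CDF areas and Δ-areas.

    The area under the empirical CDF of off-diagonal consensus values is the
    usual model-selection summary for subsampled consensus clustering; the
    relative gain Δ(k) flattens once k exceeds the true structure.
    """
    results = {}
    rows = []
    prev_area = None
    for k in sorted(k_range):
        if not 2 <= k <= table.shape[1] - 1:
            continue
        res = consensus_cluster_binary(table, k=k, **kwargs)
        results[k] = res
        C = res.consensus.to_numpy()
        off = C[np.triu_indices_from(C, k=1)]
        off = off[~np.isnan(off)]
        xs = np.sort(off)
        area = float(np.trapezoid(np.arange(1, len(xs) + 1) / len(xs), xs)) if len(xs) > 1 else 0.0
        delta = np.nan if prev_area is None else (area - prev_area) / max(prev_area, 1e-12)
        rows.append({"k": k, "cophenetic": res.cophenetic, "cdf_area": area,
                     "delta_area": delta})
        prev_area = area
    return KSweep(results=results, report=pd.DataFrame(rows))


def replicate_agreement(labels: pd.Series, sample_to_line: pd.Series) -> float:
    """Fraction of lines whose replicates all share one final label."""
    lines = sample_to_line.loc[labels.index]
    agree = [labels[lines == line].nunique() == 1 for line in lines.unique()]
    return float(np.mean(agree))
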