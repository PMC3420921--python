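"""Metabolite network detection from the phenotype correlation structure.

Networks are found by hierarchically clustering the metabolite-metabolite
Pearson correlation matrix (distance 1 - r by default, so anti-correlated
metabolites are distant) and cutting the dendrogram with an adaptive
height rule whose sensitivity is controlled by an integer ``deep_split``
parameter in 0..4: higher values cut lower and split more aggressively,
so the number of clusters is non-decreasing in ``deep_split``. A minimum
cluster size of 1 (the default) allows singleton networks.

The agglomeration itself is written here rather than delegated, because
deterministic lexicographic tie-breaking on metabolite names is part of the
contract; the merge list uses the scipy ``linkage`` layout so scipy's
dendrogram utilities apply directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .containers import MetaboliteNetwork, PhenotypeTable

__all__ = [
    "ClusterParams",
    "correlation_matrix",
    "hierarchical_dendrogram",
    "dynamic_tree_cut",
    "network_report",
    "MetaboliteNetworkClusterer",
]

#: deep_split -> fraction of the merge-height range at which the tree is cut
_CUT_FRACTION = {0: 0.95, 1: 0.85, 2: 0.75, 3: 0.65, 4: 0.55}


@dataclass(frozen=True)
class ClusterParams:
    linkage: str = "average"  # one of average, complete, single
    distance: str = "signed"  # "signed" = 1 - r, "unsigned" = 1 - |r|
    deep_split: int = 2
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.linkage not in ("average", "complete", "single"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.distance not in ("signed", "unsigned"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be an integer in 0..4")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def correlation_matrix(pheno: PhenotypeTable | pd.DataFrame) -> pd.DataFrame:
    """Metabolite-metabolite Pearson correlations (pairwise-complete)."""
    if isinstance(pheno, PhenotypeTable):
        df = pheno.data[pheno.metabolites]
    else:
        df = pheno
    if df.shape[1] < 2:
        raise ValueError("need at least 2 metabolites")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    const = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    if const:
        raise ValueError(f"constant metabolite columns: {const}")
    corr = df.corr(method="pearson")  # pandas: pairwise-complete observations
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr.values, 1.0)
    return corr.clip(-1.0, 1.0)


def _distance(corr: pd.DataFrame, kind: str) -> np.ndarray:
    r = corr.to_numpy(dtype=float)
    d = 1.0 - (np.abs(r) if kind == "unsigned" else r)
    d = (d + d.T) / 2.0  # guard against last-bit asymmetry in the input
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_dendrogram(corr: pd.DataFrame, params: ClusterParams | None = None):
    """Agglomerative clustering of the correlation matrix.

    Returns ``(Z, names)`` where ``Z`` is an (n-1) x 4 merge list in scipy
    ``linkage`` layout. Ties in the minimum inter-cluster distance are broken
    toward the pair of clusters whose (lexicographically smallest member
    name) representatives sort first, so the result is deterministic.
    """
    params = params or ClusterParams()
    arr = np.asarray(corr, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    names = [str(c) for c in corr.columns] if isinstance(corr, pd.DataFrame) else [
        str(i) for i in range(arr.shape[0])
    ]
    n = arr.shape[0]
    D = _distance(corr if isinstance(corr, pd.DataFrame) else pd.DataFrame(arr), params.distance)

    # working matrix indexed by row slot; each slot holds one active cluster
    work = D.copy().astype(float)
    np.fill_diagonal(work, np.inf)
    slot_id = np.arange(n)  # scipy cluster id occupying each slot (-1 = dead)
    sizes = np.ones(n)
    reps = list(names)  # lexicographic representative per slot
    alive = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        d_min = work[np.ix_(alive, alive)].min()
        cand = np.argwhere(work == d_min)
        cand = [(i, j) for i, j in cand if i < j and alive[i] and alive[j]]
        # among exact ties, pick the pair whose sorted representatives sort first
        ia, ib = min(cand, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        a, b = slot_id[ia], slot_id[ib]
        Z[step] = [min(a, b), max(a, b), d_min, sizes[ia] + sizes[ib]]

        others = alive.copy()
        others[[ia, ib]] = False
        if params.linkage == "average":
            d_new = (sizes[ia] * work[ia, others] + sizes[ib] * work[ib, others]) / (
                sizes[ia] + sizes[ib]
            )
        elif params.linkage == "complete":
            d_new = np.maximum(work[ia, others], work[ib, others])
        else:
            d_new = np.minimum(work[ia, others], work[ib, others])
        work[ia, others] = d_new
        work[others, ia] = d_new
        work[ib, :] = np.inf
        work[:, ib] = np.inf
        alive[ib] = False
        sizes[ia] = sizes[ia] + sizes[ib]
        slot_id[ia] = n + step
        reps[ia] = min(reps[ia], reps[ib])

    return Z, names


def _cut_height(Z: np.ndarray, deep_split: int) -> float:
    h = Z[:, 2]
    lo, hi = float(h.min()), float(h.max())
    return lo + _CUT_FRACTION[deep_split] * (hi - lo)


def dynamic_tree_cut(
    dendrogram,
    params: ClusterParams | None = None,
    corr: pd.DataFrame | None = None,
) -> list[MetaboliteNetwork]:
    """Cut the dendrogram into metabolite networks.

    The cut height is an adaptive quantile of the merge-height range mapped
    from ``deep_split`` (0 -> 0.95 of the range, 4 -> 0.55), so higher
    sensitivity always produces at least as many clusters. Clusters smaller
    than ``min_cluster_size`` are merged into their cophenetically nearest
    neighbour. Network ids are assigned by descending size, ties broken by
    the first member name; the result partitions the metabolite set.
    """
    params = params or ClusterParams()
    Z, names = dendrogram
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1
    if n == 1:
        labels = np.ones(1, dtype=int)
    else:
        labels = fcluster(Z, t=_cut_height(Z, params.deep_split), criterion="distance")

    labels = _enforce_min_size(Z, labels, params.min_cluster_size)

    networks = []
    for lab in np.unique(labels):
        members = [names[i] for i in np.flatnonzero(labels == lab)]
        networks.append(members)
    networks.sort(key=lambda m: (-len(m), min(m)))
    result = [
        MetaboliteNetwork(network_id=i + 1, members=members)
        for i, members in enumerate(networks)
    ]
    if corr is not None:
        for net in result:
            net.mean_intra_r = _mean_intra_r(net.members, corr)
    return result


def _enforce_min_size(Z: np.ndarray, labels: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1:
        return labels
    labels = labels.copy()
    n = len(labels)
    coph = squareform(cophenet(Z)) if n > 1 else np.zeros((1, 1))
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1 or counts.min() >= min_size:
            return labels
        small = uniq[np.argmin(counts)]
        members = np.flatnonzero(labels == small)
        best_lab, best_d = None, np.inf
        for lab in uniq:
            if lab == small:
                continue
            others = np.flatnonzero(labels == lab)
            d = coph[np.ix_(members, others)].mean()
            if d < best_d:
                best_lab, best_d = lab, d
        labels[members] = best_lab


def _mean_intra_r(members: list[str], corr: pd.DataFrame) -> float | None:
    if len(members) < 2:
        return None
    sub = corr.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def network_report(networks: list[MetaboliteNetwork], corr: pd.DataFrame) -> pd.DataFrame:
    """Per-network summary: size, mean/min intra-network correlation, members."""
    rows = []
    for net in networks:
        if len(net.members) >= 2:
            sub = corr.loc[net.members, net.members].to_numpy()
            iu = np.triu_indices(len(net.members), k=1)
            mean_r, min_r = float(sub[iu].mean()), float(sub[iu].min())
        else:
            mean_r = min_r = None
        rows.append(
            {
                "network": net.network_id,
                "size": net.size,
                "mean_intra_r": mean_r,
                "min_intra_r": min_r,
                "members": ",".join(net.members),
            }
        )
    return pd.DataFrame(rows)


class MetaboliteNetworkClusterer(BaseEstimator):
    """Detect metabolite networks from a samples x metabolites table.

    Clusters the *columns* (metabolites) of ``X`` by their Pearson
    correlation structure. After ``fit``:

    ``corr_`` — metabolite correlation matrix (DataFrame);
    ``dendrogram_`` — scipy-format merge list;
    ``networks_`` — list of :class:`MetaboliteNetwork`;
    ``labels_`` — network id per metabolite column.
    """

    def __init__(self, linkage="average", distance="signed", deep_split=2, min_cluster_size=1):
        self.linkage = linkage
        self.distance = distance
        self.deep_split = deep_split
        self.min_cluster_size = min_cluster_size

    def _params(self) -> ClusterParams:
        return ClusterParams(
            linkage=self.linkage,
            distance=self.distance,
            deep_split=self.deep_split,
            min_cluster_size=self.min_cluster_size,
        )

    def fit(self, X, y=None):
        if isinstance(X, PhenotypeTable):
            df = X.data[X.metabolites]
        elif isinstance(X, pd.DataFrame):
            df = X
        else:
            X = np.asarray(X, dtype=float)
            df = pd.DataFrame(X, columns=[f"m{j}" for j in range(X.shape[1])])
        params = self._params()
        self.corr_ = correlation_matrix(df)
        self.dendrogram_ = hierarchical_dendrogram(self.corr_, params)
        self.networks_ = dynamic_tree_cut(self.dendrogram_, params, corr=self.corr_)
        name_to_net = {m: net.network_id for net in self.networks_ for m in net.members}
        self.feature_names_in_ = np.asarray(df.columns)
        self.labels_ = np.array([name_to_net[str(c)] for c in df.columns])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
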