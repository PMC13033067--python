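"""Subtype discovery: cosine/Ward hierarchical clustering with silhouette
k-selection, size-ordered subtype naming, and dendrogram utilities.

Samples (not genes) are the clustered unit. Distances are cosine
distances between progression-normalized expression profiles; the
agglomeration is Ward's criterion applied to those distances. Because the
named Ward variant is a known dialect issue for non-Euclidean distances,
both the squared-distance ("D2", default, matching R ``hclust`` ward.D2)
and the unsquared ("D") recurrences are available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import pairwise_distances, silhouette_samples


def cosine_distance_matrix(X: pd.DataFrame, *, axis: str = "samples") -> pd.DataFrame:
    """Pairwise cosine distances d(a, b) = 1 - cos(a, b).

    ``X`` is genes x samples; with ``axis="samples"`` (the default and the
    clustered unit of the pipeline) the result is samples x samples.
    Zero-norm vectors have no direction, so they are an error naming the
    offending sample.
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    M = X.T if axis == "samples" else X
    if M.shape[0] < 2:
        raise ValueError("need at least 2 vectors to compute pairwise distances")
    norms = np.linalg.norm(M.to_numpy(dtype=float), axis=1)
    if (norms == 0).any():
        bad = M.index[norms == 0].tolist()
        raise ValueError(f"zero-norm vector(s): {bad}")
    D = pairwise_distances(M.to_numpy(dtype=float), metric="cosine")
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=M.index, columns=M.index)


def _check_distance_matrix(D: pd.DataFrame | np.ndarray) -> np.ndarray:
    A = np.asarray(D, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (A < 0).any():
        raise ValueError("distance matrix must be non-negative")
    return (A + A.T) / 2.0


def ward_linkage(D: pd.DataFrame | np.ndarray, *, variant: str = "D2") -> np.ndarray:
    """Ward agglomeration of a precomputed distance matrix.

    ``variant="D2"`` runs the Lance–Williams Ward recurrence on squared
    distances (scipy's ``ward``, equivalent to R ward.D2); ``variant="D"``
    runs it on the distances themselves (R ward.D).
    """
    A = _check_distance_matrix(D)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    np.fill_diagonal(A, 0.0)
    if variant == "D2":
        return linkage(squareform(A, checks=False), method="ward")
    if variant == "D":
        Z = linkage(squareform(np.sqrt(A), checks=False), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
        return Z
    raise ValueError(f"unknown Ward variant {variant!r}; use 'D2' or 'D'")


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut a dendrogram into k flat clusters (labels 1..k, scipy order)."""
    n = Z.shape[0] + 1
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from a precomputed distance matrix.

    Singleton clusters take width 0 (scikit-learn's convention)."""
    return float(np.mean(silhouette_samples(D, labels, metric="precomputed")))


def find_k(
    Z: np.ndarray,
    D: pd.DataFrame | np.ndarray,
    k_range=None,
) -> tuple[int, dict[int, float]]:
    """Silhouette-based choice of the number of subtypes.

    Cuts the dendrogram at every candidate k, scores the cut by mean
    silhouette width on the precomputed distances, and returns the argmax
    (smallest k on ties, favoring parsimony).
    """
    A = _check_distance_matrix(D)
    n = A.shape[0]
    if n < 3:
        raise ValueError("silhouette-based k selection requires at least 3 samples")
    offdiag = A[~np.eye(n, dtype=bool)]
    if np.allclose(offdiag, 0.0):
        raise ValueError("all pairwise distances are zero; clustering is degenerate")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    scores: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"candidate k={k} outside [2, {n - 1}]")
        labels = cut_tree(Z, k)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = mean_silhouette(A, labels)
    if not scores:
        raise ValueError("no candidate k produced >= 2 clusters")
    best_score = max(scores.values())
    best = min(k for k, s in scores.items() if s == best_score)
    return best, scores


@dataclass
class SubtypeResult:
    """A flat cut of the dendrogram with size-ordered subtype names.

    For k = 2 the larger subtype is named ``L`` and the smaller ``S``;
    for other k the names are ``C1`` (largest) .. ``Ck``. Size ties are
    broken by the smallest leaf index in dendrogram order.
    """

    k: int
    labels: pd.Series  # sample_id -> subtype name
    sizes: dict[str, int]
    silhouette_by_k: dict[int, float]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


def assign_subtypes(
    Z: np.ndarray,
    k: int,
    sample_ids,
    silhouette_by_k: dict[int, float] | None = None,
) -> SubtypeResult:
    """Cut at k and name clusters by descending size (L/S for k = 2)."""
    sample_ids = list(sample_ids)
    n = Z.shape[0] + 1
    if len(sample_ids) != n:
        raise ValueError("sample_ids length must match the dendrogram leaf count")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    leaf_order = leaves_list(Z)
    leaf_rank = np.empty(n, dtype=int)
    leaf_rank[leaf_order] = np.arange(n)
    clusters = np.unique(raw)
    # order clusters by (descending size, first leaf in dendrogram order)
    keyed = sorted(
        clusters,
        key=lambda c: (-int(np.sum(raw == c)), int(leaf_rank[raw == c].min())),
    )
    if len(clusters) == 2:
        names = ["L", "S"]
    else:
        names = [f"C{i + 1}" for i in range(len(clusters))]
    mapping = {c: names[i] for i, c in enumerate(keyed)}
    labels = pd.Series([mapping[c] for c in raw], index=sample_ids, name="subtype")
    sizes = {name: int((labels == name).sum()) for name in names}
    return SubtypeResult(
        k=int(len(clusters)),
        labels=labels,
        sizes=sizes,
        silhouette_by_k=silhouette_by_k or {},
    )


def clustering_concordance(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Fraction of samples co-assigned under the best label bijection.

    1.0 means the two labelings are identical up to cluster renaming —
    e.g. a full-transcriptome clustering and a reduced-panel clustering
    placing every sample in the same subtype.
    """
    labels_a = pd.Series(labels_a)
    labels_b = pd.Series(labels_b)
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("the two labelings cover different sample sets")
    labels_b = labels_b.reindex(labels_a.index)
    cats_a = sorted(labels_a.unique())
    cats_b = sorted(labels_b.unique())
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for i, ca in enumerate(cats_a):
        for j, cb in enumerate(cats_b):
            table[i, j] = int(((labels_a == ca) & (labels_b == cb)).sum())
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(labels_a))


def to_newick(Z: np.ndarray, leaf_names) -> str:
    """Export a dendrogram as Newick, branch lengths from merge heights."""
    leaf_names = list(leaf_names)
    tree = to_tree(Z)

    def build(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return build(tree, tree.dist) + ";"


class CosineWardClusterer(ClusterMixin, BaseEstimator):
    """Sklearn-style clusterer: cosine distances, Ward linkage, silhouette k.

    Parameters
    ----------
    k : int or None
        Fixed number of clusters; ``None`` (default) selects k by maximal
        mean silhouette width over ``k_range``.
    k_range : iterable of int, optional
        Candidate k values; defaults to 2..min(10, n_samples - 1).
    ward_variant : {"D2", "D"}

    Attributes
    ----------
    labels_ : ndarray of cluster indices (0-based, size-ordered: 0 largest)
    k_ : selected number of clusters
    linkage_ : scipy linkage matrix
    silhouette_by_k_ : dict of candidate k -> mean silhouette width
    """

    def __init__(self, k=None, k_range=None, ward_variant="D2"):
        self.k = k
        self.k_range = k_range
        self.ward_variant = ward_variant

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)  # samples x features
        frame = pd.DataFrame(X.T)  # cosine_distance_matrix expects genes x samples
        D = cosine_distance_matrix(frame, axis="samples")
        self.distance_matrix_ = D.to_numpy()
        self.linkage_ = ward_linkage(D, variant=self.ward_variant)
        if self.k is None:
            self.k_, self.silhouette_by_k_ = find_k(self.linkage_, D, self.k_range)
        else:
            self.k_ = int(self.k)
            self.silhouette_by_k_ = {}
        result = assign_subtypes(
            self.linkage_, self.k_, range(X.shape[0]), self.silhouette_by_k_
        )
        order = {"L": 0, "S": 1} if result.k == 2 else {
            f"C{i + 1}": i for i in range(result.k)
        }
        self.subtype_names_ = result.labels.to_numpy()
        self.labels_ = np.array([order[s] for s in self.subtype_names_])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def best_matching_accuracy_bruteforce(labels_a, labels_b) -> float:
    """Exhaustive-bijection concordance (reference oracle, small k only)."""
    labels_a = pd.Series(labels_a)
    labels_b = pd.Series(labels_b).reindex(labels_a.index)
    cats_a = sorted(labels_a.unique())
    cats_b = sorted(labels_b.unique())
    if len(cats_b) < len(cats_a):
        cats_a, cats_b = cats_b, cats_a
        labels_a, labels_b = labels_b, labels_a
    best = 0
    for perm in itertools.permutations(cats_b, len(cats_a)):
        agree = sum(
            ((labels_a == ca) & (labels_b == cb)).sum()
            for ca, cb in zip(cats_a, perm)
        )
        best = max(best, agree)
    return best / len(labels_a)
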