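"""Patient phenotyping by Ward hierarchical clustering with k-means
consolidation on z-scored indicator variables.

The pipeline mirrors the hierarchical-clustering-on-components convention of
FactoMineR-style analyses: (1) standardize each indicator to zero mean and
unit (population) SD so all variables weigh equally; (2) build a Ward
minimum-variance hierarchy, whose merge heights are reported as within-cluster
inertia gains; (3) choose the cluster count k that maximizes the relative
loss of within-cluster inertia Δ(k) = (W(k−1) − W(k)) / W(k−1), ties broken
toward smaller k (parsimony); (4) consolidate the chosen partition by Lloyd
k-means started from the hierarchical cluster centroids.

The default search range is k ∈ [3, 6]: consolidation-style partition
selection conventionally considers at least three clusters, and with strongly
overlapping groups the first split otherwise competes with the true partition
on relative inertia loss alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .types import Group, ScoreRecord

__all__ = [
    "IndicatorMatrix",
    "WardTree",
    "ClusterResult",
    "standardize",
    "ward_tree",
    "select_partition",
    "kmeans_consolidate",
    "cluster_cohort",
    "HierarchicalKMeansClusterer",
]

INDICATOR_NAMES = ("tsp1", "cs_mean", "tsp2", "cpm_pct")


@dataclass
class IndicatorMatrix:
    """n×p matrix of cluster indicator variables, with the standardization
    state and the column statistics used for it."""

    participant_ids: list[str]
    values: np.ndarray
    column_names: tuple[str, ...] = INDICATOR_NAMES
    standardized: bool = False
    column_means: Optional[np.ndarray] = None
    column_sds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("indicator values must be a 2-D matrix")
        if np.isnan(self.values).any():
            raise ValueError("indicator matrix contains missing entries")

    @classmethod
    def from_records(cls, records: Sequence[ScoreRecord]) -> "IndicatorMatrix":
        ids = [r.participant_id for r in records]
        values = np.array([r.indicator_vector() for r in records], dtype=float)
        return cls(participant_ids=ids, values=values)


@dataclass
class WardTree:
    """Ward hierarchy: scipy linkage matrix plus merge heights expressed as
    within-cluster inertia gains (the increase in W at each merge)."""

    linkage_matrix: np.ndarray
    inertia_gains: np.ndarray  # one per merge, ascending
    n_leaves: int

    @property
    def total_inertia(self) -> float:
        return float(self.inertia_gains.sum())

    def within_inertia(self, k: int) -> float:
        """Within-cluster inertia of the k-cluster cut: total minus the top
        k−1 merge gains."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}]")
        return float(self.inertia_gains[: self.n_leaves - k].sum())

    def cut(self, k: int) -> np.ndarray:
        """Labels (1..k) of the k-cluster cut."""
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")


@dataclass
class ClusterResult:
    k: int
    participant_ids: list[str]
    labels_hierarchical: np.ndarray
    labels_consolidated: np.ndarray
    merge_heights: np.ndarray
    within_inertia_by_k: dict[int, float]
    explained_fraction: float
    seed: Optional[int]
    relative_loss_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels_consolidated, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}


def standardize(matrix: IndicatorMatrix) -> IndicatorMatrix:
    """Z-score each column using the population SD (divisor n); after
    standardization total inertia equals n × p."""
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("standardization requires at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population SD
    zero = np.nonzero(sds == 0)[0]
    if zero.size:
        names = ", ".join(matrix.column_names[i] for i in zero)
        raise ValueError(f"zero-variance column(s): {names}")
    return IndicatorMatrix(
        participant_ids=list(matrix.participant_ids),
        values=(X - means) / sds,
        column_names=matrix.column_names,
        standardized=True,
        column_means=means,
        column_sds=sds,
    )


def ward_tree(z: IndicatorMatrix | np.ndarray) -> WardTree:
    """Agglomerate under Ward's minimum-variance criterion (Euclidean).

    scipy's 'ward' heights h satisfy h² = 2 ΔW, so the reported inertia gain
    at each merge is h²/2; the gains sum to the total inertia.
    """
    X = z.values if isinstance(z, IndicatorMatrix) else np.asarray(z, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Ward tree requires at least 2 observations")
    L = linkage(X, method="ward")
    gains = L[:, 2] ** 2 / 2.0
    return WardTree(linkage_matrix=L, inertia_gains=gains, n_leaves=X.shape[0])


def select_partition(tree: WardTree, k_min: int = 3, k_max: int = 6) -> int:
    """Choose the cluster count with the highest relative loss of inertia,
    Δ(k) = (W(k−1) − W(k)) / W(k−1) over k in [k_min, k_max]; exact ties go to
    the smaller k (parsimony)."""
    if not 2 <= k_min <= k_max:
        raise ValueError("need 2 <= k_min <= k_max")
    if k_max >= tree.n_leaves:
        raise ValueError("k_max must be smaller than the number of observations")
    losses = relative_inertia_losses(tree, k_min, k_max)
    best = max(losses.values())
    return min(k for k, v in losses.items() if v == best)


def relative_inertia_losses(tree: WardTree, k_min: int, k_max: int) -> dict[int, float]:
    return {
        k: (tree.within_inertia(k - 1) - tree.within_inertia(k)) / tree.within_inertia(k - 1)
        for k in range(k_min, k_max + 1)
    }


def _within_inertia_of(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        P = X[labels == c]
        w += float(((P - P.mean(axis=0)) ** 2).sum())
    return w


def kmeans_consolidate(
    z: IndicatorMatrix | np.ndarray,
    labels: np.ndarray,
    seed: Optional[int] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Refine a partition by Lloyd k-means initialized at its centroids.

    Returns labels 1..k. Being a descent method, the within-cluster inertia
    of the result never exceeds that of the initial partition.
    """
    X = z.values if isinstance(z, IndicatorMatrix) else np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in uniq])
    km = KMeans(
        n_clusters=uniq.size,
        init=centroids,
        n_init=1,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    km.fit(X)
    return km.labels_ + 1


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in decreasing size (cluster 1 = largest); ties
    broken by original label for determinism."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(range(uniq.size), key=lambda i: (-counts[i], uniq[i]))
    mapping = {int(uniq[i]): rank + 1 for rank, i in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels])


class HierarchicalKMeansClusterer(ClusterMixin, BaseEstimator):
    """Ward hierarchy + inertia-based partition selection + k-means
    consolidation, as a scikit-learn style clusterer.

    Parameters
    ----------
    n_clusters : int or None
        Fixed cluster count; if None the count is selected by the highest
        relative loss of within-cluster inertia over [k_min, k_max].
    k_min, k_max : int
        Search range for the partition selection.
    scale : bool
        Z-score columns (population SD) before clustering.
    random_state : int or None
        Seed forwarded to the k-means consolidation (tie-breaking only; the
        single initialization is deterministic).

    Attributes
    ----------
    n_clusters_ : selected cluster count.
    labels_ : consolidated labels, renumbered 1..k by decreasing cluster size.
    labels_hierarchical_ : labels of the tree cut before consolidation
        (same renumbering as ``labels_``).
    merge_heights_ : inertia gain at each merge, ascending.
    within_inertia_by_k_ : dict k → within-cluster inertia of the tree cut.
    relative_loss_by_k_ : dict k → Δ(k) over the search range.
    explained_fraction_ : between-inertia / total inertia of the final
        consolidated partition.
    cluster_centers_ : centroids in the (scaled) feature space, one row per
        renumbered cluster.
    mean_, scale_ : column statistics used for standardization.
    """

    def __init__(
        self,
        n_clusters: Optional[int] = None,
        k_min: int = 3,
        k_max: int = 6,
        scale: bool = True,
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.k_min = k_min
        self.k_max = k_max
        self.scale = scale
        self.random_state = random_state

    def fit(self, X, y=None) -> "HierarchicalKMeansClusterer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2-D matrix with at least 2 rows")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        self.n_features_in_ = X.shape[1]

        if self.scale:
            m = IndicatorMatrix(
                participant_ids=[str(i) for i in range(X.shape[0])],
                values=X,
                column_names=tuple(f"x{j}" for j in range(X.shape[1])),
            )
            zm = standardize(m)
            Z = zm.values
            self.mean_ = zm.column_means
            self.scale_ = zm.column_sds
        else:
            Z = X
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])

        tree = ward_tree(Z)
        self.tree_ = tree
        self.merge_heights_ = tree.inertia_gains
        self.within_inertia_by_k_ = {
            k: tree.within_inertia(k)
            for k in range(1, min(self.k_max, tree.n_leaves - 1) + 1)
        }
        if self.n_clusters is not None:
            k = int(self.n_clusters)
            if not 1 <= k < tree.n_leaves:
                raise ValueError("n_clusters out of range")
            self.relative_loss_by_k_ = {}
        else:
            self.relative_loss_by_k_ = relative_inertia_losses(tree, self.k_min, self.k_max)
            k = select_partition(tree, self.k_min, self.k_max)
        self.n_clusters_ = k

        hier = tree.cut(k)
        cons = kmeans_consolidate(Z, hier, seed=self.random_state)
        # a shared renumbering keyed on consolidated sizes keeps the two label
        # sets comparable cluster-for-cluster
        self.labels_ = _renumber_by_size(cons)
        mapping_src = _renumber_by_size(cons)
        self.labels_hierarchical_ = self._renumber_like(hier, cons, mapping_src)

        total = tree.total_inertia
        within = _within_inertia_of(Z, self.labels_)
        self.explained_fraction_ = (total - within) / total if total > 0 else 0.0
        self.cluster_centers_ = np.vstack(
            [Z[self.labels_ == c].mean(axis=0) for c in range(1, k + 1)]
        )
        return self

    @staticmethod
    def _renumber_like(hier: np.ndarray, cons: np.ndarray, cons_renumbered: np.ndarray) -> np.ndarray:
        """Renumber hierarchical labels with the map implied by consolidated
        renumbering (majority overlap per original consolidated label)."""
        mapping: dict[int, int] = {}
        for orig in np.unique(cons):
            new = np.bincount(cons_renumbered[cons == orig]).argmax()
            mapping[int(orig)] = int(new)
        # hierarchical labels share k with the consolidation start, so reuse
        # the same original-label space
        return np.array([mapping.get(int(l), int(l)) for l in hier])

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_

    def predict(self, X) -> np.ndarray:
        """Assign new points to the nearest consolidated centroid."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        d = ((Z[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1) + 1


def cluster_cohort(
    records: Sequence[ScoreRecord],
    k_min: int = 3,
    k_max: int = 6,
    n_clusters: Optional[int] = None,
    seed: Optional[int] = None,
    patients_only: bool = True,
) -> ClusterResult:
    """Cluster score records on the four indicator variables (TSP1, CS mean,
    TSP2, CPM %). Controls are held out by default and compared post hoc.
    Cluster ids are renumbered 1..k in decreasing cluster size."""
    if patients_only:
        records = [r for r in records if r.group == Group.PATIENT]
    if len(records) <= k_max:
        raise ValueError(f"need more than k_max={k_max} records to cluster")
    matrix = IndicatorMatrix.from_records(records)
    est = HierarchicalKMeansClusterer(
        n_clusters=n_clusters, k_min=k_min, k_max=k_max, random_state=seed
    ).fit(matrix.values)
    return ClusterResult(
        k=est.n_clusters_,
        participant_ids=matrix.participant_ids,
        labels_hierarchical=est.labels_hierarchical_,
        labels_consolidated=est.labels_,
        merge_heights=est.merge_heights_,
        within_inertia_by_k=est.within_inertia_by_k_,
        explained_fraction=est.explained_fraction_,
        seed=seed,
        relative_loss_by_k=est.relative_loss_by_k_,
    )
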