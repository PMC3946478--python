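"""Cluster validity indices.

Two families are implemented:

* **External indices** compare a crisp partition against ground-truth
  classes: purity, (normalized) entropy, and the pair-counting family
  (Rand, Jaccard, Fowlkes-Mallows) built on SS/SD/DS/DD pair counts.
* **Relative indices** score a partition from the geometry alone: the Dunn
  index (minimum single-linkage inter-cluster distance over maximum cluster
  diameter), the maximum cluster diameter itself (``diam``), Davies-Bouldin,
  and RMSSTD (root-mean-square standard deviation).

Conventions used throughout (all are deliberate, documented choices):

* Distances are Euclidean by default; every geometric index accepts a
  ``metric`` hook forwarded to :func:`scipy.spatial.distance.pdist`.
* Objects labeled :data:`UNASSIGNED` (= -1) — e.g. DBSCAN noise or objects a
  partial trace has not yet processed — are excluded from every computation.
* Entropy uses natural logarithms normalized by ``log(l)`` (``l`` = number
  of classes) so the index lies in [0, 1]; with a single class it is 0.
* Jaccard and Fowlkes-Mallows return 0 (with a warning) when their
  denominator vanishes.
* Dunn returns ``None`` when fewer than two non-empty clusters exist and
  ``math.inf`` when every cluster is a singleton (zero maximum diameter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import InputError

#: Cluster identifier for objects not (yet) allocated to any cluster.
UNASSIGNED = -1

__all__ = [
    "UNASSIGNED",
    "ConfusionMatrix",
    "PairCounts",
    "confusion_matrix",
    "purity",
    "entropy",
    "pair_counts",
    "rand",
    "jaccard",
    "fowlkes_mallows",
    "dunn",
    "max_diameter",
    "davies_bouldin",
    "rmsstd",
    "index_report",
]


# ---------------------------------------------------------------------------
# contingency structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Class-by-cluster contingency table.

    ``counts[i, j]`` is the number of objects of ground-truth class ``i``
    placed in cluster ``j``; rows follow ``classes``, columns ``clusters``.
    """

    counts: np.ndarray
    classes: tuple
    clusters: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.size == 0:
            raise InputError("confusion matrix must be a non-empty 2-D array")
        if (counts < 0).any():
            raise InputError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        """Grand total N of counted objects."""
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[1]

    @property
    def class_totals(self) -> np.ndarray:
        """Row margins (objects per ground-truth class)."""
        return self.counts.sum(axis=1)

    @property
    def cluster_totals(self) -> np.ndarray:
        """Column margins (objects per cluster)."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class PairCounts:
    """SS/SD/DS/DD object-pair counts.

    * ``a`` (SS): same cluster and same class,
    * ``b`` (SD): same cluster, different class,
    * ``c`` (DS): different cluster, same class,
    * ``d`` (DD): different cluster and different class.

    Always satisfies ``a + b + c + d == n * (n - 1) / 2``.
    """

    a: int
    b: int
    c: int
    d: int
    n: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("pair counts must be non-negative")
        if self.a + self.b + self.c + self.d != self.n * (self.n - 1) // 2:
            raise InputError("pair counts do not sum to n(n-1)/2")


def _assigned_mask(labels: np.ndarray) -> np.ndarray:
    return labels != UNASSIGNED


def _as_partition(predicted) -> np.ndarray:
    labels = np.asarray(predicted)
    if labels.ndim != 1:
        raise InputError("partition must be a 1-D label vector")
    return labels


def confusion_matrix(predicted, truth) -> ConfusionMatrix:
    """Cross-tabulate cluster labels against ground-truth classes.

    Objects with cluster label :data:`UNASSIGNED` are excluded from the
    counts. Classes index the rows, clusters the columns; both are sorted.
    """
    predicted = _as_partition(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise InputError(
            f"length mismatch: {len(predicted)} cluster labels vs "
            f"{len(truth)} truth labels"
        )
    mask = _assigned_mask(predicted)
    predicted, truth = predicted[mask], truth[mask]
    if len(predicted) == 0:
        raise InputError("no assigned objects to tabulate")
    classes, class_idx = np.unique(truth, return_inverse=True)
    clusters, cluster_idx = np.unique(predicted, return_inverse=True)
    counts = np.zeros((len(classes), len(clusters)), dtype=np.int64)
    np.add.at(counts, (class_idx, cluster_idx), 1)
    return ConfusionMatrix(counts, tuple(classes.tolist()), tuple(clusters.tolist()))


# ---------------------------------------------------------------------------
# external indices
# ---------------------------------------------------------------------------

def purity(cm: ConfusionMatrix) -> float:
    """Fraction of objects in the majority class of their cluster.

    Sum over clusters of the column maximum, divided by N; equals 1 exactly
    when every cluster is single-class.
    """
    if cm.n == 0:
        raise InputError("purity undefined for an empty confusion matrix")
    return float(cm.counts.max(axis=0).sum() / cm.n)


def entropy(cm: ConfusionMatrix) -> float:
    """Cluster-size-weighted class entropy, normalized to [0, 1].

    Per-cluster entropies use natural logs and are divided by ``log(l)``
    (``l`` = number of classes), so maximal confusion scores 1. Returns 0
    by convention when only one class exists.
    """
    if cm.n == 0:
        raise InputError("entropy undefined for an empty confusion matrix")
    l = cm.n_classes
    if l == 1:
        return 0.0
    total = 0.0
    for j in range(cm.n_clusters):
        column = cm.counts[:, j]
        nj = column.sum()
        if nj == 0:
            continue
        p = column[column > 0] / nj
        h = -(p * np.log(p)).sum() / math.log(l)
        total += (nj / cm.n) * h
    return float(total)


def pair_counts(predicted, truth) -> PairCounts:
    """Count object pairs by cluster/class agreement (SS, SD, DS, DD).

    Computed through the contingency table rather than explicit pair
    enumeration, so it is O(l * k) after tabulation. UNASSIGNED objects are
    excluded; at least two assigned objects are required.
    """
    cm = confusion_matrix(predicted, truth)
    n = cm.n
    if n < 2:
        raise InputError("pair counts require at least two assigned objects")

    def _choose2(values) -> int:
        values = np.asarray(values, dtype=np.int64)
        return int((values * (values - 1) // 2).sum())

    total = n * (n - 1) // 2
    a = _choose2(cm.counts.ravel())
    same_cluster = _choose2(cm.cluster_totals)
    same_class = _choose2(cm.class_totals)
    b = same_cluster - a
    c = same_class - a
    d = total - a - b - c
    return PairCounts(a=a, b=b, c=c, d=d, n=n)


def rand(pc: PairCounts) -> float:
    """Rand index (a + d) / (a + b + c + d)."""
    return (pc.a + pc.d) / (pc.a + pc.b + pc.c + pc.d)


def jaccard(pc: PairCounts) -> float:
    """Jaccard index a / (a + b + c); 0 (with a warning) when a+b+c = 0."""
    denom = pc.a + pc.b + pc.c
    if denom == 0:
        warnings.warn("Jaccard denominator a+b+c is zero; returning 0",
                      stacklevel=2)
        return 0.0
    return pc.a / denom


def fowlkes_mallows(pc: PairCounts) -> float:
    """Fowlkes-Mallows a / sqrt((a+b)(a+c)); 0 (with a warning) if degenerate."""
    denom = (pc.a + pc.b) * (pc.a + pc.c)
    if denom == 0:
        warnings.warn("Fowlkes-Mallows denominator is zero; returning 0",
                      stacklevel=2)
        return 0.0
    return pc.a / math.sqrt(denom)


# ---------------------------------------------------------------------------
# relative (geometric) indices
# ---------------------------------------------------------------------------

def _clusters_of(data, partition):
    """Split assigned rows of ``data`` by cluster; returns (X, list of index arrays)."""
    X = np.asarray(data, dtype=float)
    labels = _as_partition(partition)
    if X.ndim != 2:
        raise InputError("data must be a 2-D object-by-feature matrix")
    if X.shape[0] != len(labels):
        raise InputError(
            f"data has {X.shape[0]} rows but partition has {len(labels)} labels"
        )
    mask = _assigned_mask(labels)
    members = [np.flatnonzero(mask & (labels == c))
               for c in np.unique(labels[mask])]
    return X, members


def dunn(data, partition, *, metric: str = "euclidean") -> float | None:
    """Dunn index: min inter-cluster distance / max cluster diameter.

    Inter-cluster distance is single linkage (minimum pairwise distance
    between members of the two clusters); the diameter is the maximum
    intra-cluster pairwise distance. Larger is better. Invariant under
    global rescaling of the coordinates.

    Returns ``None`` when fewer than two non-empty clusters exist (the index
    is undefined mid-run) and ``inf`` when every cluster is a singleton.
    """
    X, members = _clusters_of(data, partition)
    if len(members) < 2:
        return None
    diam = max_diameter(data, partition, metric=metric)
    min_between = math.inf
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            d = cdist(X[members[i]], X[members[j]], metric=metric).min()
            min_between = min(min_between, d)
    if diam == 0.0:
        return math.inf
    return float(min_between / diam)


def max_diameter(data, partition, *, metric: str = "euclidean") -> float | None:
    """Maximum over clusters of the largest intra-cluster pairwise distance.

    The ``diam`` compactness measure; smaller is better.
    Returns ``None`` when no object is assigned; singleton clusters
    contribute 0.
    """
    X, members = _clusters_of(data, partition)
    if not members:
        return None
    result = 0.0
    for idx in members:
        if len(idx) >= 2:
            result = max(result, float(pdist(X[idx], metric=metric).max()))
    return result


def davies_bouldin(data, partition, *, metric: str = "euclidean") -> float:
    """Davies-Bouldin index: mean over clusters of the worst similarity ratio.

    For clusters i, j with centroids mu_i, mu_j and mean member-to-centroid
    scatters s_i, s_j, the ratio is (s_i + s_j) / d(mu_i, mu_j); each
    cluster takes its maximum over partners and the index is the mean.
    Smaller is better. Requires >= 2 clusters with pairwise-distinct
    centroids.
    """
    X, members = _clusters_of(data, partition)
    k = len(members)
    if k < 2:
        raise InputError("Davies-Bouldin requires at least two clusters")
    centroids = np.stack([X[idx].mean(axis=0) for idx in members])
    scatters = np.array([
        cdist(X[idx], centroids[i:i + 1], metric=metric).mean()
        for i, idx in enumerate(members)
    ])
    centroid_dist = squareform(pdist(centroids, metric=metric))
    total = 0.0
    for i in range(k):
        best = 0.0
        for j in range(k):
            if i == j:
                continue
            if centroid_dist[i, j] == 0.0:
                raise InputError(
                    f"Davies-Bouldin undefined: clusters {i} and {j} have "
                    "coincident centroids"
                )
            best = max(best, (scatters[i] + scatters[j]) / centroid_dist[i, j])
        total += best
    return float(total / k)


def rmsstd(data, partition) -> float:
    """Root-mean-square standard deviation of the partition.

    Square root of the pooled within-cluster sum of squared deviations from
    cluster centroids over the pooled degrees of freedom
    ``n_features * sum_i (n_i - 1)``. Smaller is better; 0 when every
    cluster is a singleton or all members coincide.
    """
    X, members = _clusters_of(data, partition)
    if not members:
        raise InputError("RMSSTD requires at least one assigned object")
    ssw = 0.0
    dof = 0
    for idx in members:
        centroid = X[idx].mean(axis=0)
        ssw += float(((X[idx] - centroid) ** 2).sum())
        dof += len(idx) - 1
    dof *= X.shape[1]
    if dof == 0:
        return 0.0
    return math.sqrt(ssw / dof)


def index_report(data=None, predicted=None, truth=None,
                 *, metric: str = "euclidean") -> dict:
    """Compute every applicable index for a partition in one pass.

    External indices are included when ``truth`` is given, relative indices
    when ``data`` is given. Returns a plain dict suitable for
    :func:`vericlust.io.write_index_report`.
    """
    if predicted is None:
        raise InputError("a predicted partition is required")
    report: dict = {}
    if truth is not None:
        cm = confusion_matrix(predicted, truth)
        pc = pair_counts(predicted, truth)
        report.update(
            purity=purity(cm),
            entropy=entropy(cm),
            rand=rand(pc),
            jaccard=jaccard(pc),
            fowlkes_mallows=fowlkes_mallows(pc),
        )
    if data is not None:
        report["dunn"] = dunn(data, predicted, metric=metric)
        report["diam"] = max_diameter(data, predicted, metric=metric)
        X, members = _clusters_of(data, predicted)
        if len(members) >= 2:
            try:
                report["davies_bouldin"] = davies_bouldin(
                    data, predicted, metric=metric)
            except InputError:
                report["davies_bouldin"] = None
        else:
            report["davies_bouldin"] = None
        report["rmsstd"] = rmsstd(data, predicted) if members else None
    return report
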