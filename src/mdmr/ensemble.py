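"""Dimension reduction and density clustering of distance embeddings.

The feature matrices (all entries in Å) are mean-centered and projected
onto principal components; the smallest set of leading components whose
cumulative explained-variance ratio reaches the retention fraction
(default 0.75) is kept. Features are deliberately *not* standardized: they
share Å units, and the cluster-selection threshold ϵ̂ is meaningful only on
an unscaled Å-derived axis.

Clustering uses HDBSCAN on the retained principal-component scores with
``min_samples`` k = 5 and ``cluster_selection_epsilon`` ϵ̂ = 10.0 by
default; ϵ̂ keeps clusters closer than the threshold from being split
further. Points not assigned to any cluster are labeled −1 (noise).
The mutual-reachability construction underlying HDBSCAN —
d_mreach(i, j) = max(κ(i), κ(j), d(i, j)) with core distance κ(i) the
Euclidean distance to the kth nearest neighbor — is exposed for
diagnostics, together with a per-cluster stability score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

from .representation import FeatureMatrix
from .structio import Ligand, StructureRecord

__all__ = [
    "EnsembleProjection",
    "ClusterAssignment",
    "MutualReachabilityGraph",
    "pca_project",
    "mutual_reachability",
    "cluster",
    "cluster_stability",
    "filter_ligand_entries",
]


@dataclass
class EnsembleProjection:
    """PCA scores over retained components plus variance bookkeeping."""

    ids: list[str]
    scores: np.ndarray                  # (n_samples, m)
    explained_variance_ratio: np.ndarray  # retained components only
    loadings: np.ndarray                # (m, n_features)
    feature_labels: list[str]
    retention: float
    all_explained_variance_ratio: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    @property
    def cumulative_evr(self) -> float:
        return float(self.explained_variance_ratio.sum())

    def score_of(self, structure_id: str) -> np.ndarray:
        return self.scores[self.ids.index(structure_id)]


@dataclass
class ClusterAssignment:
    """Integer labels per structure; −1 marks noise."""

    ids: list[str]
    labels: np.ndarray
    k: int
    epsilon: float

    def label_of(self, structure_id: str) -> int:
        return int(self.labels[self.ids.index(structure_id)])

    def members(self, label: int) -> list[str]:
        return [i for i, l in zip(self.ids, self.labels) if l == label]

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels == -1))


@dataclass
class MutualReachabilityGraph:
    """Core distances κ and pairwise mutual reachability distances."""

    ids: list[str]
    core_distances: np.ndarray      # κ per point
    d_mreach: np.ndarray            # symmetric; diagonal = κ by convention
    k: int


def pca_project(features: FeatureMatrix, retention: float = 0.75) -> EnsembleProjection:
    """Mean-centered PCA keeping the fewest components with cumulative
    explained-variance ratio ≥ ``retention``.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores reproducible across runs.
    """
    X = np.asarray(features.X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("degenerate ensemble: all rows identical (rank 0)")

    pca = PCA()
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(evr), retention - 1e-12) + 1)
    m = min(m, scores.shape[1])

    loadings = pca.components_[:m].copy()
    kept = scores[:, :m].copy()
    for c in range(m):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] *= -1.0
            kept[:, c] *= -1.0

    return EnsembleProjection(
        ids=list(features.ids),
        scores=kept,
        explained_variance_ratio=evr[:m].copy(),
        loadings=loadings,
        feature_labels=list(features.labels),
        retention=retention,
        all_explained_variance_ratio=evr.copy(),
    )


def mutual_reachability(points: np.ndarray, k: int = 5,
                        ids: Optional[Sequence[str]] = None) -> MutualReachabilityGraph:
    """Mutual reachability distances d_mreach = max(κ_i, κ_j, d_ij).

    κ(X_i) is the Euclidean distance from X_i to its kth nearest neighbor
    (self excluded). Requires at least k+1 points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    d = cdist(points, points)
    kappa = np.sort(d, axis=1)[:, k]  # column 0 is the self distance
    dmr = np.maximum(d, np.maximum(kappa[:, None], kappa[None, :]))
    if ids is None:
        ids = [str(i) for i in range(n)]
    return MutualReachabilityGraph(ids=list(ids), core_distances=kappa,
                                   d_mreach=dmr, k=k)


def cluster(projection: EnsembleProjection | np.ndarray, k: int = 5,
            epsilon: float = 10.0,
            min_cluster_size: Optional[int] = None) -> ClusterAssignment:
    """Density clustering of PCA scores under the HDBSCAN contract.

    Delegates to scikit-learn's HDBSCAN (mutual-reachability construction
    plus excess-of-mass cluster selection) with ``min_samples=k`` and the
    ϵ̂ floor ``cluster_selection_epsilon=epsilon``. Labels are relabeled to
    contiguous integers in order of first appearance; unclustered points
    keep the noise label −1. Fewer than 2k points yields an all-noise
    assignment with a warning.
    """
    if isinstance(projection, EnsembleProjection):
        X, ids = projection.scores, projection.ids
    else:
        X = np.asarray(projection, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2 * k:
        warnings.warn(f"only {n} points for k={k}; assigning all to noise")
        return ClusterAssignment(ids=list(ids), labels=np.full(n, -1), k=k,
                                 epsilon=epsilon)
    mcs = min_cluster_size if min_cluster_size is not None else max(k, 2)
    model = HDBSCAN(min_cluster_size=mcs, min_samples=k, copy=True)
    raw = model.fit_predict(X)
    if epsilon > 0:
        raw = _apply_epsilon_floor(model._single_linkage_tree_, raw, X, k,
                                   epsilon)
    labels = _relabel_contiguous(raw)
    return ClusterAssignment(ids=list(ids), labels=labels, k=k, epsilon=epsilon)


def _apply_epsilon_floor(slt: np.ndarray, labels: np.ndarray, X: np.ndarray,
                         k: int, epsilon: float) -> np.ndarray:
    """Enforce the ϵ̂ cluster-selection floor on excess-of-mass labels.

    Cutting the mutual-reachability single-linkage dendrogram at ϵ̂ yields
    the components that a density level of ϵ̂ cannot split further; all
    excess-of-mass clusters falling inside one component are merged, and
    noise points of a merged component whose core distance is within ϵ̂
    (density-reachable at that level) join it. Components without any
    selected cluster stay noise.
    """
    from scipy.cluster.hierarchy import fcluster

    slt = np.asarray(slt)
    if slt.dtype.names:  # structured MST/linkage record array
        slt = np.column_stack([slt[name].astype(float)
                               for name in slt.dtype.names])
    comp = fcluster(slt, t=epsilon, criterion="distance")
    n = len(labels)
    kappa = (mutual_reachability(X, k=k).core_distances
             if n >= k + 1 else np.full(n, np.inf))
    out = labels.copy()
    for c in np.unique(comp):
        idx = comp == c
        present = sorted(set(labels[idx]) - {-1})
        if not present:
            continue
        target = present[0]
        for l in present[1:]:
            out[labels == l] = target
        absorb = idx & (labels == -1) & (kappa <= epsilon)
        out[absorb] = target
    return out


def _relabel_contiguous(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.full(raw.shape, -1, dtype=int)
    nxt = 0
    for i, l in enumerate(raw):
        if l < 0:
            continue
        if l not in mapping:
            mapping[l] = nxt
            nxt += 1
        out[i] = mapping[l]
    return out


def cluster_stability(graph: MutualReachabilityGraph,
                      labels: np.ndarray) -> dict[int, float]:
    """Per-cluster stability diagnostic S(C) = Σ_p (λ_p − λ_birth).

    λ = 1/d on the mutual-reachability scale: λ_p is taken as 1/κ(p) (the
    density level at which point p appears) and λ_birth as the reciprocal
    of the largest within-cluster mutual-reachability distance (the level
    at which the cluster becomes connected). This scores how persistently
    dense each selected cluster is; it is a diagnostic on a given
    partition, not the selection criterion itself.
    """
    out: dict[int, float] = {}
    for lab in sorted(set(int(l) for l in labels if l >= 0)):
        idx = np.flatnonzero(labels == lab)
        sub = graph.d_mreach[np.ix_(idx, idx)]
        birth_d = sub.max()
        lam_birth = 1.0 / birth_d if birth_d > 0 else np.inf
        lam_p = np.where(graph.core_distances[idx] > 0,
                         1.0 / graph.core_distances[idx], np.inf)
        out[lab] = float(np.sum(lam_p - lam_birth))
    return out


def filter_ligand_entries(records: Sequence[StructureRecord],
                          ) -> list[tuple[StructureRecord, Ligand]]:
    """Select (record, ligand) entries for ligand-mode analysis.

    Apo records are dropped, as are records where the same component code
    is bound more than once to one copy (the ligand-to-conformation
    correspondence is ambiguous there). Each surviving bound ligand yields
    one entry.
    """
    out: list[tuple[StructureRecord, Ligand]] = []
    for rec in records:
        if not rec.ligands:
            continue
        codes = [l.code for l in rec.ligands]
        if any(codes.count(c) > 1 for c in codes):
            continue
        for lig in rec.ligands:
            out.append((rec, lig))
    return out
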