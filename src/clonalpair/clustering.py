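"""Agglomerative hierarchical clustering of SCNA profiles.

The cohort question is whether each primary tumor and its matched metastasis
are "most closely related" in an unsupervised tree built from their binned
copy-number profiles — operationalised strictly as dendrogram siblinghood:
the pair's two leaves merge with each other before either merges with
anything else.  The fraction of pairs grouped this way is the cohort's
SCNA-level concordance.

The agglomerator is written out explicitly rather than delegated, because
the pair-adjacency criterion depends on the exact merge sequence and
therefore on a documented deterministic tie-break: when several cluster
pairs sit at the minimal distance, the pair whose (creation-index, creation-
index) label is lexicographically smallest merges first.  Leaves are numbered
0..n-1 in input order and the cluster created by merge *k* gets index n+k
(the familiar linkage-matrix convention), so results are reproducible
bit-for-bit and comparable with standard implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_formats import CohortManifest
from .scna import CnvMatrix

METRICS = ("euclidean", "manhattan", "correlation")
LINKAGES = ("complete", "average", "single")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered list of samples."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix has nonzero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float


@dataclass
class Dendrogram:
    """Merge sequence of an agglomerative clustering.

    ``leaves[i]`` is leaf index *i*; merge *k* creates cluster ``n + k``.
    """

    leaves: list[str]
    merges: list[Merge]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram on n leaves has exactly n-1 merges")

    def leaf_index(self, sample_id: str) -> int:
        try:
            return self.leaves.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown leaf {sample_id!r}") from None

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node = {i: f"{self.leaves[i]}" for i in range(n)}
        for k, m in enumerate(self.merges):
            for child in (m.left, m.right):
                bl = m.height - height[child]
                node[child] = f"{node[child]}:{bl:g}"
            node[n + k] = f"({node[m.left]},{node[m.right]})"
            height[n + k] = m.height
        return node[n + len(self.merges) - 1] + ";"


def pairwise_distance(
    matrix: CnvMatrix, metric: str = "euclidean", loh_weight: float = 1.0
) -> DistanceMatrix:
    """Pairwise distances between samples' binned profiles.

    The LOH layer is appended to the copy-number bins at ``loh_weight``
    before the metric is applied.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    features = matrix.features(loh_weight=loh_weight)
    if features.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    scipy_metric = {"manhattan": "cityblock"}.get(metric, metric)
    dense = squareform(pdist(features, metric=scipy_metric))
    # correlation distance on constant rows yields NaN; treat as maximal (1)
    dense = np.nan_to_num(dense, nan=1.0)
    np.fill_diagonal(dense, 0.0)
    return DistanceMatrix(sample_ids=list(matrix.sample_ids), values=dense)


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerate by repeatedly merging the closest pair of clusters.

    Inter-cluster distance is the maximum (complete), mean (average) or
    minimum (single) over cross-pairs, maintained with the Lance-Williams
    update.  Ties on the minimal distance break toward the lexicographically
    smallest (left, right) cluster-index pair.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = len(dist)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist.values[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[Merge] = []

    for k in range(n - 1):
        # min distance, then lexicographic (i, j) — both via tuple ordering
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        new = n + k
        merges.append(Merge(left=i, right=j, height=h))
        for other in sorted(active - {i, j}):
            a, b = (min(other, i), max(other, i)), (min(other, j), max(other, j))
            di, dj = d.pop(a), d.pop(b)
            if linkage == "complete":
                dn = max(di, dj)
            elif linkage == "single":
                dn = min(di, dj)
            else:  # average: size-weighted mean over cross-pairs
                dn = (size[i] * di + size[j] * dj) / (size[i] + size[j])
            d[(other, new)] = dn
        d.pop((i, j))
        active -= {i, j}
        active.add(new)
        size[new] = size[i] + size[j]
    return Dendrogram(leaves=list(dist.sample_ids), merges=merges)


def leaf_pair_adjacent(tree: Dendrogram, a: str, b: str) -> bool:
    """True iff leaves ``a`` and ``b`` are dendrogram siblings.

    Equivalently: the first merge involving either leaf merges exactly the
    two singleton clusters {a} and {b}.
    """
    ia, ib = tree.leaf_index(a), tree.leaf_index(b)
    lo, hi = min(ia, ib), max(ia, ib)
    return any(m.left == lo and m.right == hi for m in tree.merges)


@dataclass
class AdjacencyResult:
    """Per-pair sibling flags and the cohort fraction grouped."""

    per_pair: dict[str, bool]

    @property
    def fraction_grouped(self) -> float:
        if not self.per_pair:
            return 0.0
        return sum(self.per_pair.values()) / len(self.per_pair)


def cohort_adjacency(tree: Dendrogram, manifest: CohortManifest) -> AdjacencyResult:
    """Dendrogram-siblinghood call for every pair in the manifest."""
    flags = {}
    for pair in manifest:
        flags[pair.patient_id] = leaf_pair_adjacent(
            tree, pair.primary_sample_id, pair.metastasis_sample_id
        )
    return AdjacencyResult(per_pair=flags)


def mutual_nearest_neighbors(dist: DistanceMatrix, a: str, b: str) -> bool:
    """Relaxed relatedness criterion: a and b are each other's nearest sample.

    Provided for sensitivity analysis alongside strict siblinghood.
    """
    ids: Sequence[str] = dist.sample_ids
    ia, ib = ids.index(a), ids.index(b)
    row_a = dist.values[ia].copy()
    row_b = dist.values[ib].copy()
    row_a[ia] = np.inf
    row_b[ib] = np.inf
    return int(np.argmin(row_a)) == ib and int(np.argmin(row_b)) == ia
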