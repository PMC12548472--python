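"""Mixed-data distances, complete-linkage clustering and silhouette k-selection.

The chain mirrors how phage phenotypes are grouped in practice: Gower
distance handles tables mixing binary host-range bits with quantitative
physiology measurements; phylogeny-based classifications enter the same
chain as patristic distance matrices computed from Newick trees; clusters
come from complete-linkage agglomeration, and the number of clusters is
chosen by maximizing the average silhouette width over a k sweep.

Determinism: equal-distance merge candidates are broken by the
lexicographically smallest pair of cluster indices (in cluster-creation
order), and silhouette ties in the k sweep resolve to the smallest k.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io import (
    Dendrogram,
    DistanceMatrix,
    Partition,
    PhenotypeTable,
    SilhouetteSweep,
)

__all__ = [
    "gower_matrix",
    "patristic_distances",
    "hclust_complete",
    "cut_k",
    "silhouette_avg",
    "select_k",
]


def gower_matrix(table: PhenotypeTable,
                 weights: Mapping[str, float] | None = None) -> DistanceMatrix:
    """Gower dissimilarity over mixed binary/quantitative features.

    d_ij = sum_f w_f * delta_f(i, j) / sum_f w_f, the sums running over
    features observed in both items (pairwise deletion). Binary features
    contribute a 0/1 mismatch; quantitative features contribute
    |x_i - x_j| / range_f with the range taken over observed values;
    zero-range features contribute 0 but still count toward the weight
    normalization.
    """
    n = len(table.phage_ids)
    if n < 2:
        raise ValueError("Gower distance needs at least two phages")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for spec in table.features:
        w = weights[spec.name] if weights and spec.name in weights else spec.weight
        if w < 0:
            raise ValueError(f"negative weight for feature {spec.name!r}")
        col = table.values[spec.name].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        pair_obs = np.outer(obs, obs)
        if spec.kind == "binary":
            delta = (col[:, None] != col[None, :]).astype(float)
        else:
            observed = col[obs]
            rng = observed.max() - observed.min() if observed.size else 0.0
            if rng > 0:
                delta = np.abs(col[:, None] - col[None, :]) / rng
            else:
                delta = np.zeros((n, n))
        delta = np.where(pair_obs, delta, 0.0)
        num += w * delta
        den += w * pair_obs
    uncovered = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))
    if uncovered.size:
        i, j = uncovered[0]
        raise ValueError(
            f"phages {table.phage_ids[i]!r} and {table.phage_ids[j]!r} share no "
            "observed feature with positive weight"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.phage_ids), d)


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the leaf-to-leaf path, for every leaf pair."""
    leaves = list(tree.leaf_node_iter())
    ids = [leaf.taxon.label for leaf in leaves]
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            if node.edge.length is None:
                raise ValueError("tree has a missing branch length")
            if node.edge.length < 0:
                raise ValueError(f"negative branch length: {node.edge.length}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
    return DistanceMatrix(ids, d)


def hclust_complete(d: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomeration of a distance matrix.

    At each step the pair of clusters with the smallest maximum pairwise
    member distance is merged; ties go to the lexicographically smallest
    (i, j) over cluster indices in creation order. Merge heights are
    monotone for complete linkage.
    """
    n = len(d)
    if n < 2:
        raise ValueError("clustering needs at least two items")

    # cluster-to-cluster complete-linkage distances, indexed by node id
    # (leaves 0..n-1, merge i creates node n+i)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])
    active: list[int] = list(range(n))
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                h = get(a, b)
                if best is None or h < best[0]:
                    best = (h, a, b)
                # ties resolved by (a, b) order of the scan, which is
                # lexicographic in creation-order indices
        h, a, b = best
        size = sizes[a] + sizes[b]
        merges.append((a, b, h, size))
        for c in active:
            if c not in (a, b):
                nd = max(get(a, c), get(b, c))
                dist[(c, next_id) if c < next_id else (next_id, c)] = nd
        active = [c for c in active if c not in (a, b)] + [next_id]
        sizes[next_id] = size
        next_id += 1

    return Dendrogram(list(d.item_ids), merges)


def cut_k(dendrogram: Dendrogram, k: int) -> Partition:
    """Cut the dendrogram into k clusters by undoing the k-1 highest merges.

    Cluster labels are "1", "2", ... in order of each cluster's first leaf.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + max(n - 1, 0)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (left, right, _, _) in enumerate(dendrogram.merges[: n - k]):
        node = n + m
        parent[find(left)] = node
        parent[find(right)] = node

    labels_by_root: dict[int, str] = {}
    labels: list[str] = []
    for leaf in range(n):
        root = find(leaf)
        if root not in labels_by_root:
            labels_by_root[root] = str(len(labels_by_root) + 1)
        labels.append(labels_by_root[root])
    return Partition(list(dendrogram.leaf_ids), labels)


def silhouette_avg(d: DistanceMatrix, p: Partition) -> float:
    """Average silhouette width s(i) = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the item's own cluster (excluding itself),
    b_i the smallest mean distance to any other cluster. Items in singleton
    clusters score 0 (standard convention), as do items with
    max(a_i, b_i) = 0.
    """
    order = {item: i for i, item in enumerate(d.item_ids)}
    if set(p.item_ids) != set(d.item_ids):
        raise ValueError("partition and distance matrix cover different items")
    labels = np.empty(len(d), dtype=object)
    for item, lab in zip(p.item_ids, p.labels):
        labels[order[item]] = lab
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")

    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}
    scores = np.zeros(len(d))
    for i in range(len(d)):
        own = members[labels[i]]
        if len(own) == 1:
            scores[i] = 0.0
            continue
        a = d.values[i, own[own != i]].mean()
        b = min(d.values[i, members[lab]].mean() for lab in uniq if lab != labels[i])
        m = max(a, b)
        scores[i] = 0.0 if m == 0 else (b - a) / m
    return float(scores.mean())


def select_k(d: DistanceMatrix, k_min: int = 2, k_max: int | None = None) -> SilhouetteSweep:
    """Sweep k over complete-linkage cuts and pick the silhouette argmax.

    Default sweep is 2..min(10, n-1); ties resolve to the smallest k.
    """
    n = len(d)
    if k_max is None:
        k_max = min(10, n - 1)
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError(f"need 2 <= k_min <= k_max <= n-1 (= {n - 1}); "
                         f"got k_min={k_min}, k_max={k_max}")
    dendro = hclust_complete(d)
    ks = list(range(k_min, k_max + 1))
    scores = [silhouette_avg(d, cut_k(dendro, k)) for k in ks]
    best = max(scores)
    chosen = min(k for k, s in zip(ks, scores) if s == best)
    return SilhouetteSweep(ks, scores, chosen)
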