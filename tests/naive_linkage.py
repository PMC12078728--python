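"""Brute-force Lance-Williams agglomeration used as an oracle in tests.

Clusters are nested tuples of leaf indices; every inter-cluster
dissimilarity is recomputed from scratch by recursion on the merge trees,
independently of the incremental matrix updates the package uses.
"""

import numpy as np


def _leaves(tree):
    if isinstance(tree, int):
        return (tree,)
    return _leaves(tree[0]) + _leaves(tree[1])


def _size(tree):
    return len(_leaves(tree))


def cluster_distance(a, b, delta, method):
    """Dissimilarity between two merge trees on the working scale."""
    if isinstance(a, int) and isinstance(b, int):
        return delta[a, b]
    if not isinstance(a, int):
        a1, a2 = a
        d_ac = cluster_distance(a1, b, delta, method)
        d_bc = cluster_distance(a2, b, delta, method)
        d_ab = cluster_distance(a1, a2, delta, method)
        n_a, n_b, n_c = _size(a1), _size(a2), _size(b)
    else:
        return cluster_distance(b, a, delta, method)
    if method in ("ward.d", "ward.d2"):
        tot = n_a + n_b + n_c
        return ((n_a + n_c) * d_ac + (n_b + n_c) * d_bc - n_c * d_ab) / tot
    if method == "single":
        return min(d_ac, d_bc)
    if method == "complete":
        return max(d_ac, d_bc)
    if method == "average":
        return (n_a * d_ac + n_b * d_bc) / (n_a + n_b)
    raise ValueError(method)


def naive_agglomerate(square_delta, method):
    """O(n^3)-ish agglomeration recomputing all pair costs each step.

    Returns (heights, partitions): the merge heights in order and the list
    of partitions (sets of frozensets of leaves) after each merge.  Uses
    the same tie-break as the package: smallest (left id, right id), ids
    being creation order.
    """
    delta = np.asarray(square_delta, dtype=float)
    if method == "ward.d2":
        delta = delta**2
    n = delta.shape[0]
    clusters = {i: i for i in range(n)}  # id -> tree
    next_id = n
    heights, partitions = [], []
    for _ in range(n - 1):
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                d = cluster_distance(clusters[i], clusters[j], delta, method)
                if best is None or d < best[0] - 1e-12 or (
                    abs(d - best[0]) <= 1e-12 and (i, j) < best[1:]
                ):
                    best = (d, i, j)
        d, i, j = best
        heights.append(np.sqrt(d) if method == "ward.d2" else d)
        clusters[next_id] = (clusters.pop(i), clusters.pop(j))
        next_id += 1
        partitions.append(
            {frozenset(_leaves(t)) for t in clusters.values()}
        )
    return np.array(heights), partitions


def linkage_partitions(linkage):
    """Partition trace (sets of frozensets) from a package Linkage."""
    n = linkage.n
    trees = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (left, right, _, _) in enumerate(linkage.merges):
        trees[n + step] = trees.pop(int(left)) | trees.pop(int(right))
        out.append(set(trees.values()))
    return out
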