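"""Brute-force agglomeration oracles, independent of the package's
Lance-Williams implementation.

At every step the distance between each active pair of clusters is recomputed
from first principles: WPGMA by the recursive definition over the original
pairwise distances, Ward by the minimum-variance formula over the raw member
coordinates.  Ties break on the lexicographically smallest (id_a, id_b) pair,
with leaves numbered 0..n-1 and merge i creating cluster n+i.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _wpgma_dist(tree_a, tree_b, d0) -> float:
    if isinstance(tree_a, int) and isinstance(tree_b, int):
        return d0[tree_a, tree_b]
    if not isinstance(tree_a, int):
        left, right = tree_a
        return 0.5 * (_wpgma_dist(left, tree_b, d0) + _wpgma_dist(right, tree_b, d0))
    left, right = tree_b
    return 0.5 * (_wpgma_dist(tree_a, left, d0) + _wpgma_dist(tree_a, right, d0))


def _leaves(tree) -> list[int]:
    if isinstance(tree, int):
        return [tree]
    return _leaves(tree[0]) + _leaves(tree[1])


def naive_agglomerate(points: np.ndarray, linkage: str) -> list[tuple[int, int, float, int]]:
    """Merge list (id_a, id_b, height, size) for WPGMA or Ward."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    d0 = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    trees: dict[int, object] = {i: i for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i, j in itertools.combinations(sorted(trees), 2):
            if linkage == "wpgma":
                dij = _wpgma_dist(trees[i], trees[j], d0)
            elif linkage == "ward":
                la, lb = _leaves(trees[i]), _leaves(trees[j])
                ca, cb = points[la].mean(axis=0), points[lb].mean(axis=0)
                na, nb = len(la), len(lb)
                dij = math.sqrt(2.0 * na * nb / (na + nb)) * float(
                    np.linalg.norm(ca - cb)
                )
            else:
                raise ValueError(linkage)
            if best is None or dij < best[0] - 1e-15:
                best = (dij, i, j)
        dij, i, j = best
        size = len(_leaves(trees[i])) + len(_leaves(trees[j]))
        merges.append((i, j, dij, size))
        trees[next_id] = (trees[i], trees[j])
        del trees[i], trees[j]
        next_id += 1
    return merges
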