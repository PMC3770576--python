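"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: spanning topologies
are enumerated via Prufer sequences, and permutation p-values by exhaustive
enumeration of group relabellings.
"""

from functools import lru_cache
from itertools import combinations, product

import numpy as np


@lru_cache(maxsize=None)
def prufer_trees(n: int) -> np.ndarray:
    """All labeled trees on n nodes as an (n^(n-2), n-1, 2) edge array."""
    if n == 1:
        return np.zeros((1, 0, 2), dtype=np.int64)
    if n == 2:
        return np.array([[[0, 1]]], dtype=np.int64)
    trees = []
    for seq in product(range(n), repeat=n - 2):
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        seq_list = list(seq)
        edges = []
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        import heapq

        heapq.heapify(leaves)
        for x in seq_list:
            leaf = heapq.heappop(leaves)
            edges.append((leaf, x))
            degree[x] -= 1
            if degree[x] == 1:
                heapq.heappush(leaves, x)
        u, v = leaves
        edges.append((u, v))
        trees.append(edges)
    return np.array(trees, dtype=np.int64)


def min_connection_weight(D: np.ndarray) -> int:
    """Minimum total edge count over all spanning topologies.

    Each inter-haplotype connection of Hamming distance d contributes d
    single-mutation edges; the minimum over all Prufer-enumerated spanning
    trees is the parsimony lower bound used as the network-size oracle.
    """
    n = D.shape[0]
    if n == 1:
        return 0
    trees = prufer_trees(n)
    weights = D[trees[:, :, 0], trees[:, :, 1]].sum(axis=1)
    return int(weights.min())


def exhaustive_group_f_pvalue(y: np.ndarray, n_a: int, f_obs: float) -> float:
    """Classical two-sample permutation p over all group relabellings.

    Enumerates every choice of which individuals form group A (statistic:
    pooled-variance F = squared two-sample t) and counts assignments whose F
    meets or exceeds the observed one.
    """
    y = np.asarray(y, float)
    n = len(y)
    idx = range(n)
    count = 0
    total = 0
    for combo in combinations(idx, n_a):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        ya, yb = y[mask], y[~mask]
        va = ya.var(ddof=1) if len(ya) > 1 else 0.0
        vb = yb.var(ddof=1) if len(yb) > 1 else 0.0
        sp2 = ((len(ya) - 1) * va + (len(yb) - 1) * vb) / (n - 2)
        if sp2 == 0:
            f = np.inf if ya.mean() != yb.mean() else 0.0
        else:
            t = (ya.mean() - yb.mean()) / np.sqrt(sp2 * (1 / len(ya) + 1 / len(yb)))
            f = t * t
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return count / total
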