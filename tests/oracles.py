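"""Independent oracles used across the test suite.

Each is a deliberately naive reimplementation (brute force, enumeration, or
direct formula) kept free of any package internals so it can check the
production code paths.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def brute_force_patristic(newick: str):
    """Leaf-pair distances via symmetric difference of root-to-leaf edge paths."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(node.edge)
            node = node.parent_node
        paths[leaf.taxon.label] = set(edges)
    labels = sorted(paths)
    p = len(labels)
    D = np.zeros((p, p))
    for i, j in itertools.combinations(range(p), 2):
        d = sum(e.length for e in paths[labels[i]] ^ paths[labels[j]])
        D[i, j] = D[j, i] = d
    return labels, D


def pam_cost(dist: np.ndarray, medoids) -> float:
    return float(dist[:, list(medoids)].min(axis=1).sum())


def exhaustive_k2_cost(dist: np.ndarray) -> float:
    """Global optimum of the 2-medoid objective by enumerating all pairs."""
    p = dist.shape[0]
    return min(pam_cost(dist, pair)
               for pair in itertools.combinations(range(p), 2))


def silhouette_direct(dist: np.ndarray, labels: np.ndarray) -> float:
    """Per-point a/b/s recomputation straight from the definition."""
    s = []
    for i in range(dist.shape[0]):
        own = labels[i]
        mates = [j for j in range(dist.shape[0]) if labels[j] == own and j != i]
        if not mates:
            s.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in mates])
        b = min(np.mean([dist[i, j] for j in range(dist.shape[0])
                         if labels[j] == other])
                for other in set(labels) if other != own)
        denom = max(a, b)
        s.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(s))


def exhaustive_best_split(X: np.ndarray, y: np.ndarray, task: str):
    """Best (feature, threshold) by full enumeration of features x midpoints.

    Minimizes the weighted child impurity (Gini or variance); ties break
    toward the lower feature index, then the lower threshold, mirroring the
    documented policy.
    """
    m, p = X.shape
    best = None
    for f in range(p):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            mask = X[:, f] <= thr
            crit = 0.0
            for part in (y[mask], y[~mask]):
                if task == "classification":
                    q = part.mean()
                    crit += len(part) * 2 * q * (1 - q)   # n * Gini
                else:
                    crit += len(part) * part.var()        # n * variance
            if best is None or crit < best[0] - 1e-12:
                best = (crit, f, thr)
    return None if best is None else (best[1], best[2])
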