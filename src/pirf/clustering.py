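"""Phylogenetic clusters via partitioning around medoids (PAM).

Features are grouped on the cophenetic distance matrix with the classical
Kaufman-Rousseeuw PAM: a greedy BUILD initialization followed by SWAP passes
that exchange a medoid for a non-medoid whenever that strictly lowers the
objective (the sum over features of the distance to their cluster's medoid).
The number of clusters is chosen by maximizing the average silhouette width
over a small range, 2-10 by default.

Everything here is deterministic: BUILD and SWAP involve no randomness, and
all ties (equidistant medoids, equally good swaps, equal silhouettes) break
toward the lower index / smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phylo import DistanceMatrix

__all__ = ["ClusterAssignment", "pam", "avg_silhouette_width", "select_k_phylo"]

_TOL = 1e-12


@dataclass
class ClusterAssignment:
    """A partition of features into k mutually exclusive, exhaustive clusters.

    ``cluster_of`` maps each feature (by position in ``labels``) to a cluster
    index in 0..k-1; clusters are ordered by ascending medoid feature index.
    """

    labels: tuple
    cluster_of: np.ndarray          # (p,) int, values in 0..k-1
    medoids: np.ndarray             # (k,) feature indices, ascending
    k: int
    cost: float                     # PAM objective at the returned solution
    build_cost: float               # objective after BUILD (before SWAP)
    avg_silhouette: Optional[float] = None

    def __post_init__(self):
        self.cluster_of = np.asarray(self.cluster_of, dtype=int)
        self.medoids = np.asarray(self.medoids, dtype=int)
        p = len(self.labels)
        sizes = np.bincount(self.cluster_of, minlength=self.k)
        if sizes.sum() != p or np.any(sizes <= 0):
            raise ValidationError("clusters must be mutually exclusive and "
                                  "exhaustive with no empty cluster")
        if any(self.cluster_of[m] != j for j, m in enumerate(self.medoids)):
            raise ValidationError("each medoid must belong to its own cluster")

    @property
    def cluster_sizes(self) -> np.ndarray:
        """q_k: number of features in each cluster."""
        return np.bincount(self.cluster_of, minlength=self.k)

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_of == j)

    def to_frame(self) -> pd.DataFrame:
        """Feature -> cluster table (with medoids flagged) for TSV export."""
        return pd.DataFrame({
            "feature": list(self.labels),
            "cluster": self.cluster_of + 1,
            "is_medoid": np.isin(np.arange(len(self.labels)), self.medoids),
        })


def _check_dist(dist: DistanceMatrix) -> np.ndarray:
    if not isinstance(dist, DistanceMatrix):
        d = np.asarray(dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance input must be a square matrix")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValidationError("distance input must be symmetric")
        return d
    return dist.values


def pam(dist: DistanceMatrix, k: int) -> ClusterAssignment:
    """Classical PAM (BUILD + SWAP) on a distance matrix.

    Returns a local optimum of the k-medoids objective; SWAP never increases
    it, so ``cost <= build_cost`` always. Features are assigned to their
    nearest medoid (ties toward the lower cluster index), and each medoid is
    assigned to its own cluster even under degenerate all-equal distances.
    """
    d = _check_dist(dist)
    labels = dist.labels if isinstance(dist, DistanceMatrix) else \
        tuple(str(i) for i in range(d.shape[0]))
    p = d.shape[0]
    if not 1 <= k <= p:
        raise ValidationError(f"k={k} out of range [1, {p}]")

    # Ties everywhere break by lexicographic label order, which keeps the
    # partition invariant under permutation of the input order (exact gain
    # ties are generic, e.g. two candidates covering an isolated pair).
    rank = np.empty(p, dtype=int)
    rank[np.argsort(np.asarray(labels, dtype=object))] = np.arange(p)

    def _pick(values, best_is_min: bool):
        vals = values if best_is_min else -values
        best = np.nanmin(vals)
        eps = 1e-9 * (1.0 + abs(best))
        tied = np.flatnonzero(vals <= best + eps)
        return int(tied[np.argmin(rank[tied])])

    # BUILD: first medoid minimizes total distance; each subsequent medoid
    # maximizes the decrease in the objective.
    totals = d.sum(axis=0)
    medoids = [_pick(totals, True)]
    dnear = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = _pick(gains, False)
        medoids.append(h)
        dnear = np.minimum(dnear, d[:, h])
    build_cost = float(dnear.sum())

    # SWAP: best-improvement passes until no swap lowers the objective.
    cost = build_cost
    while True:
        med = np.asarray(sorted(medoids, key=lambda m: rank[m]))
        dmed = d[:, med]                       # (p, k)
        order = np.argsort(dmed, axis=1, kind="stable")
        d1 = np.take_along_axis(dmed, order[:, :1], axis=1).ravel()
        if k > 1:
            d2 = np.take_along_axis(dmed, order[:, 1:2], axis=1).ravel()
        else:
            d2 = np.full(p, np.inf)
        nearest = med[order[:, 0]]
        in_med = set(int(m) for m in med)
        best = (0.0, None, None)
        for m in med:
            base = np.where(nearest == m, d2, d1)
            for h in range(p):
                if h in in_med:
                    continue
                newcost = float(np.minimum(base, d[:, h]).sum())
                delta = newcost - cost
                eps = 1e-9 * (1.0 + abs(best[0]))
                if delta < best[0] - eps or (
                        best[1] is not None and abs(delta - best[0]) <= eps
                        and (rank[m], rank[h]) < (rank[best[1]],
                                                  rank[best[2]])):
                    best = (delta, int(m), h)
        if best[1] is None:
            break
        medoids[medoids.index(best[1])] = best[2]
        cost += best[0]

    med = np.asarray(sorted(medoids, key=lambda m: rank[m]))
    # nearest-medoid assignment; ties toward the lower cluster index (which
    # is label order, hence permutation-stable)
    dmed = d[:, med]
    mins = dmed.min(axis=1)
    eps = 1e-9 * (1.0 + np.abs(mins))
    cluster_of = np.argmax(dmed <= (mins + eps)[:, None], axis=1)
    cluster_of[med] = np.arange(k)             # medoid owns its cluster
    cost = float(d[np.arange(p), med[cluster_of]].sum())
    return ClusterAssignment(labels=tuple(labels), cluster_of=cluster_of,
                             medoids=med, k=k, cost=cost,
                             build_cost=build_cost)


def avg_silhouette_width(dist: DistanceMatrix,
                         assignment: ClusterAssignment) -> float:
    """Average silhouette width of a partition.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance from i
    to the other members of its cluster and b(i) the smallest mean distance
    from i to another cluster; s(i) = 0 for members of singleton clusters
    (Rousseeuw's convention), and 0/0 is taken as 0.
    """
    d = _check_dist(dist)
    if assignment.k < 2:
        raise ValidationError("silhouette is undefined for k=1")
    p = d.shape[0]
    sizes = assignment.cluster_sizes
    # mean distance from every point to every cluster
    sums = np.zeros((p, assignment.k))
    for j in range(assignment.k):
        sums[:, j] = d[:, assignment.members(j)].sum(axis=1)
    own = assignment.cluster_of
    s = np.zeros(p)
    for i in range(p):
        qi = sizes[own[i]]
        if qi == 1:
            continue
        a = sums[i, own[i]] / (qi - 1)
        others = [sums[i, j] / sizes[j]
                  for j in range(assignment.k) if j != own[i]]
        b = min(others)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_k_phylo(dist: DistanceMatrix,
                   k_range: Optional[tuple] = None) -> ClusterAssignment:
    """Choose the number of phylogenetic clusters by average silhouette width.

    Runs PAM for every k in ``k_range`` (default [2, min(10, p-1)]) and
    returns the partition with the largest average silhouette width, ties
    broken toward the smaller k.
    """
    d = _check_dist(dist)
    p = d.shape[0]
    if p < 3:
        raise ValidationError(
            f"need at least 3 features to cluster non-trivially (got {p})")
    if k_range is None:
        k_range = (2, 10)
    lo = max(2, int(k_range[0]))
    hi = min(int(k_range[1]), p - 1)
    if hi < lo:
        hi = lo
    best = None
    for k in range(lo, hi + 1):
        assignment = pam(dist, k)
        sil = avg_silhouette_width(dist, assignment)
        assignment.avg_silhouette = sil
        if best is None or sil > best.avg_silhouette + _TOL:
            best = assignment
    return best
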