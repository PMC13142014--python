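"""Numba kernels for tree growing, traversal, and permutation importance.

These implement the inner loops of the forest; all policy (candidate
weighting, stopping rules, tie-breaks) is documented in :mod:`pirf.forest`.
Tie-breaks are realized by scanning candidates in ascending feature order
and thresholds in ascending value order, keeping the first strict maximum
of the split criterion.

task codes: 0 = classification (y is 0/1), 1 = regression.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CLASSIFICATION = 0
REGRESSION = 1


@njit(cache=True)
def grow_tree_kernel(X, y, task, mtry, pos_idx, wpos, min_node_size,
                     boot, rng):
    """Grow one CART tree on the bootstrap rows ``boot``.

    Returns flat arrays (feature, threshold, left, right, value, n_nodes).
    Nodes are created in preorder; sample-index segments are partitioned in
    place. Candidate features at each node are a weighted sample without
    replacement (Efraimidis-Spirakis exponential keys over the positive
    weights), sorted ascending so criterion ties break toward the lower
    feature index.
    """
    n = boot.shape[0]
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int32)
    threshold = np.full(max_nodes, np.nan, np.float64)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    value = np.zeros(max_nodes, np.float64)

    idx = boot.copy()
    buf = np.empty(n, np.int64)
    npos = pos_idx.shape[0]
    k_draw = mtry if mtry < npos else npos
    keys = np.empty(npos, np.float64)
    cand = np.empty(npos, np.int64)

    # preorder stack over (start, end, parent, is_left)
    st_s = np.empty(max_nodes, np.int64)
    st_e = np.empty(max_nodes, np.int64)
    st_p = np.empty(max_nodes, np.int64)
    st_l = np.empty(max_nodes, np.uint8)
    sp = 0
    st_s[0] = 0
    st_e[0] = n
    st_p[0] = -1
    st_l[0] = 0
    sp = 1
    n_nodes = 0

    while sp > 0:
        sp -= 1
        s = st_s[sp]
        e = st_e[sp]
        parent = st_p[sp]
        is_left = st_l[sp]
        nid = n_nodes
        n_nodes += 1
        if parent >= 0:
            if is_left == 1:
                left[parent] = nid
            else:
                right[parent] = nid

        m = e - s
        tot = 0.0
        ymin = y[idx[s]]
        ymax = ymin
        for i in range(s, e):
            yi = y[idx[i]]
            tot += yi
            if yi < ymin:
                ymin = yi
            if yi > ymax:
                ymax = yi
        value[nid] = tot / m
        if m < 2 or m < min_node_size or ymin == ymax:
            continue

        # weighted candidate draw without replacement
        if k_draw == npos:
            for t in range(npos):
                cand[t] = pos_idx[t]
        else:
            for t in range(npos):
                u = rng.random()
                keys[t] = -np.log1p(-u) / wpos[t]
            order = np.argsort(keys)
            for t in range(k_draw):
                cand[t] = pos_idx[order[t]]
            cand[:k_draw].sort()

        best_score = -np.inf
        best_f = -1
        best_thr = 0.0
        for ci in range(k_draw):
            f = cand[ci]
            v = np.empty(m, np.float64)
            yy = np.empty(m, np.float64)
            for i in range(m):
                v[i] = X[idx[s + i], f]
                yy[i] = y[idx[s + i]]
            order = np.argsort(v)
            cum = 0.0
            for t in range(1, m):
                cum += yy[order[t - 1]]
                lo = v[order[t - 1]]
                hi = v[order[t]]
                if hi <= lo:
                    continue
                if task == CLASSIFICATION:
                    ln = float(t)
                    rn = float(m - t)
                    lpos = cum
                    rpos = tot - cum
                    score = ((lpos * lpos + (ln - lpos) * (ln - lpos)) / ln
                             + (rpos * rpos + (rn - rpos) * (rn - rpos)) / rn)
                else:
                    score = (cum * cum / t
                             + (tot - cum) * (tot - cum) / (m - t))
                if score > best_score:
                    best_score = score
                    best_f = f
                    thr = 0.5 * (lo + hi)
                    if thr >= hi:      # midpoint of adjacent doubles can
                        thr = lo       # round up; fall back to the lower value
                    best_thr = thr
        if best_f < 0:
            continue

        # stable in-place partition of the segment
        nl = 0
        nr = 0
        for i in range(s, e):
            if X[idx[i], best_f] <= best_thr:
                idx[s + nl] = idx[i]
                nl += 1
            else:
                buf[nr] = idx[i]
                nr += 1
        if nl == 0 or nr == 0:         # degenerate numeric split: keep leaf
            continue
        for i in range(nr):
            idx[s + nl + i] = buf[i]
        feature[nid] = best_f
        threshold[nid] = best_thr
        # push right first so the left child is processed next (preorder)
        st_s[sp] = s + nl
        st_e[sp] = e
        st_p[sp] = nid
        st_l[sp] = 0
        sp += 1
        st_s[sp] = s
        st_e[sp] = s + nl
        st_p[sp] = nid
        st_l[sp] = 1
        sp += 1

    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], value[:n_nodes])


@njit(cache=True)
def apply_kernel(feature, threshold, left, right, X):
    """Leaf index reached by every row of X."""
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        nid = 0
        while feature[nid] >= 0:
            if X[i, feature[nid]] <= threshold[nid]:
                nid = left[nid]
            else:
                nid = right[nid]
        out[i] = nid
    return out


@njit(cache=True)
def _tree_loss(feature, threshold, left, right, value, X, y, task):
    n = X.shape[0]
    loss = 0.0
    for i in range(n):
        nid = 0
        while feature[nid] >= 0:
            if X[i, feature[nid]] <= threshold[nid]:
                nid = left[nid]
            else:
                nid = right[nid]
        if task == CLASSIFICATION:
            pred = 1.0 if value[nid] > 0.5 else 0.0
            if pred != y[i]:
                loss += 1.0
        else:
            d = value[nid] - y[i]
            loss += d * d
    return loss / n


@njit(cache=True)
def perm_importance_kernel(feature, threshold, left, right, value,
                           Xo, yo, task, used, n_permutations, rng):
    """Mean OOB-loss increase per feature of one tree.

    ``used`` lists the features the tree splits on; others stay at 0.
    Each feature's OOB column is shuffled (Fisher-Yates) ``n_permutations``
    times and the loss increase averaged.
    """
    m = Xo.shape[0]
    p = Xo.shape[1]
    scores = np.zeros(p, np.float64)
    base = _tree_loss(feature, threshold, left, right, value, Xo, yo, task)
    col = np.empty(m, np.float64)
    for k in range(used.shape[0]):
        j = used[k]
        for i in range(m):
            col[i] = Xo[i, j]
        inc = 0.0
        for _ in range(n_permutations):
            for i in range(m - 1, 0, -1):
                r = rng.integers(0, i + 1)
                tmp = Xo[i, j]
                Xo[i, j] = Xo[r, j]
                Xo[r, j] = tmp
            inc += _tree_loss(feature, threshold, left, right, value,
                              Xo, yo, task) - base
        for i in range(m):
            Xo[i, j] = col[i]
        scores[j] = inc / n_permutations
    return scores
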