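"""Exact partial-dependence evaluation for tree ensembles.

Brute-force partial dependence substitutes each grid value into every data row
and averages the forest's predictions: PD(v) = mean_i f(x_i with x_s := v).
Evaluating that naively costs n_rows * n_grid full forest passes, which is
prohibitive when scanning all 190 AU pairs of a 500-tree forest.

The kernels here compute the *same sum* in one traversal per (tree, row): a
decision path is deterministic in all features except the target one(s); at a
split on the target feature the sorted grid interval is partitioned between
the two children, and each leaf reached contributes its value to a contiguous
block of grid cells (accumulated via difference arrays).  The result is
mathematically identical to brute-force substitution, up to floating-point
summation order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pack_forest", "pd_grid_1d", "pd_grid_2d"]


def pack_forest(forest) -> tuple[np.ndarray, ...]:
    """Flatten a fitted sklearn forest into contiguous node arrays.

    Returns (feature, threshold, left, right, value, roots); child indices are
    globalised, leaves keep child index -1.
    """
    feats, thrs, lefts, rights, vals, roots = [], [], [], [], [], []
    offset = 0
    for est in forest.estimators_:
        t = est.tree_
        roots.append(offset)
        feats.append(t.feature.astype(np.int64))
        thrs.append(t.threshold.astype(np.float64))
        lefts.append(np.where(t.children_left < 0, -1, t.children_left + offset))
        rights.append(np.where(t.children_right < 0, -1, t.children_right + offset))
        vals.append(t.value[:, 0, 0].astype(np.float64))
        offset += t.node_count
    return (np.concatenate(feats), np.concatenate(thrs),
            np.concatenate(lefts).astype(np.int64),
            np.concatenate(rights).astype(np.int64),
            np.concatenate(vals), np.asarray(roots, np.int64))


@njit(cache=True)
def _bisect_right(grid, x):
    a, b = 0, grid.shape[0]
    while a < b:
        mid = (a + b) // 2
        if grid[mid] <= x:
            a = mid + 1
        else:
            b = mid
    return a


@njit(cache=True)
def pd_grid_1d(feature, threshold, left, right, value, roots, X, col, grid):
    """Mean prediction over rows of X with X[:, col] forced to each grid value."""
    G = grid.shape[0]
    acc = np.zeros(G + 1)
    cap = 4096
    st_node = np.empty(cap, np.int64)
    st_lo = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    for t in range(roots.shape[0]):
        root = roots[t]
        for i in range(X.shape[0]):
            sp = 0
            st_node[0] = root
            st_lo[0] = 0
            st_hi[0] = G
            sp = 1
            while sp > 0:
                sp -= 1
                node = st_node[sp]
                lo = st_lo[sp]
                hi = st_hi[sp]
                while left[node] != -1:
                    f = feature[node]
                    if f == col:
                        s = _bisect_right(grid, threshold[node])
                        if s <= lo:
                            node = right[node]
                        elif s >= hi:
                            node = left[node]
                        else:
                            st_node[sp] = right[node]
                            st_lo[sp] = s
                            st_hi[sp] = hi
                            sp += 1
                            node = left[node]
                            hi = s
                    else:
                        if X[i, f] <= threshold[node]:
                            node = left[node]
                        else:
                            node = right[node]
                acc[lo] += value[node]
                acc[hi] -= value[node]
    out = np.empty(G)
    run = 0.0
    for g in range(G):
        run += acc[g]
        out[g] = run
    return out / (roots.shape[0] * X.shape[0])


@njit(cache=True)
def pd_grid_2d(feature, threshold, left, right, value, roots, X,
               col_i, col_j, grid_i, grid_j):
    """2-D partial-dependence surface over the product grid, exact."""
    Gi = grid_i.shape[0]
    Gj = grid_j.shape[0]
    acc = np.zeros((Gi + 1, Gj + 1))
    cap = 4096
    st_node = np.empty(cap, np.int64)
    st_li = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    st_lj = np.empty(cap, np.int64)
    st_hj = np.empty(cap, np.int64)
    for t in range(roots.shape[0]):
        root = roots[t]
        for r in range(X.shape[0]):
            st_node[0] = root
            st_li[0] = 0
            st_hi[0] = Gi
            st_lj[0] = 0
            st_hj[0] = Gj
            sp = 1
            while sp > 0:
                sp -= 1
                node = st_node[sp]
                li = st_li[sp]
                hi = st_hi[sp]
                lj = st_lj[sp]
                hj = st_hj[sp]
                while left[node] != -1:
                    f = feature[node]
                    if f == col_i:
                        s = _bisect_right(grid_i, threshold[node])
                        if s <= li:
                            node = right[node]
                        elif s >= hi:
                            node = left[node]
                        else:
                            st_node[sp] = right[node]
                            st_li[sp] = s
                            st_hi[sp] = hi
                            st_lj[sp] = lj
                            st_hj[sp] = hj
                            sp += 1
                            node = left[node]
                            hi = s
                    elif f == col_j:
                        s = _bisect_right(grid_j, threshold[node])
                        if s <= lj:
                            node = right[node]
                        elif s >= hj:
                            node = left[node]
                        else:
                            st_node[sp] = right[node]
                            st_li[sp] = li
                            st_hi[sp] = hi
                            st_lj[sp] = s
                            st_hj[sp] = hj
                            sp += 1
                            node = left[node]
                            hj = s
                    else:
                        if X[r, f] <= threshold[node]:
                            node = left[node]
                        else:
                            node = right[node]
                v = value[node]
                acc[li, lj] += v
                acc[li, hj] -= v
                acc[hi, lj] -= v
                acc[hi, hj] += v
    out = np.empty((Gi, Gj))
    for a in range(Gi):
        run = 0.0
        for b in range(Gj):
            run += acc[a, b]
            out[a, b] = run if a == 0 else run + out[a - 1, b]
    return out / (roots.shape[0] * X.shape[0])
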