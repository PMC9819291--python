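"""Numba kernels for the conditional-inference random forest.

Everything latency-critical lives here as nopython kernels operating on
flat arrays: mid-rank computation, the per-node association tests, tree
construction, prediction, bootstrap forest fitting and out-of-bag
permutation importance.  The Python-facing classes in
:mod:`facit_mcid.rf_screening` wrap these.

Trees are stored structure-of-arrays: ``feat[node]`` is the split
predictor (-1 for a leaf), ``thr[node]`` the split threshold (go left
when ``x <= thr``), ``left``/``right`` the child ids and ``value`` the
node mean of the response.

Determinism: every kernel that draws randomness seeds numba's own
per-thread legacy RNG from an explicit integer argument, and per-tree
seeds are derived arithmetically from the forest seed, so results are
identical regardless of threading or call order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SEED_MOD = 2147483647  # 2**31 - 1


@njit(cache=True)
def _midranks(x):
    """Mid-ranks (ties averaged), 1-based."""
    n = x.shape[0]
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, np.float64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


@njit(cache=True)
def _norm_sf(z):
    return 0.5 * math.erfc(z / math.sqrt(2.0))


@njit(cache=True)
def _build_tree(X, y, idx, mtry, alpha, min_node,
                feat, thr, left, right, value):
    """Grow one conditional-inference tree on the rows listed in ``idx``.

    At each node, ``mtry`` candidate predictors are sampled without
    replacement; for each, a rank-correlation association test between the
    predictor and the response (normal approximation of the linear rank
    statistic; for a binary response this reduces to the tie-corrected
    rank-sum test) yields a p-value, Bonferroni-adjusted over the
    candidates.  The node becomes a leaf when the best adjusted p exceeds
    ``alpha`` or the node is smaller than ``2 * min_node``; otherwise it
    splits on the most significant predictor at the cut maximizing the
    standardized two-sample rank statistic, ties broken toward the
    balanced split, threshold at the midpoint of the adjacent values.

    ``idx`` is partitioned in place; returns the number of nodes.
    """
    p = X.shape[1]
    cap = feat.shape[0]
    st_lo = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    st_parent = np.empty(cap, np.int64)
    st_isleft = np.empty(cap, np.uint8)
    st_lo[0] = 0
    st_hi[0] = idx.shape[0]
    st_parent[0] = -1
    st_isleft[0] = 0
    top = 1
    n_nodes = 0
    perm = np.empty(p, np.int64)
    while top > 0:
        top -= 1
        lo = st_lo[top]
        hi = st_hi[top]
        parent = st_parent[top]
        node = n_nodes
        n_nodes += 1
        if parent >= 0:
            if st_isleft[top] == 1:
                left[parent] = node
            else:
                right[parent] = node
        m = hi - lo
        s = 0.0
        for k in range(lo, hi):
            s += y[idx[k]]
        feat[node] = -1
        value[node] = s / m
        if m < 2 * min_node:
            continue
        ynode = np.empty(m, np.float64)
        for k in range(m):
            ynode[k] = y[idx[lo + k]]
        ry = _midranks(ynode)
        rbar = 0.5 * (m + 1.0)
        vy = 0.0
        for k in range(m):
            d = ry[k] - rbar
            vy += d * d
        vy /= m                       # population variance of the y mid-ranks
        if vy <= 0.0:
            continue                  # constant response in this node
        for k in range(p):
            perm[k] = k
        kmax = mtry if mtry < p else p
        for k in range(kmax):
            j = k + np.random.randint(0, p - k)
            t = perm[k]
            perm[k] = perm[j]
            perm[j] = t
        best_p = 2.0
        best_f = -1
        xbuf = np.empty(m, np.float64)
        for c in range(kmax):
            f = perm[c]
            for k in range(m):
                xbuf[k] = X[idx[lo + k], f]
            rx = _midranks(xbuf)
            vx = 0.0
            cov = 0.0
            for k in range(m):
                dx = rx[k] - rbar
                vx += dx * dx
                cov += dx * (ry[k] - rbar)
            if vx <= 0.0:
                continue
            r = cov / math.sqrt(vx * (vy * m))
            z = abs(r) * math.sqrt(m - 1.0)
            pval = 2.0 * _norm_sf(z)
            if pval < best_p:
                best_p = pval
                best_f = f
        if best_f < 0:
            continue
        p_adj = best_p * kmax
        if p_adj > alpha:
            continue
        for k in range(m):
            xbuf[k] = X[idx[lo + k], best_f]
        order = np.argsort(xbuf, kind="mergesort")
        best_t = -1.0
        best_k = -1
        best_bal = np.int64(1 << 60)
        best_thr = 0.0
        s_left = 0.0
        for k in range(1, m):
            s_left += ry[order[k - 1]]
            if k < min_node or m - k < min_node:
                continue
            if xbuf[order[k]] == xbuf[order[k - 1]]:
                continue
            e = k * rbar
            # variance of a without-replacement sum of k mid-ranks
            v = k * (m - k) / (m - 1.0) * vy
            t_stat = abs(s_left - e) / math.sqrt(v)
            bal = abs(2 * k - m)
            if t_stat > best_t + 1e-12 or (t_stat > best_t - 1e-12 and bal < best_bal):
                best_t = t_stat
                best_k = k
                best_bal = bal
                best_thr = 0.5 * (xbuf[order[k - 1]] + xbuf[order[k]])
        if best_k < 0:
            continue
        feat[node] = best_f
        thr[node] = best_thr
        tmp = np.empty(m, np.int64)
        for k in range(m):
            tmp[k] = idx[lo + order[k]]
        for k in range(m):
            idx[lo + k] = tmp[k]
        st_lo[top] = lo + best_k
        st_hi[top] = hi
        st_parent[top] = node
        st_isleft[top] = 0
        top += 1
        st_lo[top] = lo
        st_hi[top] = lo + best_k
        st_parent[top] = node
        st_isleft[top] = 1
        top += 1
    return n_nodes


@njit(cache=True)
def _predict_rows(feat, thr, left, right, value, X, rows, out):
    for i in range(rows.shape[0]):
        node = 0
        r = rows[i]
        while feat[node] >= 0:
            if X[r, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]


@njit(cache=True)
def _fit_single_tree(X, y, mtry, alpha, min_node, seed,
                     feat, thr, left, right, value):
    np.random.seed(seed % _SEED_MOD)
    idx = np.arange(X.shape[0])
    return _build_tree(X, y, idx, mtry, alpha, min_node,
                       feat, thr, left, right, value)


@njit(cache=True)
def _fit_forest(X, y, n_trees, mtry, alpha, min_node, seed, max_nodes):
    n = X.shape[0]
    feats = np.full((n_trees, max_nodes), -1, np.int64)
    thrs = np.zeros((n_trees, max_nodes), np.float64)
    lefts = np.full((n_trees, max_nodes), -1, np.int64)
    rights = np.full((n_trees, max_nodes), -1, np.int64)
    values = np.zeros((n_trees, max_nodes), np.float64)
    n_nodes = np.zeros(n_trees, np.int64)
    inbag = np.zeros((n_trees, n), np.uint8)
    for t in range(n_trees):
        np.random.seed((seed + 1000003 * t) % _SEED_MOD)
        idx = np.random.randint(0, n, n)
        for k in range(n):
            inbag[t, idx[k]] = 1
        n_nodes[t] = _build_tree(X, y, idx, mtry, alpha, min_node,
                                 feats[t], thrs[t], lefts[t], rights[t],
                                 values[t])
    return feats, thrs, lefts, rights, values, n_nodes, inbag


@njit(cache=True)
def _loss(pred, y, rows, n_used, binary):
    acc = 0.0
    if binary == 1:
        for k in range(n_used):
            cls = 1.0 if pred[k] >= 0.5 else 0.0
            if cls != y[rows[k]]:
                acc += 1.0
    else:
        for k in range(n_used):
            d = pred[k] - y[rows[k]]
            acc += d * d
    return acc / n_used


@njit(cache=True)
def _permutation_importance(feats, thrs, lefts, rights, values, n_nodes,
                            inbag, X, y, seed, binary):
    """Mean over trees of (permuted OOB loss - baseline OOB loss) per
    predictor.  Predictors unused by a tree contribute exactly zero for
    that tree, so only the used ones are permuted."""
    n_trees = feats.shape[0]
    n = X.shape[0]
    p = X.shape[1]
    imp = np.zeros(p, np.float64)
    np.random.seed(seed % _SEED_MOD)
    oob = np.empty(n, np.int64)
    pred = np.empty(n, np.float64)
    used = np.zeros(p, np.uint8)
    for t in range(n_trees):
        n_oob = 0
        for r in range(n):
            if inbag[t, r] == 0:
                oob[n_oob] = r
                n_oob += 1
        if n_oob == 0:
            continue
        rows = oob[:n_oob]
        _predict_rows(feats[t], thrs[t], lefts[t], rights[t], values[t],
                      X, rows, pred)
        base = _loss(pred, y, rows, n_oob, binary)
        for j in range(p):
            used[j] = 0
        for nd in range(n_nodes[t]):
            f = feats[t, nd]
            if f >= 0:
                used[f] = 1
        for f in range(p):
            if used[f] == 0:
                continue
            col = np.empty(n_oob, np.float64)
            for k in range(n_oob):
                col[k] = X[rows[k], f]
            permcol = col.copy()
            for k in range(n_oob - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tv = permcol[k]
                permcol[k] = permcol[j]
                permcol[j] = tv
            for k in range(n_oob):
                X[rows[k], f] = permcol[k]
            _predict_rows(feats[t], thrs[t], lefts[t], rights[t], values[t],
                          X, rows, pred)
            lp = _loss(pred, y, rows, n_oob, binary)
            for k in range(n_oob):
                X[rows[k], f] = col[k]
            imp[f] += lp - base
    return imp / n_trees
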