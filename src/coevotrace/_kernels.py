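"""Compiled inner loop for the all-ordered-pairs epistatic statistic.

The numba kernel mirrors `epistat.ordered_statistics` (kept as the
reference implementation and test oracle): one depth-first walk with
per-site "most recent event on the current root path" state, undone on
backtrack.  The walk is precomputed as a token stream (positive = enter
node, negative = leave node).
"""

from __future__ import annotations

import numpy as np
from numba import njit


def dfs_walk(tree) -> np.ndarray:
    """Enter/leave token stream over non-root nodes: +v enter, -(v+1) leave."""
    walk = []
    stack = [(c, False) for c in reversed(tree.children[tree.root])]
    while stack:
        v, done = stack.pop()
        if done:
            walk.append(-(v + 1))
            continue
        walk.append(v)
        stack.append((v, True))
        stack.extend((c, False) for c in reversed(tree.children[v]))
    return np.asarray(walk, dtype=np.int64)


@njit(cache=True)
def _kernel(walk, level, mdepth, ev_ptr, ev_site, ev_w, S, tau, same_branch, stat):
    last_order = np.full(S, -1.0)
    last_depth = np.zeros(S)
    last_weight = np.zeros(S)
    # undo storage: worst case one record per event occurrence in the walk
    cap = len(ev_site) + 1
    u_site = np.empty(cap, dtype=np.int64)
    u_order = np.empty(cap)
    u_depth = np.empty(cap)
    u_w = np.empty(cap)
    u_top = 0
    # per-node undo counts
    marks = np.empty(len(walk), dtype=np.int64)
    m_top = 0
    on_b = np.zeros(S, dtype=np.uint8)
    for token in walk:
        if token >= 0:
            v = token
            lo = ev_ptr[v]
            hi = ev_ptr[v + 1]
            n_ev = hi - lo
            if n_ev > 1 or (n_ev == 1 and same_branch):
                for e in range(lo, hi):
                    on_b[ev_site[e]] = 1
            md = mdepth[v]
            for e in range(lo, hi):
                j = ev_site[e]
                wj = ev_w[e]
                oj = last_order[j]
                for i in range(S):
                    if i == j:
                        continue
                    if same_branch and n_ev > 1 and on_b[i] == 1:
                        continue
                    li = last_order[i]
                    if li < 0.0 or li < oj:
                        continue
                    dt = md - last_depth[i]
                    stat[i, j] += wj * last_weight[i] * np.exp(-dt / tau[j])
            if same_branch and n_ev > 1:
                for a in range(lo, hi):
                    for b in range(a + 1, hi):
                        ki = ev_site[a]
                        kj = ev_site[b]
                        w = ev_w[a] * ev_w[b]
                        stat[ki, kj] += w
                        stat[kj, ki] += w
            lv = float(level[v])
            for e in range(lo, hi):
                k = ev_site[e]
                u_site[u_top] = k
                u_order[u_top] = last_order[k]
                u_depth[u_top] = last_depth[k]
                u_w[u_top] = last_weight[k]
                u_top += 1
                last_order[k] = lv
                last_depth[k] = md
                last_weight[k] = ev_w[e]
                on_b[k] = 0
            marks[m_top] = n_ev
            m_top += 1
        else:
            m_top -= 1
            n_ev = marks[m_top]
            for _ in range(n_ev):
                u_top -= 1
                k = u_site[u_top]
                last_order[k] = u_order[u_top]
                last_depth[k] = u_depth[u_top]
                last_weight[k] = u_w[u_top]


def ordered_statistics_fast(
    tree,
    branches_by_site,
    weights_by_site,
    tau,
    same_branch_pairs=True,
    walk=None,
):
    """Numba-backed version of `epistat.ordered_statistics`."""
    S = len(branches_by_site)
    n = tree.n_nodes
    if walk is None:
        walk = dfs_walk(tree)
    sites = np.concatenate(
        [np.full(len(b), k, dtype=np.int64) for k, b in enumerate(branches_by_site)]
    ) if S else np.empty(0, dtype=np.int64)
    branches = np.concatenate(
        [np.asarray(b, dtype=np.int64) for b in branches_by_site]
    ) if S else np.empty(0, dtype=np.int64)
    weights = np.concatenate(
        [np.asarray(w, dtype=float) for w in weights_by_site]
    ) if S else np.empty(0)
    order = np.argsort(branches, kind="stable")
    branches = branches[order]
    ev_site = sites[order]
    ev_w = weights[order]
    ev_ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(ev_ptr[1:], branches, 1)
    ev_ptr = np.cumsum(ev_ptr)
    stat = np.zeros((S, S))
    _kernel(
        walk,
        tree.level.astype(np.int64),
        tree.midpoint_depth,
        ev_ptr,
        ev_site,
        ev_w,
        S,
        np.asarray(tau, dtype=float),
        same_branch_pairs,
        stat,
    )
    return stat
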