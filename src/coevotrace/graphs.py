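"""Signed coevolution graphs and coevolving-group detection.

Sites are nodes; a positive edge (weighted by the association statistic)
records a significant excess of rapid consecutive substitutions, a
negative edge (weighted by the pseudo-correlation) a significant deficit.
Groups of coevolving sites are communities that maximize signed
modularity, Q = Q_pos - Q_neg: the modularity of the positive-weight
subgraph minus the modularity of the negative-weight subgraph, each with
its own configuration-model null strength.  Dense positive edges inside a
group and negative edges between groups both raise the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    pass


def build_coevolution_graph(
    pair_stats: pd.DataFrame,
    thresholds: dict,
    p_cap: float = 0.05,
) -> nx.Graph:
    """Assemble the signed coevolution graph from per-pair statistics.

    ``pair_stats`` needs columns site_i, site_j, rho, a, p_upper, p_lower.
    ``thresholds`` maps "concordant"/"discordant" to the nominal p-value
    thresholds for FDR < target (None when no threshold exists).  An edge
    is included only when its p-value is below the minimum of ``p_cap``
    and the direction's threshold.  All sites remain as nodes even when
    isolated.
    """
    g = nx.Graph()
    sites = sorted(set(pair_stats["site_i"]) | set(pair_stats["site_j"]))
    g.add_nodes_from(sites)

    if (pair_stats["a"] > 0).any() and "concordant" not in thresholds:
        raise ConfigurationError("missing concordant threshold with candidate positive edges")
    if (pair_stats["a"] < 0).any() and "discordant" not in thresholds:
        raise ConfigurationError("missing discordant threshold with candidate negative edges")
    up = thresholds.get("concordant")
    lo = thresholds.get("discordant")
    # permutation p-values are discrete and the FDR threshold is itself an
    # observed p, so pairs at the threshold are the findings that defined it
    pos_cut = -1.0 if up is None else min(p_cap, up)
    neg_cut = -1.0 if lo is None else min(p_cap, lo)
    has_pos = (pair_stats["a"] > 0) & (pair_stats["p_upper"] <= pos_cut)
    has_neg = (pair_stats["a"] < 0) & (pair_stats["p_lower"] <= neg_cut)

    for row, is_pos, is_neg in zip(pair_stats.itertuples(index=False), has_pos, has_neg):
        if is_pos:
            g.add_edge(row.site_i, row.site_j, weight=float(row.a), sign=1, p=float(row.p_upper))
        elif is_neg:
            g.add_edge(row.site_i, row.site_j, weight=float(row.a), sign=-1, p=float(row.p_lower))
    return g


# ---------------------------------------------------------------------------
# signed modularity


def signed_modularity(graph: nx.Graph, partition: dict, balance: float = 1.0) -> float:
    """Q_pos - balance * Q_neg for a node -> group assignment."""
    q_pos = _modularity_one_sign(graph, partition, +1)
    q_neg = _modularity_one_sign(graph, partition, -1)
    return q_pos - balance * q_neg


def _modularity_one_sign(graph, partition, sign):
    m2 = 0.0
    strength = {v: 0.0 for v in graph.nodes}
    inner = {}
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        w = max(w, 0.0) if sign > 0 else max(-w, 0.0)
        if w == 0:
            continue
        m2 += 2 * w
        strength[u] += w
        strength[v] += w
        if partition[u] == partition[v]:
            inner[partition[u]] = inner.get(partition[u], 0.0) + 2 * w
    if m2 == 0:
        return 0.0
    comm_strength = {}
    for v, s in strength.items():
        comm_strength[partition[v]] = comm_strength.get(partition[v], 0.0) + s
    q = 0.0
    for c, s in comm_strength.items():
        q += inner.get(c, 0.0) / m2 - (s / m2) ** 2
    return q


@dataclass
class GroupPartition:
    """Division of the coevolution graph into coevolving groups."""

    assignment: dict                 # site -> group id (0-based, by size)
    modularity: float
    group_sizes: dict
    pos_density_within: float        # weight fraction of positive edges inside groups
    neg_density_within: float

    @property
    def groups(self) -> dict:
        out = {}
        for site, gid in self.assignment.items():
            out.setdefault(gid, []).append(site)
        return {g: sorted(v) for g, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["site", "group"]
        )


class _SignedLouvain:
    """Greedy Louvain moves on the signed objective, deterministic."""

    def __init__(self, graph: nx.Graph, balance: float = 1.0):
        self.nodes = sorted(graph.nodes)
        self.idx = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        self.adj_pos = [dict() for _ in range(n)]
        self.adj_neg = [dict() for _ in range(n)]
        for u, v, d in graph.edges(data=True):
            w = d.get("weight", 1.0)
            iu, iv = self.idx[u], self.idx[v]
            if iu == iv:
                continue
            if w > 0:
                self.adj_pos[iu][iv] = self.adj_pos[iu].get(iv, 0.0) + w
                self.adj_pos[iv][iu] = self.adj_pos[iv].get(iu, 0.0) + w
            elif w < 0:
                self.adj_neg[iu][iv] = self.adj_neg[iu].get(iv, 0.0) - w
                self.adj_neg[iv][iu] = self.adj_neg[iv].get(iu, 0.0) - w
        self.balance = balance

    def run(self, rng: np.random.Generator):
        n = len(self.nodes)
        comm = list(range(n))
        node_sets = [[i] for i in range(n)]          # flat membership per super-node
        adj_pos, adj_neg = self.adj_pos, self.adj_neg
        while True:
            comm, improved = self._local_move(adj_pos, adj_neg, rng)
            if not improved:
                break
            adj_pos, adj_neg, node_sets = self._aggregate(adj_pos, adj_neg, comm, node_sets)
        labels = {}
        for c, members in enumerate(node_sets):
            for i in members:
                labels[self.nodes[i]] = c
        return labels

    def _strengths(self, adj):
        k = np.array([sum(nb.values()) for nb in adj])
        m2 = k.sum()
        return k, m2

    def _local_move(self, adj_pos, adj_neg, rng):
        n = len(adj_pos)
        comm = list(range(n))
        k_pos, m2_pos = self._strengths(adj_pos)
        k_neg, m2_neg = self._strengths(adj_neg)
        tot_pos = k_pos.astype(float).copy()
        tot_neg = k_neg.astype(float).copy()
        order = list(rng.permutation(n))
        improved_any = False
        for _ in range(50):  # passes over nodes until stable
            moved = False
            for i in order:
                ci = comm[i]
                # weights to neighboring communities
                w_pos, w_neg = {}, {}
                for j, w in adj_pos[i].items():
                    w_pos[comm[j]] = w_pos.get(comm[j], 0.0) + w
                for j, w in adj_neg[i].items():
                    w_neg[comm[j]] = w_neg.get(comm[j], 0.0) + w
                tot_pos[ci] -= k_pos[i]
                tot_neg[ci] -= k_neg[i]
                candidates = set(w_pos) | set(w_neg) | {ci}
                best_c, best_gain = ci, 0.0

                def gain(c):
                    g = 0.0
                    if m2_pos > 0:
                        g += (w_pos.get(c, 0.0) - tot_pos[c] * k_pos[i] / m2_pos) / m2_pos * 2
                    if m2_neg > 0:
                        g -= self.balance * (
                            w_neg.get(c, 0.0) - tot_neg[c] * k_neg[i] / m2_neg
                        ) / m2_neg * 2
                    return g

                base = gain(ci)
                for c in sorted(candidates):
                    g = gain(c) - base
                    if g > best_gain + 1e-12 or (
                        abs(g - best_gain) <= 1e-12 and best_gain > 0 and c < best_c
                    ):
                        best_gain, best_c = g, c
                comm[i] = best_c
                tot_pos[best_c] += k_pos[i]
                tot_neg[best_c] += k_neg[i]
                if best_c != ci:
                    moved = True
                    improved_any = True
            if not moved:
                break
        return comm, improved_any

    def _aggregate(self, adj_pos, adj_neg, comm, node_sets):
        labels = sorted(set(comm))
        remap = {c: i for i, c in enumerate(labels)}
        new_sets = [[] for _ in labels]
        for i, c in enumerate(comm):
            new_sets[remap[c]].extend(node_sets[i])
        def agg(adj):
            out = [dict() for _ in labels]
            for i, nbrs in enumerate(adj):
                ci = remap[comm[i]]
                for j, w in nbrs.items():
                    cj = remap[comm[j]]
                    if ci == cj:
                        continue
                    out[ci][cj] = out[ci].get(cj, 0.0) + w
            return out
        return agg(adj_pos), agg(adj_neg), new_sets


def detect_groups(
    graph: nx.Graph, seed: int = 0, n_restarts: int = 10, balance: float = 1.0
) -> GroupPartition:
    """Partition the signed graph into coevolving groups.

    Louvain-style greedy optimization of Q_pos - Q_neg, best of
    ``n_restarts`` seeded node orders; deterministic for a fixed seed.
    Isolated sites become singleton groups; group ids are assigned by
    decreasing size.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weights = [abs(d.get("weight", 1.0)) for _, _, d in graph.edges(data=True)]
    if not weights:
        # edgeless graph: every site its own group
        assignment = {v: i for i, v in enumerate(sorted(graph.nodes))}
        return _finish(graph, assignment, balance)
    if max(weights) == 0:
        # edges exist but carry no signed weight: nothing to optimize
        assignment = {v: 0 for v in graph.nodes}
        return _finish(graph, assignment, balance)

    engine = _SignedLouvain(graph, balance=balance)
    best_labels, best_q = None, -np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        labels = engine.run(rng)
        q = signed_modularity(graph, labels, balance)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return _finish(graph, best_labels, balance)


def _finish(graph, assignment, balance):
    # relabel groups by decreasing size, ties by smallest member
    groups = {}
    for v, c in assignment.items():
        groups.setdefault(c, []).append(v)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))
    final = {}
    for gid, members in enumerate(ordered):
        for v in members:
            final[v] = gid
    w_pos_in = w_pos_tot = w_neg_in = w_neg_tot = 0.0
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        if w > 0:
            w_pos_tot += w
            if final[u] == final[v]:
                w_pos_in += w
        elif w < 0:
            w_neg_tot += -w
            if final[u] == final[v]:
                w_neg_in += -w
    return GroupPartition(
        assignment=final,
        modularity=signed_modularity(graph, final, balance),
        group_sizes={gid: len(m) for gid, m in enumerate(ordered)},
        pos_density_within=w_pos_in / w_pos_tot if w_pos_tot else float("nan"),
        neg_density_within=w_neg_in / w_neg_tot if w_neg_tot else float("nan"),
    )
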