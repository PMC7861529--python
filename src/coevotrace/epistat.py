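"""Epistatic statistic, margin-preserving permutation null, and FDR.

For an ordered site pair (i -> j) the epistatic statistic is the weighted
number of consecutive substitution pairs, each penalized exponentially for
the waiting time t between the two events::

    stat(i -> j) = sum over consecutive pairs of  w_lead * w_trail * exp(-t / tau_j)

The null keeps the number of substitutions at every site and on every
branch exactly fixed while shuffling which branch carries which site's
events (degree-preserving rewiring of the bipartite site-branch incidence
graph, implemented with curveball trades).  Upper-tail excess over this
null is concordant evolution; lower-tail deficit is discordant evolution.

False discovery rates follow the randomized-replicate procedure: a batch
of rewired histories is treated as pseudo-data, scored with the same
p-values as the data, and FDR(p) is the ratio of the mean number of
pseudo-data findings at nominal level p to the number of data findings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import (
    Phylogeny,
    SubstitutionEvent,
    SubstitutionHistory,
    poorly_resolved_components,
)


@dataclass
class EpistatConfig:
    """Knobs of the pair analysis.

    tau: waiting-time penalty scale in branch-length units; None means the
        per-trailing-site default (total tree length / number of events at
        the trailing site, i.e. that site's expected waiting time).
    n_null: rewired replicates for the null distribution.
    n_fdr_sets: rewired replicates scored as pseudo-data for FDR curves.
    fdr_target: target false discovery rate for the reported threshold.
    p_cap: hard nominal cap applied when thresholds feed graph edges.
    support_threshold: when set, hemiplasy weights (1/n within poorly
        resolved subtrees) are recomputed for every rewired replicate.
    """

    tau: float | None = None
    n_null: int = 10000
    n_fdr_sets: int = 400
    fdr_target: float = 0.3
    p_cap: float = 0.05
    seed: int = 0
    support_threshold: float | None = None
    trades_factor: int = 5

    def __post_init__(self):
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_null < 100:
            raise ValueError("n_null must be at least 100")


def epistatic_statistic(pairs: list, tau: float) -> float:
    """Closed-form statistic for an explicit list of consecutive pairs."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(sum(p.weight * np.exp(-p.waiting_time / tau) for p in pairs))


def default_tau(tree: Phylogeny, n_events: np.ndarray) -> np.ndarray:
    """Per-site penalty scale: tree length over the site's event count."""
    return tree.total_length / np.maximum(n_events, 1)


# ---------------------------------------------------------------------------
# all-ordered-pairs statistic in one tree traversal

def ordered_statistics(
    tree: Phylogeny,
    branches_by_site: list,
    weights_by_site: list,
    tau: np.ndarray,
    same_branch_pairs: bool = True,
) -> np.ndarray:
    """Epistatic statistic for every ordered site pair.

    ``branches_by_site[k]`` holds the branch indices carrying events of
    site k, ``weights_by_site[k]`` the matching hemiplasy weights, and
    ``tau[k]`` the penalty scale used when site k is the trailing site.
    Returns an (S, S) matrix ``stat[i, j]`` for ordered pair i -> j.

    One depth-first pass suffices: along the current root path we track,
    per site, the most recent event; a trailing event pairs with the most
    recent event of the leading site provided no event of its own site
    intervened — which reduces to comparing path positions of the two most
    recent events.
    """
    S = len(branches_by_site)
    stat = np.zeros((S, S))
    events_on = [[] for _ in range(tree.n_nodes)]
    for k, (brs, ws) in enumerate(zip(branches_by_site, weights_by_site)):
        for b, w in zip(brs, ws):
            events_on[int(b)].append((k, float(w)))

    md = tree.midpoint_depth
    level = tree.level
    last_order = np.full(S, -1.0)
    last_depth = np.zeros(S)
    last_weight = np.zeros(S)

    # iterative DFS with undo records so arrays reflect the current path
    root = tree.root
    stack = [(c, False) for c in reversed(tree.children[root])]
    undo: list = []
    while stack:
        v, done = stack.pop()
        if done:
            for k, o, d, w in undo.pop():
                last_order[k], last_depth[k], last_weight[k] = o, d, w
            continue
        evs = events_on[v]
        on_b = [k for k, _ in evs]
        for j, wj in evs:
            mask = (last_order >= 0) & (last_order >= last_order[j])
            mask[j] = False
            if same_branch_pairs and len(on_b) > 1:
                mask[on_b] = False
            if mask.any():
                dt = md[v] - last_depth[mask]
                stat[mask, j] += wj * last_weight[mask] * np.exp(-dt / tau[j])
        if same_branch_pairs and len(evs) > 1:
            for a in range(len(evs)):
                for b in range(a + 1, len(evs)):
                    ki, wi = evs[a]
                    kj, wj = evs[b]
                    stat[ki, kj] += wi * wj
                    stat[kj, ki] += wi * wj
        rec = []
        for k, w in evs:
            rec.append((k, last_order[k], last_depth[k], last_weight[k]))
            last_order[k] = level[v]
            last_depth[k] = md[v]
            last_weight[k] = w
        undo.append(rec)
        stack.append((v, True))
        stack.extend((c, False) for c in reversed(tree.children[v]))
    return stat


# ---------------------------------------------------------------------------
# margin-preserving rewiring (curveball trades)

def curveball_trades(rows: list, n_trades: int, rng: np.random.Generator) -> list:
    """Degree-preserving randomization of a binary bipartite incidence.

    ``rows[k]`` is a sorted int array of the branches incident to site k.
    Each trade picks two sites and randomly redistributes the branches
    that belong to exactly one of them; row and column sums are invariant.
    """
    rows = [np.asarray(r, dtype=np.int64) for r in rows]
    S = len(rows)
    if S < 2:
        return rows
    pick = rng.integers(0, S, size=(n_trades, 2))
    for r1, r2 in pick:
        if r1 == r2:
            continue
        a, b = rows[r1], rows[r2]
        shared = np.intersect1d(a, b, assume_unique=True)
        only_a = np.setdiff1d(a, shared, assume_unique=True)
        only_b = np.setdiff1d(b, shared, assume_unique=True)
        if len(only_a) == 0 or len(only_b) == 0:
            continue
        pool = rng.permutation(np.concatenate([only_a, only_b]))
        rows[r1] = np.sort(np.concatenate([shared, pool[: len(only_a)]]))
        rows[r2] = np.sort(np.concatenate([shared, pool[len(only_a):]]))
    return rows


class NullSampler:
    """Stream of margin-preserving rewired event placements.

    Yields, per replicate, (branches_by_site, weights_by_site) with the
    observed per-site and per-branch event counts preserved exactly.
    When a support threshold is given, hemiplasy weights are recomputed
    for each rewired placement with the same 1/n rule applied to the
    data — every replicate is processed by the identical pipeline.
    """

    def __init__(
        self,
        history: SubstitutionHistory,
        sites: list,
        seed: int = 0,
        trades_factor: int = 5,
        support_threshold: float | None = None,
    ):
        self.tree = history.tree
        self.sites = list(sites)
        self.rng = np.random.default_rng(seed)
        self.rows = [
            np.asarray(sorted(ev.branch for ev in history.events_at(s)), dtype=np.int64)
            for s in self.sites
        ]
        self.trades = max(1, trades_factor * len(self.rows))
        self._comp = (
            poorly_resolved_components(self.tree, support_threshold)
            if support_threshold is not None
            else None
        )
        # burn-in before the first retained sample
        self.rows = curveball_trades(self.rows, 4 * self.trades, self.rng)

    def weights_for(self, rows: list) -> list:
        if self._comp is None:
            return [np.ones(len(r)) for r in rows]
        out = []
        for r in rows:
            comps = self._comp[r]
            _, inv, counts = np.unique(comps, return_inverse=True, return_counts=True)
            out.append(1.0 / counts[inv])
        return out

    def __iter__(self):
        return self

    def __next__(self):
        self.rows = curveball_trades(self.rows, self.trades, self.rng)
        rows = [r.copy() for r in self.rows]
        return rows, self.weights_for(rows)


def rewire_null(history: SubstitutionHistory, n_samples: int, seed: int = 0) -> list:
    """Materialize ``n_samples`` rewired histories (margin-preserving).

    Amino-acid identities are not meaningful under the null and are filled
    with placeholders; identity-dependent statistics are simply not
    evaluated on rewired histories.
    """
    sites = history.analyzed_sites
    sampler = NullSampler(history, sites, seed=seed)
    out = []
    for _ in range(n_samples):
        rows, weights = next(sampler)
        events = [
            SubstitutionEvent(branch=int(b), site=s, ancestral="A", derived="X", weight=float(w))
            for s, brs, ws in zip(sites, rows, weights)
            for b, w in zip(brs, ws)
        ]
        out.append(history.with_events(events))
    return out


# ---------------------------------------------------------------------------
# p-values and FDR

def pair_pvalues(observed: float, null: np.ndarray):
    """Permutation p-values and z-score of one observed statistic.

    Uses the add-one pseudocount (r + 1) / (n + 1); ties count toward both
    tails, so p_upper + p_lower >= 1.
    """
    null = np.asarray(null, dtype=float)
    n = len(null)
    p_upper = (np.sum(null >= observed) + 1.0) / (n + 1.0)
    p_lower = (np.sum(null <= observed) + 1.0) / (n + 1.0)
    sd = null.std()
    z = 0.0 if sd == 0 else float((observed - null.mean()) / sd)
    return float(p_upper), float(p_lower), z


@dataclass
class FdrResult:
    """FDR curve over the grid of observed p-values for one direction."""

    direction: str
    grid: np.ndarray
    fdr: np.ndarray
    data_findings: np.ndarray
    threshold: float | None
    threshold_capped: float | None
    n_significant: int


@dataclass
class PairResults:
    """Observed and null summaries for every site pair of one protein."""

    sites: list
    ordered_stat: np.ndarray          # (S, S) observed, stat[i, j] = i -> j
    null_sum: np.ndarray              # (n_null, P) sum statistic, upper triangle
    pseudo_sum: np.ndarray | None = None   # (n_fdr_sets, P) disjoint pseudo-data sets
    sum_stat: np.ndarray = field(init=False)   # (P,) observed ordered-sum
    z: np.ndarray = field(init=False)
    p_upper: np.ndarray = field(init=False)
    p_lower: np.ndarray = field(init=False)
    fdr_target: float = 0.3
    p_cap: float = 0.05

    def __post_init__(self):
        iu = np.triu_indices(len(self.sites), k=1)
        self.sum_stat = (self.ordered_stat + self.ordered_stat.T)[iu]
        n = self.null_sum.shape[0]
        ge = (self.null_sum >= self.sum_stat[None, :]).sum(axis=0)
        le = (self.null_sum <= self.sum_stat[None, :]).sum(axis=0)
        self.p_upper = (ge + 1.0) / (n + 1.0)
        self.p_lower = (le + 1.0) / (n + 1.0)
        mean = self.null_sum.mean(axis=0)
        sd = self.null_sum.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (self.sum_stat - mean) / sd
        self.z = np.where(sd == 0, 0.0, z)

    @property
    def pair_index(self):
        iu = np.triu_indices(len(self.sites), k=1)
        return list(zip(iu[0], iu[1]))

    def _pseudo_pvalues(self, chunk: int = 64):
        """p-values of the disjoint pseudo-data sets, scored like the data."""
        if self.pseudo_sum is None or len(self.pseudo_sum) == 0:
            raise ValueError("no pseudo-data replicates available for FDR estimation")
        pseudo = self.pseudo_sum
        n = self.null_sum.shape[0]
        m, P = pseudo.shape
        pu = np.empty((m, P))
        pl = np.empty((m, P))
        for lo in range(0, P, chunk):
            hi = min(lo + chunk, P)
            block = self.null_sum[:, lo:hi]              # (n, c)
            q = pseudo[:, lo:hi]                          # (m, c)
            ge = (block[:, None, :] >= q[None, :, :]).sum(axis=0)
            le = (block[:, None, :] <= q[None, :, :]).sum(axis=0)
            pu[:, lo:hi] = (ge + 1.0) / (n + 1.0)
            pl[:, lo:hi] = (le + 1.0) / (n + 1.0)
        return pu, pl

    def fdr_threshold(self, direction: str) -> FdrResult:
        """Largest nominal p with estimated FDR below the target.

        ``direction`` is "concordant" (upper tail) or "discordant" (lower
        tail).  The FDR at a candidate p is the mean number of findings at
        that level across the pseudo-data replicates divided by the number
        of findings in the data.
        """
        if direction not in ("concordant", "discordant"):
            raise ValueError("direction must be 'concordant' or 'discordant'")
        p_data = self.p_upper if direction == "concordant" else self.p_lower
        pu, pl = self._pseudo_pvalues()
        p_pseudo = pu if direction == "concordant" else pl
        grid = np.unique(p_data)
        data_sorted = np.sort(p_data)
        data_counts = np.searchsorted(data_sorted, grid, side="right")
        pseudo_sorted = np.sort(p_pseudo, axis=1)
        pseudo_counts = np.stack(
            [np.searchsorted(row, grid, side="right") for row in pseudo_sorted]
        ).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fdr = pseudo_counts / data_counts
        ok = np.flatnonzero((fdr < self.fdr_target) & (data_counts > 0))
        if len(ok) == 0:
            return FdrResult(direction, grid, fdr, data_counts, None, None, 0)
        thr = float(grid[ok[-1]])
        capped = min(thr, self.p_cap)
        n_sig = int(np.sum(p_data <= capped))
        return FdrResult(direction, grid, fdr, data_counts, thr, capped, n_sig)

    def to_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.sites), k=1)
        sites = np.asarray(self.sites)
        return pd.DataFrame(
            {
                "site_i": sites[iu[0]],
                "site_j": sites[iu[1]],
                "stat_ij": self.ordered_stat[iu],
                "stat_ji": self.ordered_stat.T[iu],
                "z": self.z,
                "p_upper": self.p_upper,
                "p_lower": self.p_lower,
            }
        )


def analyze_pairs(history: SubstitutionHistory, config: EpistatConfig) -> PairResults:
    """Observed statistics plus the full rewired null for one history.

    The last ``n_fdr_sets`` replicates of the null double as the
    pseudo-data sets of the FDR procedure; they are drawn from the same
    margin-preserving ensemble as the null itself.
    """
    tree = history.tree
    sites = history.analyzed_sites
    if len(sites) < 2:
        raise ValueError("need at least two analyzed sites")
    S = len(sites)
    obs_rows = [
        np.asarray(sorted(ev.branch for ev in history.events_at(s)), dtype=np.int64)
        for s in sites
    ]
    weight_map = {(ev.branch, ev.site): ev.weight for ev in history.events}
    obs_weights = [
        np.asarray([weight_map[(int(b), s)] for b in row])
        for row, s in zip(obs_rows, sites)
    ]
    n_events = np.asarray([len(r) for r in obs_rows])
    tau = (
        np.full(S, config.tau, dtype=float)
        if config.tau is not None
        else default_tau(tree, n_events)
    )

    from ._kernels import dfs_walk, ordered_statistics_fast

    walk = dfs_walk(tree)
    obs = ordered_statistics_fast(
        tree, obs_rows, obs_weights, tau,
        same_branch_pairs=history.same_branch_pairs, walk=walk,
    )

    sampler = NullSampler(
        history,
        sites,
        seed=config.seed,
        trades_factor=config.trades_factor,
        support_threshold=config.support_threshold,
    )
    iu = np.triu_indices(S, k=1)
    null_sum = np.empty((config.n_null, len(iu[0])), dtype=np.float32)
    pseudo_sum = np.empty((config.n_fdr_sets, len(iu[0])), dtype=np.float32)
    for r in range(config.n_null + config.n_fdr_sets):
        rows, weights = next(sampler)
        stat = ordered_statistics_fast(
            tree, rows, weights, tau,
            same_branch_pairs=history.same_branch_pairs, walk=walk,
        )
        flat = (stat + stat.T)[iu]
        if r < config.n_null:
            null_sum[r] = flat
        else:
            pseudo_sum[r - config.n_null] = flat

    return PairResults(
        sites=sites,
        ordered_stat=obs,
        null_sum=null_sum,
        pseudo_sum=pseudo_sum,
        fdr_target=config.fdr_target,
        p_cap=config.p_cap,
    )
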