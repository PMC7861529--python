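"""Branch-specific shifts of substitution rates between coevolving groups.

A pre-order traversal keeps a "current ancestor"; at each internal branch
i the vector of per-group substitution counts in the clade below i
(v_i = n_i + m_i) is compared to the counts in the rest of the current
ancestor's clade (c_i = m_a(i) - v_i).  A significant contingency test
(Bonferroni-corrected for the number of internal branches actually
tested) flags branch i as a rate shift and makes it the new current
ancestor.  Subtrees whose total count does not exceed the number of
groups are not tested further.

Cross-protein concordance re-addresses every shift to its parental branch
(a shift detected at a branch could equally sit on its sister) and
compares how many parental branches are hit by several proteins with a
permutation null in which each protein draws the same number of parental
branches with probability proportional to the summed length of the two
daughter branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import Phylogeny, SubstitutionHistory


@dataclass
class RateShift:
    branch: int
    branch_name: str
    parent_branch: int
    parent_name: str
    groups_tested: list
    subtree_counts: np.ndarray        # v_i over tested groups
    rest_counts: np.ndarray           # c_i over tested groups
    test: str                          # "chi2" or "mc-exact"
    p_raw: float
    p_corrected: float


def _contingency_p(v, c, n_mc: int = 100_000, seed: int = 0):
    """2 x G test of homogeneity of two count vectors.

    Pearson chi-square when all expected cells are at least 5, otherwise a
    Monte-Carlo exact test: fixed-margin tables are sampled and the
    observed table's probability compared against theirs (the behavior of
    fisher.test with simulated p-values).
    """
    table = np.vstack([v, c]).astype(int)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
        return 1.0, "degenerate"
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() >= 5:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(p), "chi2"
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = dist.rvs(n_mc, random_state=np.random.default_rng(seed))
    logp_obs = dist.logpmf(table)
    logp_draws = dist.logpmf(draws)
    p = (np.sum(logp_draws <= logp_obs + 1e-9) + 1.0) / (n_mc + 1.0)
    return float(p), "mc-exact"


def _per_branch_counts(tree: Phylogeny, history: SubstitutionHistory, partition: dict):
    """n_i (on-branch) and m_i (below-branch) count vectors per branch."""
    groups = sorted(set(partition.values()))
    gidx = {g: k for k, g in enumerate(groups)}
    G = len(groups)
    n = np.zeros((tree.n_nodes, G), dtype=int)
    for ev in history.events:
        g = partition.get(ev.site)
        if g is not None:
            n[ev.branch, gidx[g]] += 1
    m = np.zeros_like(n)
    for v in tree.preorder[::-1]:
        p = tree.parent[v]
        if p >= 0:
            m[p] += n[v] + m[v]
    return groups, n, m


def detect_rate_shifts(
    history: SubstitutionHistory,
    partition: dict,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
    return_tested: bool = False,
):
    """Branches where relative substitution frequencies between groups shift.

    ``partition`` maps analyzed sites to group ids.  Only internal
    branches are tested; the Bonferroni denominator is the number of
    branches actually subjected to a test under the stop rule (a subtree
    whose total event count is at most the number of groups is not
    descended into).
    """
    if not partition:
        raise ValueError("empty partition")
    tree = history.tree
    groups, n, m = _per_branch_counts(tree, history, partition)
    G = len(groups)
    internal = ~tree.is_leaf

    # branches tested: reachable from the root without crossing the stop rule
    testable = []
    stack = list(tree.children[tree.root])
    while stack:
        v = stack.pop()
        if not internal[v]:
            continue
        testable.append(v)
        for ch in tree.children[v]:
            if n[ch].sum() + m[ch].sum() > G:
                stack.append(ch)
    n_tests = len(testable)

    shifts = []
    # pre-order with explicit current ancestor propagation
    stack = [(ch, tree.root) for ch in tree.children[tree.root]]
    while stack:
        v, anc = stack.pop()
        if not internal[v]:
            continue
        v_counts = n[v] + m[v]
        # events below the current ancestor, excluding the ancestor's own branch
        anc_below = m[anc] if anc != tree.root else n[tree.children[tree.root]].sum(axis=0) + m[
            tree.children[tree.root]
        ].sum(axis=0)
        c_counts = anc_below - v_counts
        keep = anc_below > 0
        p_raw, test = _contingency_p(
            v_counts[keep], c_counts[keep], n_mc=n_mc, seed=seed + v
        )
        p_corr = min(1.0, p_raw * n_tests)
        new_anc = anc
        if p_corr < alpha:
            parent = int(tree.parent[v])
            shifts.append(
                RateShift(
                    branch=int(v),
                    branch_name=tree.names[v],
                    parent_branch=parent,
                    parent_name=tree.names[parent],
                    groups_tested=[g for g, k in zip(groups, keep) if k],
                    subtree_counts=v_counts[keep],
                    rest_counts=c_counts[keep],
                    test=test,
                    p_raw=p_raw,
                    p_corrected=p_corr,
                )
            )
            new_anc = v
        for ch in tree.children[v]:
            if n[ch].sum() + m[ch].sum() > G:
                stack.append((ch, new_anc))
    if return_tested:
        return shifts, sorted(testable)
    return shifts


def shifts_to_frame(shifts: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "branch": s.branch_name,
                "parent": s.parent_name,
                "test": s.test,
                "p_raw": s.p_raw,
                "p_corrected": s.p_corrected,
                "subtree_counts": ",".join(map(str, s.subtree_counts)),
                "rest_counts": ",".join(map(str, s.rest_counts)),
            }
            for s in shifts
        ],
        columns=[
            "branch", "parent", "test", "p_raw", "p_corrected",
            "subtree_counts", "rest_counts",
        ],
    )


@dataclass
class ConcordanceResult:
    counts_by_branch: pd.DataFrame    # parent branch, number of proteins shifting
    observed: np.ndarray              # observed #branches with >= k proteins, k = 0..K
    expected: np.ndarray
    p_values: np.ndarray
    n_parental: int


def concordance_test(
    shifts_by_protein: dict,
    tree: Phylogeny,
    testable_by_protein: dict,
    n_perm: int = 10000,
    seed: int = 0,
) -> ConcordanceResult:
    """Do different proteins shift their group rates on the same branches?

    ``shifts_by_protein`` maps protein -> list of RateShift;
    ``testable_by_protein`` maps protein -> tested branch indices.  Only
    branches tested in every protein enter; each shift is re-addressed to
    its parental branch.  The permutation null draws, per protein, the
    same number of parental branches with probability proportional to the
    summed lengths of the two daughter branches, without replacement.
    """
    proteins = sorted(shifts_by_protein)
    K = len(proteins)
    common = set.intersection(*(set(testable_by_protein[p]) for p in proteins))
    if not common:
        raise ValueError("no branch tested in all proteins")
    parental = sorted({int(tree.parent[b]) for b in common})
    pidx = {b: i for i, b in enumerate(parental)}

    def branch_of(s):
        return s.branch if isinstance(s, RateShift) else int(s)

    weights = np.zeros(len(parental))
    for b in common:
        weights[pidx[int(tree.parent[b])]] += tree.length[b]
    probs = weights / weights.sum()

    hits = np.zeros(len(parental), dtype=int)
    n_obs = []
    for p in proteins:
        addressed = {
            pidx[int(tree.parent[branch_of(s)])]
            for s in shifts_by_protein[p]
            if branch_of(s) in common
        }
        n_obs.append(len(addressed))
        for i in addressed:
            hits[i] += 1
    observed = np.asarray([(hits >= k).sum() for k in range(K + 1)])

    rng = np.random.default_rng(seed)
    perm_counts = np.zeros((n_perm, K + 1), dtype=int)
    for r in range(n_perm):
        h = np.zeros(len(parental), dtype=int)
        for nk in n_obs:
            if nk == 0:
                continue
            draw = rng.choice(len(parental), size=min(nk, len(parental)), replace=False, p=probs)
            h[draw] += 1
        perm_counts[r] = [(h >= k).sum() for k in range(K + 1)]
    expected = perm_counts.mean(axis=0)
    pvals = (np.sum(perm_counts >= observed[None, :], axis=0) + 1.0) / (n_perm + 1.0)

    counts = pd.DataFrame(
        {
            "parent_branch": [tree.names[b] for b in parental],
            "n_proteins": hits,
        }
    )
    return ConcordanceResult(
        counts_by_branch=counts,
        observed=observed,
        expected=expected,
        p_values=pvals,
        n_parental=len(parental),
    )
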