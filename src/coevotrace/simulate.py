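"""Forward simulators and planted histories for ground-truth testing.

Three generative regimes mirror the validation experiments the pair
statistics are meant to pass:

* a haploid Wright-Fisher population with pairwise epistatic fitness
  tables over binary alleles (positive epistasis: the single mutant is a
  fitness valley; negative epistasis: the double mutant is deleterious);
* a clonal-interference population in which every site prefers one amino
  acid and adaptation from a random start produces competing clades;
* per-site fluctuating fitness landscapes on a fixed phylogeny
  (origin-fixation dynamics with lognormal fitness vectors redrawn at
  Poisson change points) — episodic positive selection without any
  interaction between sites.

A fourth generator plants consecutive-pair excess or deficit directly
into a substitution history, bypassing population genetics, for unit
tests of the statistics.  Desk-scale presets shrink population sizes and
durations while preserving the compound parameters (N*mu, and N*s well
above 1) of the full-scale configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo import (
    Phylogeny,
    SubstitutionEvent,
    SubstitutionHistory,
    parse_newick,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# random trees and desk-scale reconstruction


def random_coalescent_tree(n_leaves: int, seed: int = 0, total_length: float | None = None) -> Phylogeny:
    """Kingman-coalescent topology with exponential waiting times."""
    rng = np.random.default_rng(seed)
    active = list(range(n_leaves))
    newick = {i: f"t{i}" for i in active}
    height = {i: 0.0 for i in active}
    t = 0.0
    nxt = n_leaves
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        newick[nxt] = (
            f"({newick[a]}:{t - height[a]:.8f},{newick[b]}:{t - height[b]:.8f})"
        )
        height[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    tree = parse_newick(newick[active[0]] + ";")
    if total_length is not None:
        scale = total_length / tree.total_length
        tree = Phylogeny(
            names=tree.names,
            parent=tree.parent,
            length=tree.length * scale,
            support=tree.support,
        )
    return tree


def random_yule_tree(n_leaves: int, seed: int = 0, total_length: float | None = None) -> Phylogeny:
    """Pure-birth ultrametric topology (broad and shallow).

    A Yule tree's height grows like log(n) while its total length grows
    like n, so per-lineage path lengths stay short — the regime of large
    species phylogenies, where episodic processes touch any single line
    of descent only a few times.
    """
    rng = np.random.default_rng(seed)
    splits = {}          # lineage -> (child_a, child_b, split time)
    active = [0]
    t = 0.0
    nxt = 1
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        v = active[i]
        a, b = nxt, nxt + 1
        nxt += 2
        splits[v] = (a, b, t)
        active[i] = a
        active.append(b)
    end_time = t

    def render(v, born):
        if v in splits:
            a, b, ts = splits[v]
            return f"({render(a, ts)},{render(b, ts)}):{ts - born:.8f}"
        return f"t{v}:{end_time - born:.8f}"

    a, b, t0 = splits[0]
    text = f"({render(a, t0)},{render(b, t0)});"
    tree = parse_newick(text)
    if total_length is not None:
        tree = Phylogeny(
            names=tree.names,
            parent=tree.parent,
            length=tree.length * (total_length / tree.total_length),
            support=tree.support,
        )
    return tree


def neighbor_joining_tree(alignment: dict) -> Phylogeny:
    """Midpoint-rooted NJ tree on p-distances between sampled sequences."""
    import skbio

    names = sorted(alignment)
    arr = np.asarray([list(alignment[n]) for n in names])
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i] != arr).mean(axis=1)
        dm[i] = diff
    dm = (dm + dm.T) / 2
    np.fill_diagonal(dm, 0.0)
    tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=names))
    tree = tree.root_at_midpoint()
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
        if node.length is None and not node.is_root():
            node.length = 0.0
    newick = str(tree).strip()
    return parse_newick(newick)


def fasttree_tree(alignment: dict, seed: int = 0, supports: bool = True) -> Phylogeny:
    """Approximate-ML tree (FastTree, JTT) midpoint-rooted.

    Scales to ~1000 sampled genotypes where neighbor joining becomes both
    slow and noisy; requires the ``fasttree`` executable.  With
    ``supports`` the SH-like local supports are kept, rescaled to percent,
    so hemiplasy weighting can use them.
    """
    import subprocess
    import tempfile

    import skbio

    with tempfile.TemporaryDirectory() as tmp:
        fasta = f"{tmp}/aln.fasta"
        with open(fasta, "w") as fh:
            for name in sorted(alignment):
                fh.write(f">{name}\n{alignment[name]}\n")
        cmd = ["fasttree", "-quiet", "-seed", str(seed)]
        if not supports:
            cmd.append("-nosupport")
        proc = subprocess.run(cmd + [fasta], capture_output=True, text=True, check=True)
    tree = skbio.TreeNode.read([proc.stdout.strip()])
    tree = tree.root_at_midpoint()
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
        if node.length is None and not node.is_root():
            node.length = 0.0
        if supports and not node.is_tip() and node.name:
            try:
                node.name = format(float(node.name) * 100.0, "g")
            except ValueError:
                pass
    return parse_newick(str(tree).strip())


def reconstruct_history(
    alignment: dict,
    seed: int = 0,
    method: str = "fasttree",
    hemiplasy_threshold: float | None = 95.0,
) -> SubstitutionHistory:
    """Alignment -> tree -> parsimony substitution map, desk scale.

    The full-scale analyses consume RAxML trees and MEGA ancestral states;
    at desk scale FastTree (or NJ) plus Fitch parsimony stands in, with
    hemiplasy weighting applied when supports are available.
    """
    from .phylo import weight_hemiplasies

    if method == "fasttree":
        tree = fasttree_tree(alignment, seed=seed, supports=hemiplasy_threshold is not None)
    elif method == "nj":
        tree = neighbor_joining_tree(alignment)
    else:
        raise ValueError("method must be 'fasttree' or 'nj'")
    history = fitch_history(tree, alignment)
    if hemiplasy_threshold is not None and method == "fasttree":
        history = weight_hemiplasies(history, hemiplasy_threshold)
    return history


def fitch_history(tree: Phylogeny, alignment: dict, same_branch_pairs: bool = True) -> SubstitutionHistory:
    """Ancestral states by Fitch parsimony; events are per-branch changes.

    Leaf states come from the alignment; ambiguities are resolved
    deterministically (the parent's state when possible, otherwise the
    lexicographically smallest candidate).
    """
    L = len(next(iter(alignment.values())))
    post = tree.preorder[::-1]
    name_of = tree.names
    events = []
    for site in range(L):
        sets = [None] * tree.n_nodes
        for v in post:
            if tree.is_leaf[v]:
                sets[v] = {alignment[name_of[v]][site]}
            else:
                inter = None
                for ch in tree.children[v]:
                    inter = sets[ch] if inter is None else inter & sets[ch]
                if inter:
                    sets[v] = inter
                else:
                    union = set()
                    for ch in tree.children[v]:
                        union |= sets[ch]
                    sets[v] = union
        state = [None] * tree.n_nodes
        for v in tree.preorder:
            p = tree.parent[v]
            if p < 0:
                state[v] = min(sets[v])
            elif state[p] in sets[v]:
                state[v] = state[p]
            else:
                state[v] = min(sets[v])
                events.append(
                    SubstitutionEvent(
                        branch=int(v), site=site + 1,
                        ancestral=state[p], derived=state[v],
                    )
                )
    return SubstitutionHistory(tree=tree, events=events, same_branch_pairs=same_branch_pairs)


# ---------------------------------------------------------------------------
# Wright-Fisher with pairwise epistasis


@dataclass
class EpistasisSimConfig:
    """Pairwise-epistasis forward simulation.

    Full-scale defaults: haploid N = 50000 evolving 5000 generations at
    mu = 5e-4 per site per generation over 100 sites, 10 positively and 10
    negatively interacting pairs, sampling 50 genotypes every 250
    generations.  The positive table makes each single mutant a shallow
    valley (0.9945) restored by the second substitution; the negative
    table penalizes the double mutant (0.8).
    """

    n_pop: int = 50000
    generations: int = 5000
    mu: float = 5e-4
    n_sites: int = 100
    n_positive_pairs: int = 10
    n_negative_pairs: int = 10
    positive_table: tuple = (1.0, 0.9945, 0.9945, 1.0)
    negative_table: tuple = (1.0, 1.0, 1.0, 0.8)
    sample_every: int = 250
    sample_size: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.positive_table) <= 0 or min(self.negative_table) <= 0:
            raise ValueError("fitness tables must be positive")
        need = 2 * (self.n_positive_pairs + self.n_negative_pairs)
        if need > self.n_sites:
            raise ValueError("planted pairs exceed available sites")

    @classmethod
    def desk(cls, seed: int = 0) -> "EpistasisSimConfig":
        """Scaled-down preset preserving the compound parameters.

        Population shrinks 25-fold; mutation rate and log-fitnesses scale
        up 25-fold, keeping N*mu (= 25), N*s and the valley-suppression
        ratio s/mu of the full-scale configuration.
        """
        f = 25.0
        return cls(
            n_pop=2000, generations=5000, mu=5e-4 * f,
            positive_table=(1.0, 0.9945 ** f, 0.9945 ** f, 1.0),
            negative_table=(1.0, 1.0, 1.0, 0.8 ** f),
            sample_every=250, sample_size=50, seed=seed,
        )


def _planted_pairs(config: EpistasisSimConfig):
    sites = list(range(config.n_sites))
    pos = [(sites[2 * k], sites[2 * k + 1]) for k in range(config.n_positive_pairs)]
    off = 2 * config.n_positive_pairs
    neg = [
        (sites[off + 2 * k], sites[off + 2 * k + 1])
        for k in range(config.n_negative_pairs)
    ]
    return pos, neg


def _wright_fisher(
    start: np.ndarray,
    generations: int,
    mu: float,
    n_states: int,
    log_fitness,
    sample_every: int,
    sample_size: int,
    rng: np.random.Generator,
):
    """Shared WF engine tracking parents, mutations and samples.

    ``log_fitness(pop)`` returns per-individual log fitness.  Returns
    (alignment rows as state vectors, samples, parents, mutations) where
    ``samples`` is a list of (generation, row, name), ``parents[g]`` maps
    each row at generation g to its parent row at g-1, and
    ``mutations[g]`` is an (rows, cols, new_states) triple applied at g.
    """
    N, S = start.shape
    pop = start.copy()
    parents_by_gen = [None]
    muts_by_gen = [None]
    samples = []
    sampled_states = {}
    for gen in range(1, generations + 1):
        logf = log_fitness(pop)
        w = np.exp(logf - logf.max())
        parents = rng.choice(N, size=N, p=w / w.sum())
        pop = pop[parents]
        k = rng.binomial(N * S, mu)
        if k:
            rows = rng.integers(0, N, size=k).astype(np.int32)
            cols = rng.integers(0, S, size=k).astype(np.int32)
            if n_states == 2:
                new = (pop[rows, cols] ^ 1).astype(np.int8)
            else:
                shift = rng.integers(1, n_states, size=k).astype(np.int8)
                new = ((pop[rows, cols] + shift) % n_states).astype(np.int8)
            pop[rows, cols] = new
        else:
            rows = cols = np.empty(0, dtype=np.int32)
            new = np.empty(0, dtype=np.int8)
        parents_by_gen.append(parents.astype(np.int32))
        muts_by_gen.append((rows, cols, new))
        if gen % sample_every == 0:
            take = rng.choice(N, size=min(sample_size, N), replace=False)
            for idx, row in enumerate(sorted(take)):
                name = f"g{gen}_{idx}"
                samples.append((gen, int(row), name))
                sampled_states[name] = pop[row].copy()
    return sampled_states, samples, parents_by_gen, muts_by_gen


class _Lineage:
    __slots__ = ("node", "muts")

    def __init__(self, node):
        self.node = node
        self.muts = []


def _genealogy_history(
    start: np.ndarray,
    samples: list,
    parents_by_gen: list,
    muts_by_gen: list,
    mu: float,
    n_pop: int,
) -> SubstitutionHistory:
    """Exact genealogy of the sampled genotypes with true mutation placement.

    Lineages are traced backwards; lineages meeting in the same individual
    coalesce.  Unresolved lineages join at the (monomorphic) founding
    generation.  Branch lengths are generations times mu (expected
    substitutions per site); each branch's event set is the net
    state change per site over the branch, as ancestral reconstruction
    would define it.
    """
    nodes = {}   # id -> dict(time, children=[(child_id, muts)], name)
    nid = [0]

    def new_node(time, name=None):
        i = nid[0]
        nid[0] += 1
        nodes[i] = {"time": time, "children": [], "name": name or f"N{i}"}
        return i

    by_gen = {}
    for gen, row, name in samples:
        by_gen.setdefault(gen, []).append((row, name))
    G = len(parents_by_gen) - 1
    active: dict = {}

    for gen in range(G, 0, -1):
        # new tips sampled at this generation
        for row, name in by_gen.get(gen, []):
            tip = new_node(gen, name=name)
            active.setdefault(row, []).append(_Lineage(tip))
        # coalesce lineages sharing an individual
        merged = {}
        for row, lins in active.items():
            if len(lins) == 1:
                merged[row] = lins[0]
            else:
                p = new_node(gen)
                for l in lins:
                    nodes[p]["children"].append((l.node, l.muts))
                merged[row] = _Lineage(p)
        # undo this generation's mutations along surviving lineages
        rows, cols, new = muts_by_gen[gen]
        if len(rows):
            flag = np.zeros(n_pop, dtype=bool)
            flag[list(merged.keys())] = True
            hit = np.flatnonzero(flag[rows])
            for h in hit:
                merged[int(rows[h])].muts.append((int(cols[h]), int(new[h]), gen))
        # step to parents
        parents = parents_by_gen[gen]
        nxt: dict = {}
        for row, lin in merged.items():
            nxt.setdefault(int(parents[row]), []).append(lin)
        # lineages meeting in the same parent coalesce at gen-1
        active = {}
        for prow, lins in nxt.items():
            if len(lins) == 1:
                active[prow] = lins
            else:
                p = new_node(gen - 1)
                for l in lins:
                    nodes[p]["children"].append((l.node, l.muts))
                active[prow] = [_Lineage(p)]

    remaining = [l for lins in active.values() for l in lins]
    root_id = new_node(0)
    for l in remaining:
        nodes[root_id]["children"].append((l.node, l.muts))

    # assemble arrays; apply mutations forward (reverse of collection order)
    order = []
    stack = [root_id]
    while stack:
        v = stack.pop()
        order.append(v)
        for c, _ in nodes[v]["children"]:
            stack.append(c)
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    names = [None] * n
    branch_muts = [None] * n
    for v in order:
        i = index[v]
        names[i] = nodes[v]["name"]
        for c, muts in nodes[v]["children"]:
            j = index[c]
            parent[j] = i
            length[j] = (nodes[c]["time"] - nodes[v]["time"]) * mu
            branch_muts[j] = muts
    tree = Phylogeny(
        names=tuple(names),
        parent=parent,
        length=length,
        support=np.full(n, np.nan),
    )
    # forward pass: states and per-branch net changes
    state = [None] * n
    state[index[root_id]] = np.asarray(start, dtype=np.int8).copy()
    events = []
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        s = state[p].copy()
        before = {}
        for site, new_state, _gen in reversed(branch_muts[v] or []):
            before.setdefault(site, s[site])
            s[site] = new_state
        state[v] = s
        for site, old in before.items():
            if s[site] != old:
                events.append(
                    SubstitutionEvent(
                        branch=int(v), site=site + 1,
                        ancestral=AA20[int(old)], derived=AA20[int(s[site])],
                    )
                )
    return SubstitutionHistory(tree=tree, events=events)


def simulate_epistatic_population(config: EpistasisSimConfig, return_history: bool = False):
    """Wright-Fisher run; returns (alignment, truth[, true history]).

    The alignment maps sample names to amino-acid strings (allele a -> A,
    allele A -> C, the first two states of the alphabet) and the truth
    dict lists planted positive and negative pairs as 1-based columns.
    With ``return_history`` the exact sample genealogy with true mutation
    placements is returned as well, bypassing tree re-estimation.
    """
    rng = np.random.default_rng(config.seed)
    N, S = config.n_pop, config.n_sites
    pos_pairs, neg_pairs = _planted_pairs(config)
    pos_t = np.log(np.asarray(config.positive_table))
    neg_t = np.log(np.asarray(config.negative_table))

    def log_fitness(pop):
        logf = np.zeros(pop.shape[0])
        for i, j in pos_pairs:
            logf += pos_t[2 * pop[:, i] + pop[:, j]]
        for i, j in neg_pairs:
            logf += neg_t[2 * pop[:, i] + pop[:, j]]
        return logf

    start = np.zeros(S, dtype=np.int8)
    sampled, samples, parents, muts = _wright_fisher(
        np.tile(start, (N, 1)), config.generations, config.mu, 2,
        log_fitness, config.sample_every, config.sample_size, rng,
    )
    letters = np.array(list(AA20))
    alignment = {k: "".join(letters[v]) for k, v in sampled.items()}
    truth = {
        "positive_pairs": [(i + 1, j + 1) for i, j in pos_pairs],
        "negative_pairs": [(i + 1, j + 1) for i, j in neg_pairs],
    }
    if not return_history:
        return alignment, truth
    history = _genealogy_history(start, samples, parents, muts, config.mu, N)
    return alignment, truth, history


# ---------------------------------------------------------------------------
# clonal interference


@dataclass
class CloneSimConfig:
    """One preferred amino acid per site; adaptation from a random start.

    Full-scale defaults follow the printed configuration: N = 10000, 566
    sites, 5000 generations, mu = 2e-5, non-preferred fitness 0.9,
    sampling 2 genotypes every 5 generations.
    """

    n_pop: int = 10000
    n_sites: int = 566
    generations: int = 5000
    mu: float = 2e-5
    off_fitness: float = 0.9
    sample_every: int = 5
    sample_size: int = 2
    seed: int = 0
    start_at_optimum: bool = False

    @classmethod
    def desk(cls, seed: int = 0) -> "CloneSimConfig":
        """Scaled-down preset preserving N*mu (= 0.2) with N*s >> 1."""
        return cls(
            n_pop=1000, n_sites=100, generations=1500, mu=2e-4,
            sample_every=40, sample_size=2, seed=seed,
        )


def simulate_clonal_interference(config: CloneSimConfig, return_history: bool = False):
    """Wright-Fisher adaptation with one preferred amino acid per site."""
    rng = np.random.default_rng(config.seed)
    N, S = config.n_pop, config.n_sites
    preferred = rng.integers(0, 20, size=S).astype(np.int8)
    if config.start_at_optimum:
        start = preferred.copy()
    else:
        start = rng.integers(0, 20, size=S).astype(np.int8)
    letters = np.array(list(AA20))
    log_off = np.log(config.off_fitness)
    mean_fitness = []

    def log_fitness(pop):
        logf = (pop != preferred[None, :]).sum(axis=1) * log_off
        mean_fitness.append(float(np.exp(logf).mean()))
        return logf

    sampled, samples, parents, muts = _wright_fisher(
        np.tile(start, (N, 1)), config.generations, config.mu, 20,
        log_fitness, config.sample_every, config.sample_size, rng,
    )
    alignment = {k: "".join(letters[v]) for k, v in sampled.items()}
    truth = {"preferred": "".join(letters[preferred]), "mean_fitness": mean_fitness}
    if not return_history:
        return alignment, truth
    history = _genealogy_history(start, samples, parents, muts, config.mu, N)
    return alignment, truth, history


# ---------------------------------------------------------------------------
# fluctuating landscapes on a fixed tree (origin-fixation)


@dataclass
class LandscapeSimConfig:
    """Episodic site-specific selection without epistasis.

    Per site, the 20-allele fitness vector is redrawn from a lognormal
    (mu = 0, sigma = 0.25) at Poisson change points (rate 0.5 per branch
    length unit) independently on every branch; between change points
    substitutions follow origin-fixation dynamics toward the current
    optimum.  On a tree of total length 40 this yields about 20 landscape
    changes per site.
    """

    tree: Phylogeny | None = None
    n_sites: int = 500
    sigma: float = 0.25
    change_rate: float = 0.5
    neutral_rate: float = 1.0
    n_eff: float = 10000.0
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "LandscapeSimConfig":
        """300-leaf Yule tree of total length 40 (about 20 changes/site).

        A broad shallow topology keeps per-lineage change counts below
        one, the regime of large species phylogenies.
        """
        tree = random_yule_tree(300, seed=seed + 1, total_length=40.0)
        return cls(tree=tree, n_sites=100, seed=seed)


def _fixation_weight(log_ratio: np.ndarray, n_eff: float) -> np.ndarray:
    """Substitution rate relative to neutral for selection s = log fitness ratio."""
    s = np.where(np.abs(log_ratio) < 1e-12, 1e-12, log_ratio)
    with np.errstate(over="ignore", under="ignore"):
        w = -np.expm1(-2 * s) / -np.expm1(-2 * n_eff * s)
    w = np.where(np.abs(log_ratio) < 1e-12, 1.0 / (2 * n_eff), w)
    return 2 * n_eff * w


def simulate_fluctuating_landscapes(config: LandscapeSimConfig) -> SubstitutionHistory:
    """Independent episodic selection per site; returns the true history.

    Events are the per-branch endpoint differences (what an ancestral
    reconstruction would see), so at most one event per branch and site.
    The mean number of landscape changes per site is stored on the
    returned history as ``landscape_changes_per_site``.
    """
    tree = config.tree
    if tree is None:
        raise ValueError("landscape simulation requires a tree")
    if tree.total_length <= 0:
        raise ValueError("tree has zero total length")
    rng = np.random.default_rng(config.seed)
    preorder = tree.preorder
    events = []
    n_changes = 0
    for site in range(config.n_sites):
        fitness = rng.normal(0.0, config.sigma, size=20)
        state = {tree.root: int(np.argmax(fitness))}
        land = {tree.root: fitness}
        for v in preorder:
            p = tree.parent[v]
            if p < 0:
                continue
            x = state[p]
            f = land[p]
            t, L = 0.0, tree.length[v]
            start = x
            while True:
                sub_w = _fixation_weight(f - f[x], config.n_eff)
                sub_w[x] = 0.0
                sub_rate = config.neutral_rate * sub_w.sum() / 19.0
                total = config.change_rate + sub_rate
                t += rng.exponential(1.0 / total) if total > 0 else np.inf
                if t >= L:
                    break
                if rng.random() < config.change_rate / total:
                    f = rng.normal(0.0, config.sigma, size=20)
                    n_changes += 1
                else:
                    x = int(rng.choice(20, p=sub_w / sub_w.sum()))
            state[v] = x
            land[v] = f
            if x != start:
                events.append(
                    SubstitutionEvent(
                        branch=int(v), site=site + 1,
                        ancestral=AA20[start], derived=AA20[x],
                    )
                )
    history = SubstitutionHistory(tree=tree, events=events)
    history.landscape_changes_per_site = n_changes / config.n_sites
    return history


# ---------------------------------------------------------------------------
# planted histories


def generate_planted_history(
    tree: Phylogeny,
    n_sites: int,
    planted_pairs: list,
    effect: str = "concordant",
    seed: int = 0,
    events_per_site: float = 6.0,
):
    """Plant consecutive-pair excess or deficit directly into a history.

    Background sites receive events on branches drawn with probability
    proportional to branch length.  For a concordant planted pair, every
    leading event gets a trailing partner on the same branch (waiting
    time 0).  For a discordant pair, the two sites' events are confined
    to disjoint halves of the tree, so no consecutive pair can form.
    Returns (history, truth) where truth lists the planted pairs.
    """
    rng = np.random.default_rng(seed)
    non_root = np.flatnonzero(tree.parent >= 0)
    probs = tree.length[non_root] / tree.length[non_root].sum()
    planted_sites = {s for pair in planted_pairs for s in pair}
    if max(planted_sites, default=0) > n_sites:
        raise ValueError("planted pair site outside 1..n_sites")

    def draw_branches(k):
        k = min(k, len(non_root))
        return non_root[rng.choice(len(non_root), size=k, replace=False, p=probs)]

    def rand_event(branch, site):
        a, d = rng.choice(len(AA20), size=2, replace=False)
        return SubstitutionEvent(
            branch=int(branch), site=site, ancestral=AA20[a], derived=AA20[d]
        )

    events = {}

    def put(ev):
        events.setdefault((ev.branch, ev.site), ev)

    for site in range(1, n_sites + 1):
        if site in planted_sites:
            continue
        k = max(2, rng.poisson(events_per_site))
        for b in draw_branches(k):
            put(rand_event(b, site))

    if effect == "concordant":
        for lead, trail in planted_pairs:
            k = max(2, rng.poisson(events_per_site))
            for b in draw_branches(k):
                put(rand_event(b, lead))
                put(rand_event(b, trail))
    elif effect == "discordant":
        # split the tree at the root into two halves
        kids = tree.children[tree.root]
        half = {}
        for ci, c in enumerate(kids):
            stack = [c]
            while stack:
                v = stack.pop()
                half[v] = ci % 2
                stack.extend(tree.children[v])
        side0 = np.asarray([b for b in non_root if half[b] == 0])
        side1 = np.asarray([b for b in non_root if half[b] == 1])
        if len(side0) == 0 or len(side1) == 0:
            raise ValueError("tree too small to separate clades for discordant planting")
        for lead, trail in planted_pairs:
            k = max(2, rng.poisson(events_per_site))
            for site, side in ((lead, side0), (trail, side1)):
                p = tree.length[side] / tree.length[side].sum()
                take = side[rng.choice(len(side), size=min(k, len(side)), replace=False, p=p)]
                for b in take:
                    put(rand_event(b, site))
    else:
        raise ValueError("effect must be 'concordant' or 'discordant'")

    history = SubstitutionHistory(tree=tree, events=list(events.values()))
    return history, {"planted_pairs": list(planted_pairs), "effect": effect}
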