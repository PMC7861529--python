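"""Tree and substitution-history data model.

A :class:`Phylogeny` is an array-backed rooted tree (parent pointers, branch
lengths in expected substitutions per site, optional bootstrap supports on
internal branches).  Substitution events produced by external ancestral
reconstruction are attached to (branch, site) coordinates; the geometry of
events — waiting times between consecutive substitutions along a line of
descent, patristic distances between substitutions in different lineages —
is what every downstream statistic consumes.

Every branch is identified by its child node.  Events are placed at the
midpoint of their branch for both waiting times and patristic distances.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class NewickError(ValueError):
    """Malformed newick input."""


class ValidationError(ValueError):
    """Structurally valid input that violates a model invariant."""


@dataclass(frozen=True)
class Phylogeny:
    """Rooted tree with branch lengths and optional bootstrap supports.

    Node ``i`` is identified by ``names[i]``; ``parent[i]`` is the index of
    its parent (-1 for the root).  ``length[i]`` is the length of the branch
    above node ``i`` (0 for the root).  ``support[i]`` is the bootstrap
    support (percent) of the branch above internal node ``i``; NaN when
    absent.
    """

    names: tuple
    parent: np.ndarray
    length: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        n = len(self.names)
        if n == 0:
            raise ValidationError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValidationError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.length[self.parent >= 0] < 0):
            raise ValidationError("negative branch length")
        sup = self.support[~np.isnan(self.support)]
        if np.any((sup < 0) | (sup > 100)):
            raise ValidationError("bootstrap support outside [0, 100]")
        if len(set(self.names)) != n:
            raise ValidationError("duplicate node names")

    # -- derived structure (cached lazily via object.__setattr__) ---------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def index(self) -> dict:
        if not hasattr(self, "_index"):
            object.__setattr__(self, "_index", {nm: i for i, nm in enumerate(self.names)})
        return self._index

    @property
    def children(self) -> list:
        if not hasattr(self, "_children"):
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            object.__setattr__(self, "_children", ch)
        return self._children

    @property
    def is_leaf(self) -> np.ndarray:
        if not hasattr(self, "_is_leaf"):
            leaf = np.ones(self.n_nodes, dtype=bool)
            leaf[self.parent[self.parent >= 0]] = False
            object.__setattr__(self, "_is_leaf", leaf)
        return self._is_leaf

    @property
    def preorder(self) -> np.ndarray:
        """Node indices in root-first order (parents before children)."""
        if not hasattr(self, "_preorder"):
            order = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                # reversed so lowest-index child is visited first
                stack.extend(reversed(self.children[v]))
            object.__setattr__(self, "_preorder", np.asarray(order))
        return self._preorder

    @property
    def depth(self) -> np.ndarray:
        """Root-to-node path length per node."""
        if not hasattr(self, "_depth"):
            d = np.zeros(self.n_nodes)
            for v in self.preorder:
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.length[v]
            object.__setattr__(self, "_depth", d)
        return self._depth

    @property
    def level(self) -> np.ndarray:
        """Integer edge-count depth per node (for LCA climbing)."""
        if not hasattr(self, "_level"):
            lv = np.zeros(self.n_nodes, dtype=int)
            for v in self.preorder:
                p = self.parent[v]
                if p >= 0:
                    lv[v] = lv[p] + 1
            object.__setattr__(self, "_level", lv)
        return self._level

    @property
    def midpoint_depth(self) -> np.ndarray:
        """Depth of the midpoint of the branch above each node."""
        return self.depth - self.length / 2.0

    @property
    def total_length(self) -> float:
        return float(self.length.sum())

    # -- queries ----------------------------------------------------------

    def lca(self, u: int, v: int) -> int:
        lv = self.level
        while lv[u] > lv[v]:
            u = self.parent[u]
        while lv[v] > lv[u]:
            v = self.parent[v]
        while u != v:
            u = self.parent[u]
            v = self.parent[v]
        return int(u)

    def is_ancestor(self, u: int, v: int) -> bool:
        """True if branch/node ``u`` is an ancestor of ``v`` (u != v)."""
        return u != v and self.lca(u, v) == u

    def root_path(self, v: int) -> list:
        """Nodes from the root's child down to ``v`` inclusive."""
        path = []
        while v >= 0:
            path.append(v)
            v = self.parent[v]
        return path[::-1]

    def midpoint_distance(self, b1: int, b2: int) -> float:
        """Patristic distance between midpoints of two branches."""
        if b1 == b2:
            return 0.0
        d1 = self.midpoint_depth[b1]
        d2 = self.midpoint_depth[b2]
        if self.is_ancestor(b1, b2):
            return float(d2 - d1)
        if self.is_ancestor(b2, b1):
            return float(d1 - d2)
        a = self.lca(b1, b2)
        return float(d1 + d2 - 2.0 * self.depth[a])

    def write_newick(self) -> str:
        return _write_newick(self)


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Numeric internal-node labels are interpreted as bootstrap supports
    (the RAxML convention); non-numeric labels become node names.  Nodes
    without a usable label get stable generated names ``N<k>`` in preorder.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            case_sensitive_taxon_labels=True,
            terminating_semicolon_required=True,
            taxon_namespace=dendropy.TaxonNamespace(is_case_sensitive=True),
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse failure: {exc}") from exc

    nodes = list(tree.preorder_node_iter())
    names, parents, lengths, supports = [], [], [], []
    pos = {}
    auto = 0
    for nd in nodes:
        pos[id(nd)] = len(names)
        label = None
        if nd.taxon is not None and nd.taxon.label:
            label = nd.taxon.label
        elif nd.label:
            label = nd.label
        support = math.nan
        if label is not None and not nd.is_leaf():
            try:
                support = float(label)
                label = None
            except ValueError:
                pass
        if label is None:
            label = f"N{auto}"
            auto += 1
        if nd.parent_node is None:
            parents.append(-1)
            lengths.append(0.0)
            support = math.nan
        else:
            parents.append(pos[id(nd.parent_node)])
            if nd.edge.length is None:
                raise NewickError(f"missing branch length above node {label!r}")
            lengths.append(float(nd.edge.length))
        if not nd.is_leaf() and nd.parent_node is None:
            support = math.nan
        names.append(label)
        supports.append(support)

    return Phylogeny(
        names=tuple(names),
        parent=np.asarray(parents, dtype=int),
        length=np.asarray(lengths, dtype=float),
        support=np.asarray(supports, dtype=float),
    )


def _write_newick(tree: Phylogeny) -> str:
    def render(v: int) -> str:
        ch = tree.children[v]
        if not ch:
            core = tree.names[v]
        else:
            inner = ",".join(render(c) for c in ch)
            sup = tree.support[v]
            label = "" if np.isnan(sup) else format(sup, "g")
            core = f"({inner}){label}"
        if tree.parent[v] < 0:
            return core
        return f"{core}:{tree.length[v]:.10g}"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# substitution histories


@dataclass(frozen=True)
class SubstitutionEvent:
    """One amino-acid substitution on a branch at an alignment column."""

    branch: int          # child-node index identifying the branch
    site: int            # 1-based alignment column
    ancestral: str
    derived: str
    weight: float = 1.0

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValidationError("ancestral and derived states are equal")
        if not (0.0 < self.weight <= 1.0):
            raise ValidationError(f"event weight {self.weight} outside (0, 1]")


@dataclass(frozen=True)
class ConsecutivePair:
    """An ordered pair of substitutions on one line of descent."""

    leading: SubstitutionEvent
    trailing: SubstitutionEvent
    waiting_time: float

    @property
    def weight(self) -> float:
        return self.leading.weight * self.trailing.weight


@dataclass
class SubstitutionHistory:
    """A phylogeny decorated with located substitution events.

    ``analyzed_sites`` is the set of sites with at least two events; sites
    with fewer carry no pairwise signal and are excluded from all
    statistics.
    """

    tree: Phylogeny
    events: list
    same_branch_pairs: bool = True
    dropped_rows: int = 0
    _by_site: dict = field(default=None, repr=False)

    def __post_init__(self):
        n = self.tree.n_nodes
        seen = set()
        root = self.tree.root
        for ev in self.events:
            if not (0 <= ev.branch < n):
                raise ValidationError(f"event branch index {ev.branch} outside tree")
            if ev.branch == root:
                raise ValidationError("events cannot be placed on the root (no branch)")
            key = (ev.branch, ev.site)
            if key in seen:
                raise ValidationError(f"duplicate event at branch/site {key}")
            seen.add(key)
        self._by_site = {}
        for ev in self.events:
            self._by_site.setdefault(ev.site, []).append(ev)

    @property
    def site_counts(self) -> dict:
        return {s: len(evs) for s, evs in self._by_site.items()}

    @property
    def analyzed_sites(self) -> list:
        return sorted(s for s, evs in self._by_site.items() if len(evs) >= 2)

    def events_at(self, site: int) -> list:
        return list(self._by_site.get(site, []))

    def with_events(self, events: list) -> "SubstitutionHistory":
        return SubstitutionHistory(
            tree=self.tree,
            events=list(events),
            same_branch_pairs=self.same_branch_pairs,
            dropped_rows=self.dropped_rows,
        )

    def incidence(self, sites=None):
        """Binary site x branch event matrix over ``sites``.

        Returns (matrix, site list): ``matrix[k, b]`` is 1 iff site
        ``sites[k]`` has an event on branch ``b``.
        """
        if sites is None:
            sites = self.analyzed_sites
        mat = np.zeros((len(sites), self.tree.n_nodes), dtype=np.uint8)
        for k, s in enumerate(sites):
            for ev in self._by_site.get(s, []):
                mat[k, ev.branch] = 1
        return mat, list(sites)


def load_substitutions(table, tree: Phylogeny, same_branch_pairs: bool = True) -> SubstitutionHistory:
    """Build a history from a ``branch site from to`` TSV.

    ``table`` may be a path, a file-like object, a TSV string, or a
    DataFrame.  Rows whose ancestral and derived state coincide, or whose
    states fall outside the 20-letter amino-acid alphabet, are dropped (the
    count is recorded on the history).  Unknown branch names raise.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        if isinstance(table, str) and "\t" in table:
            table = io.StringIO(table)
        df = pd.read_csv(table, sep="\t", comment="#", dtype=str)
    required = {"branch", "site", "from", "to"}
    if not required.issubset(df.columns):
        raise ValidationError(f"substitution table must have columns {sorted(required)}")

    events, dropped = [], 0
    seen = set()
    for name, site, anc, der in df[["branch", "site", "from", "to"]].itertuples(
        index=False, name=None
    ):
        name = str(name)
        if name not in tree.index:
            raise KeyError(f"unknown branch {name!r} in substitution table")
        anc = str(anc).upper()
        der = str(der).upper()
        if anc == der or anc not in AMINO_ACIDS or der not in AMINO_ACIDS:
            dropped += 1
            continue
        branch = tree.index[name]
        site = int(site)
        if (branch, site) in seen:
            raise ValidationError(f"duplicate (branch, site) row: {name}, {site}")
        seen.add((branch, site))
        events.append(SubstitutionEvent(branch=branch, site=site, ancestral=anc, derived=der))
    return SubstitutionHistory(
        tree=tree, events=events, same_branch_pairs=same_branch_pairs, dropped_rows=dropped
    )


def poorly_resolved_components(tree: Phylogeny, support_threshold: float = 95.0) -> np.ndarray:
    """Component label per node after deleting well-resolved branches.

    A branch is well resolved if it is terminal or its bootstrap support
    strictly exceeds ``support_threshold``; removing well-resolved branches
    splits the tree into poorly resolved subtrees, within which the exact
    position of a substitution is considered unknown.
    """
    internal = ~tree.is_leaf
    has_sup = ~np.isnan(tree.support)
    if internal.sum() > 1 and not has_sup[internal & (tree.parent >= 0)].any():
        raise ValidationError(
            "hemiplasy weighting requires bootstrap supports on internal branches"
        )
    comp = np.arange(tree.n_nodes)
    # union nodes across branches that are NOT well resolved
    parent_map = {}
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        well = tree.is_leaf[v] or (has_sup[v] and tree.support[v] > support_threshold)
        if not well:
            parent_map[v] = p
    # simple union-find
    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for v, p in parent_map.items():
        comp[find(v)] = find(p)
    return np.asarray([find(v) for v in range(tree.n_nodes)])


def weight_hemiplasies(
    history: SubstitutionHistory, support_threshold: float = 95.0
) -> SubstitutionHistory:
    """Down-weight potentially hemiplasic events.

    Within each poorly resolved subtree (components left after removing
    branches with support > ``support_threshold``), a site reconstructed
    with n >= 2 substitutions is conservatively assumed to have experienced
    only one real substitution at an unknown position: each of the n events
    keeps weight 1/n.  All other events keep weight 1.
    """
    comp = poorly_resolved_components(history.tree, support_threshold)
    counts = {}
    for ev in history.events:
        key = (ev.site, comp[ev.branch])
        counts[key] = counts.get(key, 0) + 1
    new_events = []
    for ev in history.events:
        n = counts[(ev.site, comp[ev.branch])]
        new_events.append(replace(ev, weight=1.0 / n if n > 1 else 1.0))
    return history.with_events(new_events)


# ---------------------------------------------------------------------------
# pair geometry

def consecutive_pairs(
    history: SubstitutionHistory, leading_site: int, trailing_site: int
) -> list:
    """Ordered consecutive substitution pairs (leading site -> trailing site).

    Two substitutions are consecutive when they fall on the same line of
    descent and no other substitution at either site lies strictly between
    them.  Events on the same branch (unordered in time) are counted as a
    consecutive pair with waiting time 0 in each direction when the
    history's ``same_branch_pairs`` convention is on; the same-branch
    partner also pre-empts any strictly ancestral leading candidate.
    """
    tree = history.tree
    lead = {ev.branch: ev for ev in history.events_at(leading_site)}
    trail = {ev.branch: ev for ev in history.events_at(trailing_site)}
    md = tree.midpoint_depth
    pairs = []
    for tb, tev in trail.items():
        # nearest event at either site at-or-above the trailing branch,
        # excluding the trailing event itself
        v = tb
        nearest = None
        while v >= 0:
            if v == tb:
                # same-branch partner: ignored entirely when the
                # same-branch convention is off
                if history.same_branch_pairs and v in lead:
                    nearest = ("lead", v)
                    break
            else:
                if v in lead:
                    nearest = ("lead", v)
                    break
                if v in trail:
                    nearest = ("trail", v)
                    break
            v = tree.parent[v]
        if nearest is None or nearest[0] != "lead":
            continue
        lb = nearest[1]
        t = 0.0 if lb == tb else float(md[tb] - md[lb])
        pairs.append(ConsecutivePair(leading=lead[lb], trailing=tev, waiting_time=t))
    return pairs


def nonconsecutive_distances(
    history: SubstitutionHistory, site_a: int, site_b: int
) -> list:
    """Patristic distances between non-consecutive cross-site event pairs.

    One distance per unordered (event at a, event at b) pair that is not
    consecutive in either direction: the events fall into different
    lineages, or the same lineage with another substitution at one of the
    two sites between them.
    """
    tree = history.tree
    cons = set()
    for p in consecutive_pairs(history, site_a, site_b):
        cons.add((p.leading.branch, p.trailing.branch))
    for p in consecutive_pairs(history, site_b, site_a):
        cons.add((p.trailing.branch, p.leading.branch))
    out = []
    for ea in history.events_at(site_a):
        for eb in history.events_at(site_b):
            if (ea.branch, eb.branch) in cons:
                continue
            out.append(tree.midpoint_distance(ea.branch, eb.branch))
    return out
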