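import numpy as np
import pytest

from coevotrace.phylo import (
    Phylogeny,
    SubstitutionEvent,
    SubstitutionHistory,
    parse_newick,
)


@pytest.fixture
def three_lineage_tree():
    """Three cherries hanging off the root; stems and leaf branches length 1."""
    return parse_newick("((A:1,a:1):1,(B:1,b:1):1,(C:1,c:1):1);")


@pytest.fixture
def concordant_history(three_lineage_tree):
    """A site-1 substitution followed by a site-2 substitution in each cherry."""
    t = three_lineage_tree
    ix = t.index
    events = []
    for stem, leaf in (("N1", "A"), ("N2", "B"), ("N3", "C")):
        events.append(SubstitutionEvent(branch=ix[stem], site=1, ancestral="A", derived="V"))
        events.append(SubstitutionEvent(branch=ix[leaf], site=2, ancestral="L", derived="I"))
    return SubstitutionHistory(tree=t, events=events)


@pytest.fixture
def perfect_map_history(three_lineage_tree):
    """Perfect allele association: A background always yields W, C yields F."""
    t = three_lineage_tree
    ix = t.index
    events = [
        SubstitutionEvent(branch=ix["N1"], site=1, ancestral="G", derived="A"),
        SubstitutionEvent(branch=ix["N2"], site=1, ancestral="G", derived="C"),
        SubstitutionEvent(branch=ix["A"], site=2, ancestral="L", derived="W"),
        SubstitutionEvent(branch=ix["a"], site=2, ancestral="L", derived="W"),
        SubstitutionEvent(branch=ix["B"], site=2, ancestral="L", derived="F"),
        SubstitutionEvent(branch=ix["b"], site=2, ancestral="L", derived="F"),
    ]
    return SubstitutionHistory(tree=t, events=events)


def random_history(tree: Phylogeny, n_sites: int, rate: float, seed: int,
                   same_branch_pairs: bool = True) -> SubstitutionHistory:
    """Events placed independently per site with probability ~ branch length."""
    rng = np.random.default_rng(seed)
    non_root = np.flatnonzero(tree.parent >= 0)
    p = 1 - np.exp(-rate * tree.length[non_root])
    events = []
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for s in range(1, n_sites + 1):
        for b in non_root[rng.random(len(non_root)) < p]:
            i, j = rng.choice(20, size=2, replace=False)
            events.append(
                SubstitutionEvent(branch=int(b), site=s, ancestral=aas[i], derived=aas[j])
            )
    return SubstitutionHistory(tree=tree, events=events, same_branch_pairs=same_branch_pairs)


def brute_force_consecutive(history, leading_site, trailing_site):
    """Definition-based enumeration of consecutive pairs over explicit paths.

    A pair forms when the leading event is an ancestor of the trailing
    event on its root path and no event at either site lies strictly
    between them; events sharing the trailing branch pre-empt ancestral
    candidates (waiting time 0) under the same-branch convention.
    """
    tree = history.tree
    lead = {e.branch: e for e in history.events_at(leading_site)}
    trail = {e.branch: e for e in history.events_at(trailing_site)}
    md = tree.midpoint_depth
    out = []
    for tb in trail:
        path = tree.root_path(tb)          # root .. tb inclusive
        if history.same_branch_pairs and tb in lead:
            out.append((tb, tb, 0.0))
            continue
        for lb in path[:-1]:
            if lb not in lead:
                continue
            i0, i1 = path.index(lb), path.index(tb)
            between = path[i0 + 1:i1]
            if any(b in lead or b in trail for b in between):
                continue
            out.append((lb, tb, md[tb] - md[lb]))
    return out
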