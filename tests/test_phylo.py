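import numpy as np
import pytest

import coevotrace as ct
from coevotrace.phylo import (
    NewickError,
    SubstitutionEvent,
    SubstitutionHistory,
    ValidationError,
    parse_newick,
    poorly_resolved_components,
)
from coevotrace.simulate import random_coalescent_tree

from conftest import brute_force_consecutive, random_history


class TestParseNewick:
    def test_minimal_two_leaf_tree(self):
        t = parse_newick("(A:1,B:1):0;")
        assert set(t.names) >= {"A", "B"}
        leaves = [t.index["A"], t.index["B"]]
        assert all(t.length[v] == 1 for v in leaves)

    def test_internal_label_read_as_support(self):
        t = parse_newick("((A:1,B:1)95:2,C:3);")
        internal = [v for v in range(t.n_nodes) if not t.is_leaf[v] and t.parent[v] >= 0]
        assert len(internal) == 1
        assert t.support[internal[0]] == 95

    def test_roundtrip_on_random_tree(self):
        t = random_coalescent_tree(50, seed=3)
        t2 = parse_newick(t.write_newick())
        assert t2.names == t.names
        assert np.array_equal(t2.parent, t.parent)
        assert np.allclose(t2.length, t.length)
        assert parse_newick(t2.write_newick()).write_newick() == t2.write_newick()

    @pytest.mark.parametrize("bad", ["((A:1,B:1;", "(A:1,B:-2);", "", "(A:1,B:x);"])
    def test_malformed_or_invalid_input(self, bad):
        with pytest.raises((NewickError, ValidationError)):
            parse_newick(bad)


class TestLoadSubstitutions:
    TSV = "branch\tsite\tfrom\tto\n"

    def test_single_event_site_excluded(self, three_lineage_tree):
        h = ct.load_substitutions(self.TSV + "A\t7\tL\tI\n", three_lineage_tree)
        assert 7 not in h.analyzed_sites
        assert h.site_counts[7] == 1

    def test_empty_table_is_valid(self, three_lineage_tree):
        h = ct.load_substitutions(self.TSV, three_lineage_tree)
        assert h.analyzed_sites == []

    def test_two_events_make_site_analyzed(self, three_lineage_tree):
        h = ct.load_substitutions(self.TSV + "A\t3\tL\tI\nB\t3\tL\tV\n", three_lineage_tree)
        assert h.analyzed_sites == [3]
        assert h.site_counts[3] == 2

    def test_unknown_branch_raises(self, three_lineage_tree):
        with pytest.raises(KeyError):
            ct.load_substitutions(self.TSV + "ZZZ\t3\tL\tI\n", three_lineage_tree)

    def test_identical_states_dropped_with_count(self, three_lineage_tree):
        h = ct.load_substitutions(self.TSV + "A\t3\tL\tL\nB\t3\tX\tI\n", three_lineage_tree)
        assert h.dropped_rows == 2

    def test_duplicate_rows_rejected(self, three_lineage_tree):
        with pytest.raises(ValidationError):
            ct.load_substitutions(
                self.TSV + "A\t3\tL\tI\nA\t3\tI\tV\n", three_lineage_tree
            )


class TestHemiplasyWeights:
    def test_events_in_poorly_resolved_subtree_share_weight(self):
        # three events on internal branches with support below the cutoff:
        # they fall into one poorly resolved subtree and share weight 1/n
        t = parse_newick("((((A:1,B:1)50:1,C:1)50:1,D:1)50:1,(E:1,F:1)99:1);")
        ix = t.index
        internal_poor = [
            v for v in range(t.n_nodes)
            if not t.is_leaf[v] and t.parent[v] >= 0 and t.support[v] == 50
        ]
        assert len(internal_poor) == 3
        events = [
            SubstitutionEvent(branch=v, site=1, ancestral="L", derived="IVM"[k])
            for k, v in enumerate(internal_poor)
        ]
        h = SubstitutionHistory(tree=t, events=events)
        hw = ct.weight_hemiplasies(h, 95.0)
        assert all(abs(e.weight - 1 / 3) < 1e-12 for e in hw.events)
        # events on well-resolved (terminal) branches keep weight 1
        leaf_events = [
            SubstitutionEvent(branch=ix["A"], site=1, ancestral="L", derived="I"),
            SubstitutionEvent(branch=ix["B"], site=1, ancestral="L", derived="V"),
        ]
        hw2 = ct.weight_hemiplasies(SubstitutionHistory(tree=t, events=leaf_events), 95.0)
        assert all(e.weight == 1.0 for e in hw2.events)

    def test_fully_supported_tree_keeps_unit_weights(self):
        t = parse_newick("(((A:1,B:1)100:1,C:1)100:1,D:5);")
        ix = t.index
        events = [
            SubstitutionEvent(branch=ix["A"], site=1, ancestral="L", derived="I"),
            SubstitutionEvent(branch=ix["B"], site=1, ancestral="L", derived="V"),
        ]
        hw = ct.weight_hemiplasies(SubstitutionHistory(tree=t, events=events), 95.0)
        assert all(e.weight == 1.0 for e in hw.events)

    def test_single_event_keeps_unit_weight(self):
        t = parse_newick("(((A:1,B:1)50:1,C:1)50:1,D:5);")
        ix = t.index
        events = [SubstitutionEvent(branch=ix["A"], site=1, ancestral="L", derived="I")]
        hw = ct.weight_hemiplasies(SubstitutionHistory(tree=t, events=events), 95.0)
        assert hw.events[0].weight == 1.0

    def test_missing_supports_raise(self):
        t = parse_newick("(((A:1,B:1):1,C:1):1,D:5);")
        with pytest.raises(ValidationError):
            poorly_resolved_components(t, 95.0)


class TestConsecutivePairs:
    def test_three_lineages_give_three_ordered_pairs(self, concordant_history):
        assert len(ct.consecutive_pairs(concordant_history, 1, 2)) == 3
        assert len(ct.consecutive_pairs(concordant_history, 2, 1)) == 0

    def test_chain_breaks_long_pairs(self):
        # s1, s2, s1, s2 along one lineage: the middle s1 event breaks the
        # long-range pairing, leaving exactly two consecutive pairs
        t = parse_newick("((((L:1)X3:1)X2:1)X1:1,O:4);")
        ix = t.index
        events = [
            SubstitutionEvent(branch=ix["X1"], site=1, ancestral="L", derived="I"),
            SubstitutionEvent(branch=ix["X2"], site=2, ancestral="A", derived="V"),
            SubstitutionEvent(branch=ix["X3"], site=1, ancestral="I", derived="M"),
            SubstitutionEvent(branch=ix["L"], site=2, ancestral="V", derived="T"),
        ]
        h = SubstitutionHistory(tree=t, events=events)
        assert len(ct.consecutive_pairs(h, 1, 2)) == 2
        assert len(ct.consecutive_pairs(h, 2, 1)) == 1  # X2 -> X3

    def test_same_branch_convention_switch(self, three_lineage_tree):
        ix = three_lineage_tree.index
        events = [
            SubstitutionEvent(branch=ix["N1"], site=1, ancestral="L", derived="I"),
            SubstitutionEvent(branch=ix["N1"], site=2, ancestral="A", derived="V"),
        ]
        h = SubstitutionHistory(tree=three_lineage_tree, events=events)
        pairs = ct.consecutive_pairs(h, 1, 2)
        assert len(pairs) == 1 and pairs[0].waiting_time == 0.0
        h_off = SubstitutionHistory(
            tree=three_lineage_tree, events=events, same_branch_pairs=False
        )
        assert ct.consecutive_pairs(h_off, 1, 2) == []

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("same_branch", [True, False])
    def test_matches_brute_force_on_small_trees(self, seed, same_branch):
        tree = random_coalescent_tree(4, seed=seed, total_length=6.0)
        h = random_history(tree, n_sites=3, rate=0.8, seed=seed, same_branch_pairs=same_branch)
        for a in (1, 2, 3):
            for b in (1, 2, 3):
                if a == b:
                    continue
                got = sorted(
                    (p.leading.branch, p.trailing.branch, round(p.waiting_time, 9))
                    for p in ct.consecutive_pairs(h, a, b)
                )
                want = sorted((l, t, round(w, 9)) for l, t, w in brute_force_consecutive(h, a, b))
                assert got == want

    @pytest.mark.parametrize("seed", range(5))
    def test_pair_partition_covers_all_cross_pairs(self, seed):
        """Ordered pairs both ways plus non-consecutive pairs tile the cross product."""
        tree = random_coalescent_tree(6, seed=seed, total_length=8.0)
        h = random_history(tree, n_sites=2, rate=0.7, seed=seed + 100)
        n1, n2 = len(h.events_at(1)), len(h.events_at(2))
        c12 = ct.consecutive_pairs(h, 1, 2)
        c21 = ct.consecutive_pairs(h, 2, 1)
        nc = ct.nonconsecutive_distances(h, 1, 2)
        k12 = {(p.leading.branch, p.trailing.branch) for p in c12}
        k21 = {(p.trailing.branch, p.leading.branch) for p in c21}
        assert not (k12 & k21) or all(a == b for a, b in (k12 & k21))
        assert len(k12 | k21) + len(nc) == n1 * n2
        assert all(p.waiting_time >= 0 for p in c12 + c21)
        assert all(d >= 0 for d in nc)


class TestNonconsecutiveDistances:
    def test_sibling_midpoint_distance(self):
        t = parse_newick("(A:1,B:2);")
        ix = t.index
        h = SubstitutionHistory(
            tree=t,
            events=[
                SubstitutionEvent(branch=ix["A"], site=1, ancestral="L", derived="I"),
                SubstitutionEvent(branch=ix["B"], site=2, ancestral="A", derived="V"),
            ],
        )
        # midpoints at 0.5 and 1.0 down their branches: distance 1.5
        d = ct.nonconsecutive_distances(h, 1, 2)
        assert d == pytest.approx([1.5])

    def test_all_consecutive_gives_empty(self, concordant_history):
        # one trailing per leading in the same cherry: every cross pair in a
        # cherry is consecutive, pairs across cherries are not
        d = ct.nonconsecutive_distances(concordant_history, 1, 2)
        assert len(d) == 9 - 3

    def test_count_complements_consecutive(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ix = t.index
        events = [
            SubstitutionEvent(branch=ix["N1"], site=1, ancestral="L", derived="I"),
            SubstitutionEvent(branch=ix["C"], site=1, ancestral="L", derived="M"),
            SubstitutionEvent(branch=ix["A"], site=2, ancestral="A", derived="V"),
            SubstitutionEvent(branch=ix["D"], site=2, ancestral="A", derived="T"),
        ]
        h = SubstitutionHistory(tree=t, events=events)
        # only the stem->A pair is consecutive; 4 cross pairs minus 1
        n_cons = len(ct.consecutive_pairs(h, 1, 2)) + len(ct.consecutive_pairs(h, 2, 1))
        assert n_cons == 1
        assert len(ct.nonconsecutive_distances(h, 1, 2)) == 4 - 1
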