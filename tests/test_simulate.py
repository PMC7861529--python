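import numpy as np
import pytest
from scipy import stats

import coevotrace as ct
from coevotrace import simulate as sim


class TestTrees:
    def test_yule_tree_is_broad_and_shallow(self):
        t = sim.random_yule_tree(200, seed=1, total_length=40.0)
        leaves = int(t.is_leaf.sum())
        assert leaves == 200
        assert t.total_length == pytest.approx(40.0)
        assert t.depth.max() < 0.1 * t.total_length

    def test_coalescent_tree_scaled(self):
        t = sim.random_coalescent_tree(30, seed=2, total_length=15.0)
        assert int(t.is_leaf.sum()) == 30
        assert t.total_length == pytest.approx(15.0)


class TestEpistasisSim:
    def test_fixed_seed_is_deterministic(self):
        cfg = sim.EpistasisSimConfig(
            n_pop=300, generations=150, mu=2e-3, sample_every=50, sample_size=5, seed=3
        )
        a1, t1 = sim.simulate_epistatic_population(cfg)
        a2, t2 = sim.simulate_epistatic_population(cfg)
        assert a1 == a2 and t1 == t2

    def test_nonpositive_fitness_rejected(self):
        with pytest.raises(ValueError):
            sim.EpistasisSimConfig(positive_table=(1, 0, 1, 1))

    def test_neutral_heterozygosity_matches_diffusion_expectation(self):
        # symmetric two-state mutation at stationarity: H ~ 2N*mu / (1 + 2N*mu)
        N, mu = 400, 5e-4
        cfg = sim.EpistasisSimConfig(
            n_pop=N, generations=4000, mu=mu, n_positive_pairs=0, n_negative_pairs=0,
            n_sites=60, sample_every=200, sample_size=40, seed=4,
        )
        aln, _ = sim.simulate_epistatic_population(cfg)
        late = {k: v for k, v in aln.items() if int(k.split("_")[0][1:]) > 2000}
        arr = np.array([list(v) for v in late.values()]) != "A"
        freq = arr.mean(axis=0)
        het = 2 * freq * (1 - freq)
        expect = 2 * N * mu / (1 + 2 * N * mu)
        assert np.mean(het) == pytest.approx(expect, rel=0.4)

    def test_negative_pairs_avoid_double_mutants(self):
        cfg = sim.EpistasisSimConfig(n_pop=2000, seed=5)
        aln, truth = sim.simulate_epistatic_population(cfg)
        arr = np.array([list(v) for v in aln.values()]) != "A"
        ratios = []
        for i, j in truth["negative_pairs"]:
            pi, pj = arr[:, i - 1].mean(), arr[:, j - 1].mean()
            joint = (arr[:, i - 1] & arr[:, j - 1]).mean()
            if pi * pj > 0.01:
                ratios.append(joint / (pi * pj))
        assert ratios and np.median(ratios) < 0.2

    def test_true_genealogy_reproduces_sampled_sequences(self):
        cfg = sim.EpistasisSimConfig(
            n_pop=300, generations=200, mu=2e-3, sample_every=50, sample_size=6, seed=6
        )
        aln, _, hist = sim.simulate_epistatic_population(cfg, return_history=True)
        tree = hist.tree
        state = {tree.root: np.zeros(cfg.n_sites, dtype=int)}
        by_branch = {}
        for e in hist.events:
            by_branch.setdefault(e.branch, []).append(e)
        for v in tree.preorder:
            p = tree.parent[v]
            if p < 0:
                continue
            s = state[p].copy()
            for e in by_branch.get(v, []):
                assert sim.AA20[s[e.site - 1]] == e.ancestral
                s[e.site - 1] = sim.AA20.index(e.derived)
            state[v] = s
            if tree.is_leaf[v] and tree.names[v] in aln:
                got = "".join(sim.AA20[x] for x in s)
                assert got == aln[tree.names[v]]


class TestCloneSim:
    def test_optimum_start_barely_evolves(self):
        base = dict(n_pop=400, n_sites=50, generations=400, mu=2e-4,
                    sample_every=100, sample_size=5)
        still = sim.CloneSimConfig(**base, seed=7, start_at_optimum=True)
        aln_s, truth_s = sim.simulate_clonal_interference(still)
        moving = sim.CloneSimConfig(**base, seed=7)
        aln_m, truth_m = sim.simulate_clonal_interference(moving)
        pref = truth_s["preferred"]
        mismatch_still = np.mean(
            [sum(a != b for a, b in zip(v, pref)) for v in aln_s.values()]
        )
        mismatch_move = np.mean(
            [sum(a != b for a, b in zip(v, truth_m["preferred"])) for v in aln_m.values()]
        )
        assert mismatch_still < 2
        assert mismatch_move > mismatch_still

    def test_adaptation_raises_mean_fitness(self):
        cfg = sim.CloneSimConfig(
            n_pop=500, n_sites=60, generations=600, mu=3e-4,
            sample_every=100, sample_size=2, seed=8,
        )
        _, truth = sim.simulate_clonal_interference(cfg)
        mf = truth["mean_fitness"]
        assert mf[-1] > mf[0]

    def test_random_start_creates_coexisting_lineages(self):
        cfg = sim.CloneSimConfig.desk(seed=9)
        _, _, hist = sim.simulate_clonal_interference(cfg, return_history=True)
        tree = hist.tree
        # several ancestral lineages should coexist halfway through the run
        # (clonal interference), each leaving sampled descendants
        d_mid = tree.depth.max() / 2
        crossing = sum(
            1 for v in range(tree.n_nodes)
            if tree.parent[v] >= 0
            and tree.depth[tree.parent[v]] < d_mid <= tree.depth[v]
        )
        assert crossing >= 2


class TestLandscapeSim:
    def test_zero_change_rate_freezes_the_landscape(self):
        tree = sim.random_yule_tree(50, seed=10, total_length=10.0)
        cfg = sim.LandscapeSimConfig(tree=tree, n_sites=30, change_rate=0.0, seed=11)
        hist = sim.simulate_fluctuating_landscapes(cfg)
        assert hist.landscape_changes_per_site == 0
        # at a static optimum nearly nothing substitutes
        assert len(hist.events) < 0.2 * cfg.n_sites

    def test_change_rate_times_length_sets_changes_per_site(self):
        cfg = sim.LandscapeSimConfig.desk(seed=12)
        hist = sim.simulate_fluctuating_landscapes(cfg)
        assert hist.landscape_changes_per_site == pytest.approx(20.0, abs=2.5)

    def test_sites_evolve_independently(self):
        # co-occurrence between sites WITHIN one run should look exactly
        # like co-occurrence between sites of two independent runs on the
        # same tree — the direct signature of cross-site independence
        tree = sim.random_yule_tree(150, seed=21, total_length=40.0)
        hists = [
            sim.simulate_fluctuating_landscapes(
                sim.LandscapeSimConfig(tree=tree, n_sites=30, seed=s)
            )
            for s in (22, 23)
        ]
        mats = [h.incidence(sites=list(range(1, 31)))[0] for h in hists]

        def mean_cooc(ma, mb, skip_diag):
            tot = n = 0
            for i in range(ma.shape[0]):
                for j in range(mb.shape[0]):
                    if skip_diag and i == j:
                        continue
                    tot += np.sum(ma[i] & mb[j])
                    n += 1
            return tot / n

        within = (mean_cooc(mats[0], mats[0], True) + mean_cooc(mats[1], mats[1], True)) / 2
        across = mean_cooc(mats[0], mats[1], False)
        assert within == pytest.approx(across, rel=0.1)

    def test_zero_length_tree_rejected(self):
        tree = sim.random_yule_tree(10, seed=14, total_length=1.0)
        zero = ct.Phylogeny(
            names=tree.names, parent=tree.parent,
            length=np.zeros_like(tree.length), support=tree.support,
        )
        with pytest.raises(ValueError):
            sim.simulate_fluctuating_landscapes(
                sim.LandscapeSimConfig(tree=zero, n_sites=5)
            )


class TestPlantedHistory:
    def test_concordant_planting_boosts_the_pair_statistic(self):
        tree = sim.random_coalescent_tree(40, seed=15, total_length=25.0)
        hist, truth = sim.generate_planted_history(
            tree, n_sites=25, planted_pairs=[(1, 2)], effect="concordant", seed=16
        )
        tau = 1.0
        planted = ct.epistatic_statistic(ct.consecutive_pairs(hist, 1, 2), tau)
        others = []
        for a in range(3, 26):
            for b in range(a + 1, 26):
                others.append(ct.epistatic_statistic(ct.consecutive_pairs(hist, a, b), tau))
        assert planted > np.quantile(others, 0.95)

    def test_discordant_planting_separates_clades(self):
        tree = sim.random_coalescent_tree(40, seed=17, total_length=25.0)
        hist, _ = sim.generate_planted_history(
            tree, n_sites=10, planted_pairs=[(1, 2)], effect="discordant", seed=18
        )
        assert ct.consecutive_pairs(hist, 1, 2) == []
        assert ct.consecutive_pairs(hist, 2, 1) == []

    def test_null_history_calibrates_pair_pvalues(self):
        tree = sim.random_coalescent_tree(30, seed=19, total_length=20.0)
        hist, _ = sim.generate_planted_history(tree, n_sites=20, planted_pairs=[], seed=20)
        res = ct.analyze_pairs(hist, ct.EpistatConfig(n_null=150, n_fdr_sets=10, seed=0))
        # mid-p transform of the discrete permutation p-values ~ uniform
        midp = res.p_upper - 0.5 / (150 + 1)
        ks = stats.kstest(midp, "uniform")
        assert ks.pvalue > 0.01


class TestReconstruction:
    def test_fitch_parsimony_places_hand_checkable_events(self):
        tree = ct.parse_newick("((A:1,B:1)n1:1,(C:1,D:1)n2:1);")
        aln = {"A": "AA", "B": "AV", "C": "VV", "D": "VV"}
        hist = sim.fitch_history(tree, aln)
        got = {(tree.names[e.branch], e.site, e.ancestral, e.derived) for e in hist.events}
        assert got == {("n2", 1, "A", "V"), ("A", 2, "V", "A")}

    def test_nj_tree_covers_all_samples(self):
        cfg = sim.CloneSimConfig(n_pop=150, n_sites=40, generations=200, mu=1e-3,
                                 sample_every=50, sample_size=4, seed=24)
        aln, _ = sim.simulate_clonal_interference(cfg)
        tree = sim.neighbor_joining_tree(aln)
        leaves = {tree.names[v] for v in range(tree.n_nodes) if tree.is_leaf[v]}
        assert leaves == set(aln)
        assert (tree.length >= 0).all()

    def test_fasttree_reconstruction_pipeline(self):
        cfg = sim.CloneSimConfig(n_pop=150, n_sites=40, generations=200, mu=1e-3,
                                 sample_every=50, sample_size=4, seed=25)
        aln, _ = sim.simulate_clonal_interference(cfg)
        hist = sim.reconstruct_history(aln, seed=25)
        tree = hist.tree
        leaves = {tree.names[v] for v in range(tree.n_nodes) if tree.is_leaf[v]}
        assert leaves == set(aln)
        sup = tree.support[~np.isnan(tree.support)]
        assert len(sup) and (sup >= 0).all() and (sup <= 100).all()
        # hemiplasy weighting applied: weights in (0, 1]
        assert all(0 < e.weight <= 1 for e in hist.events)
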