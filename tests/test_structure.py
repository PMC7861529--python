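import itertools

import networkx as nx
import numpy as np
import pytest

from coevotrace.structure import (
    MappingError,
    SamplingInfeasibleError,
    build_contact_graph,
    classify_residues,
    contact_density_test,
    interface_enrichment_test,
    map_msa_to_structure,
    sample_matched_subgraphs,
)


def pdb_text(residues):
    """Minimal synthetic PDB: residues as (chain, resseq, resname, atoms)."""
    lines = []
    serial = 1
    for chain, resseq, resname, atoms in residues:
        for name, elem, x, y, z in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines)


AA3 = {"A": "ALA", "G": "GLY", "L": "LEU", "K": "LYS", "W": "TRP",
       "F": "PHE", "D": "ASP", "R": "ARG", "S": "SER", "T": "THR"}


def chain_pdb(path, seq, chain="A", spacing=5.0, resseq0=1):
    residues = [
        (chain, resseq0 + i, AA3[aa], [("CA", "C", spacing * i, 0.0, 0.0)])
        for i, aa in enumerate(seq)
    ]
    path.write_text(pdb_text(residues))
    return path


class TestMsaMapping:
    SEQ = "AGLKWFDRST"

    def test_identical_sequences_map_identically(self, tmp_path):
        pdb = chain_pdb(tmp_path / "t.pdb", self.SEQ)
        msa = {"ref": self.SEQ, "other": self.SEQ}
        smap = map_msa_to_structure(msa, "ref", str(pdb), "A")
        assert smap.identity == 1.0
        assert smap.column_to_residue == {
            i + 1: ("A", i + 1, " ") for i in range(len(self.SEQ))
        }

    def test_reference_insertion_shifts_mapping(self, tmp_path):
        # reference has one extra residue absent from the chain: its column
        # is unmapped and later columns shift by one
        pdb = chain_pdb(tmp_path / "t.pdb", self.SEQ)
        ref = self.SEQ[:5] + "C" + self.SEQ[5:]
        smap = map_msa_to_structure({"ref": ref}, "ref", str(pdb), "A", identity_floor=0.8)
        mapped = smap.column_to_residue
        assert all(mapped[c] == ("A", c, " ") for c in range(1, 6))
        assert all(mapped[c] == ("A", c - 1, " ") for c in range(7, 12))
        assert 6 not in mapped

    def test_gap_columns_are_skipped(self, tmp_path):
        pdb = chain_pdb(tmp_path / "t.pdb", self.SEQ)
        ref = "--" + self.SEQ[:4] + "--" + self.SEQ[4:]
        smap = map_msa_to_structure({"ref": ref}, "ref", str(pdb), "A")
        assert smap.column_to_residue[3] == ("A", 1, " ")
        assert smap.column_to_residue[9] == ("A", 5, " ")

    def test_wrong_chain_trips_identity_floor(self, tmp_path):
        pdb = chain_pdb(tmp_path / "t.pdb", "WWWWWWWWDD")
        with pytest.raises(MappingError):
            map_msa_to_structure({"ref": "AGLKAGLKAG"}, "ref", str(pdb), "A")


class TestContactGraph:
    def _smap(self, tmp_path, coords):
        seq = "AGLKWFDRST"[: len(coords)]
        residues = [
            ("A", i + 1, AA3[aa], [("CA", "C", *xyz)])
            for i, (aa, xyz) in enumerate(zip(seq, coords))
        ]
        p = tmp_path / "c.pdb"
        p.write_text(pdb_text(residues))
        return map_msa_to_structure({"ref": seq}, "ref", str(p), "A")

    def test_cutoff_is_exclusive(self, tmp_path):
        smap = self._smap(tmp_path, [(0, 0, 0), (3.9, 0, 0), (3.9 + 4.1, 0, 0)])
        g = build_contact_graph(smap, cutoff=4.0)
        assert g.has_edge(1, 2) and not g.has_edge(2, 3)

    def test_collinear_spacing_gives_path_not_triangle(self, tmp_path):
        smap = self._smap(tmp_path, [(0, 0, 0), (3.5, 0, 0), (7.0, 0, 0)])
        g = build_contact_graph(smap, cutoff=4.0)
        assert sorted(g.edges) == [(1, 2), (2, 3)]

    def test_invariant_to_atom_order_and_chain_name(self, tmp_path):
        coords = [(0, 0, 0), (3.0, 0, 0), (6.5, 0, 0), (20, 0, 0)]
        smap1 = self._smap(tmp_path, coords)
        g1 = build_contact_graph(smap1)
        seq = "AGLK"
        # same residues under another chain id, with a second atom listed
        # first: the graph only depends on geometry
        residues = [
            ("Z", i + 1, AA3[aa], [("CB", "C", xyz[0], 0.5, 0.0), ("CA", "C", *xyz)])
            for i, (aa, xyz) in enumerate(zip(seq, coords))
        ]
        p = tmp_path / "ren.pdb"
        p.write_text(pdb_text(residues))
        smap2 = map_msa_to_structure({"ref": seq}, "ref", str(p), "Z")
        g2 = build_contact_graph(smap2)
        assert sorted(g1.edges) == sorted(g2.edges)


class TestResidueClasses:
    def _structure(self, tmp_path):
        res = [("A", 1, "ALA", [("CB", "C", 0.0, 0.0, 0.0)])]
        k = 2
        for dx, dy, dz in itertools.product((-3.0, 0.0, 3.0), repeat=3):
            if dx == dy == dz == 0:
                continue
            res.append(("A", k, "ALA", [("CB", "C", dx, dy, dz)]))
            k += 1
        res += [
            ("A", 50, "ALA", [("CB", "C", 50.0, 0.0, 0.0)]),
            ("A", 60, "ALA", [("CB", "C", 30.0, 0.0, 0.0)]),
            ("A", 61, "ALA", [("CB", "C", 40.0, 0.0, 0.0)]),
            ("B", 1, "GLY", [("CA", "C", 30.0, 3.5, 0.0)]),
            ("B", 2, "GLY", [("CA", "C", 40.0, 5.5, 0.0)]),
        ]
        p = tmp_path / "cplx.pdb"
        p.write_text(pdb_text(res))
        return str(p)

    def test_four_classes_from_constructed_geometry(self, tmp_path):
        classes = classify_residues(self._structure(tmp_path), "A")
        assert classes[("A", 1, " ")] == "buried"          # caged, ~0% accessible
        assert classes[("A", 60, " ")] == "contact"        # 3.5 A from chain B
        assert classes[("A", 61, " ")] == "ENC_interface"  # shaded, no contact
        assert classes[("A", 50, " ")] == "ENC_noninterface"

    def test_classes_are_exhaustive_and_exclusive(self, tmp_path):
        classes = classify_residues(self._structure(tmp_path), "A")
        assert all(
            c in ("buried", "contact", "ENC_interface", "ENC_noninterface")
            for c in classes.values()
        )
        assert len(classes) == 30  # every standard residue of chain A classified


class TestContactDensity:
    def test_component_partition_maximizes_total_density(self):
        g = nx.Graph([(1, 2), (2, 3), (4, 5)])
        part = {1: 0, 2: 0, 3: 0, 4: 1, 5: 1}
        res = contact_density_test(part, g, n_samples=200, seed=0)
        assert res.total_density == 1.0

    def test_planted_spatial_clusters_are_significant(self):
        rng = np.random.default_rng(0)
        g = nx.Graph()
        blocks = [list(range(10 * b, 10 * b + 10)) for b in range(3)]
        for block in blocks:
            for u, v in itertools.combinations(block, 2):
                if rng.random() < 0.8:
                    g.add_edge(u, v)
        for u, v in itertools.combinations(range(30), 2):
            if rng.random() < 0.02:
                g.add_edge(u, v)
        part = {v: b for b, block in enumerate(blocks) for v in block}
        res = contact_density_test(part, g, n_samples=2000, seed=1)
        assert res.total_p < 5e-3
        assert res.total_density > res.total_expected

    def test_random_labels_calibrate(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(40, 0.2, seed=3)
        pvals = []
        for rep in range(40):
            part = {v: int(rng.integers(3)) for v in g.nodes}
            res = contact_density_test(part, g, n_samples=120, seed=rep)
            pvals.append(res.total_p)
        # p-values roughly uniform: mean near 0.5, spread over the range
        assert 0.3 < np.mean(pvals) < 0.7


class TestMatchedSubgraphs:
    def test_single_vertex_subset_samples_uniformly(self):
        g = nx.path_graph(6)
        samples = sample_matched_subgraphs(g, {2}, 600, seed=0)
        counts = {v: 0 for v in g.nodes}
        for s in samples:
            assert len(s) == 1
            counts[next(iter(s))] += 1
        freq = np.array(list(counts.values())) / 600
        assert np.max(np.abs(freq - 1 / 6)) < 0.07

    def test_edge_in_triangle_samples_edges(self):
        g = nx.complete_graph(3)
        samples = sample_matched_subgraphs(g, {0, 1}, 300, seed=1)
        for s in samples:
            assert len(s) == 2 and g.has_edge(*sorted(s))

    def test_constraints_hold_for_every_sample(self):
        g = nx.grid_2d_graph(5, 5)
        subset = {(0, 0), (0, 1), (1, 0), (4, 4), (4, 3)}
        comps = [c for c in nx.connected_components(g.subgraph(subset))]
        sizes = sorted(len(c) for c in comps)
        min_edges = {
            len(c): g.subgraph(c).number_of_edges() for c in comps
        }
        samples = sample_matched_subgraphs(g, subset, 80, seed=2)
        for s in samples:
            assert len(s) == len(subset)
            sub = g.subgraph(s)
            comp_sizes = sorted(len(c) for c in nx.connected_components(sub))
            # component samples are disjoint and at least as connected; they
            # may merge in the host graph, so compare total edge counts
            assert sub.number_of_edges() >= sum(min_edges.values()) - 1
            assert sum(comp_sizes) == len(subset)

    def test_backoff_resolves_component_collisions(self):
        # the only triangle shares nodes with most edges; when the edge
        # component is drawn first from the triangle, the sampler must back
        # off and redraw until a disjoint placement is found
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3), (7, 8)])
        samples = sample_matched_subgraphs(g, {0, 1, 2, 7, 8}, 60, seed=5)
        for s in samples:
            assert s == frozenset({0, 1, 2, 7, 8})

    def test_unknown_subset_nodes_raise(self):
        with pytest.raises(ValueError):
            sample_matched_subgraphs(nx.path_graph(3), {99}, 5, seed=0)


class TestInterfaceEnrichment:
    def _setting(self):
        g = nx.grid_2d_graph(6, 6)
        nodes = sorted(g.nodes)
        part = {v: (0 if v[0] < 3 else 1) for v in nodes}
        return g, nodes, part

    def test_subset_equal_to_group_maximizes_jaccard(self):
        g, nodes, part = self._setting()
        group0 = {v for v, c in part.items() if c == 0}
        samples = sample_matched_subgraphs(g, group0, 150, seed=3)
        res = interface_enrichment_test(part, group0, samples)
        row = res.table[res.table.group == 0].iloc[0]
        assert row.jaccard == 1.0
        assert row.jaccard == res.table.jaccard.max()
        assert row.p_upper <= 0.1

    def test_disjoint_subset_gives_zero_jaccard(self):
        g, nodes, part = self._setting()
        group1 = {v for v, c in part.items() if c == 1}
        samples = sample_matched_subgraphs(g, group1, 100, seed=4)
        res = interface_enrichment_test(part, group1, samples)
        row = res.table[res.table.group == 0].iloc[0]
        assert row.jaccard == 0.0
        assert row.p_lower < 0.5

    def test_empty_subset_rejected(self):
        g, nodes, part = self._setting()
        with pytest.raises(ValueError):
            interface_enrichment_test(part, set(), [frozenset()])
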