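"""Mapping alignment columns onto protein structures and testing overlap.

The alignment's reference row (a Bos taurus sequence for the mitochondrial
complexes) is globally aligned to the residue sequence of one chain of a
PDB structure; mapped columns become nodes of a contact graph whose edges
join residues with any heavy-atom pair closer than 4 A.  Residues are
classified by solvent accessibility into buried (<5% relative
accessibility in the isolated subunit), inter-subunit contact, exposed
non-contact interface (accessibility drops in the complex), and plain
surface.  Enrichment of coevolving groups in contact/interface residues is
tested against random subgraphs of the contact graph matched for vertex
count and spatial clustering (edge count), sampled component by component
with rejection and back-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Theoretical maximum accessible surface areas (A^2), Tien et al. 2013,
# used to convert absolute SASA into relative accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

RESIDUE_CLASSES = ("buried", "contact", "ENC_interface", "ENC_noninterface")


class MappingError(ValueError):
    pass


class SamplingInfeasibleError(RuntimeError):
    pass


def load_structure(pdb_path: str):
    parser = PDBParser(QUIET=True)
    return parser.get_structure("s", pdb_path)


def _chain_residues(chain):
    """Standard residues of a chain in sequence order: (key, one-letter)."""
    out = []
    for res in chain:
        het, resseq, icode = res.id
        if het != " " or res.resname not in THREE_TO_ONE:
            continue
        out.append(((chain.id, resseq, icode), THREE_TO_ONE[res.resname]))
    return out


def _heavy_coords(res) -> np.ndarray:
    coords = [a.coord for a in res.get_atoms() if a.element not in ("H", "D")]
    return np.asarray(coords, dtype=float)


@dataclass
class StructureMap:
    """Injective map from alignment columns to residues of one chain."""

    chain: str
    column_to_residue: dict       # 1-based column -> (chain id, resseq, icode)
    residue_atoms: dict           # residue key -> (n_heavy_atoms, 3) array
    identity: float

    def __post_init__(self):
        vals = list(self.column_to_residue.values())
        if len(vals) != len(set(vals)):
            raise MappingError("column-to-residue mapping is not injective")

    @property
    def mapped_columns(self) -> list:
        return sorted(self.column_to_residue)


def map_msa_to_structure(
    msa,
    reference_id: str,
    structure,
    chain: str,
    identity_floor: float = 0.9,
) -> StructureMap:
    """Align the gap-stripped reference row to a structure chain.

    ``msa`` is a FASTA path or a mapping id -> aligned sequence;
    ``structure`` is a PDB path or a parsed Bio.PDB structure.  Global
    affine alignment (BLOSUM62, gap open -11 / extend -1); columns whose
    reference residue aligns to a chain residue are mapped.  An alignment
    identity below ``identity_floor`` aborts — the chain is wrong.
    """
    if not isinstance(msa, dict):
        msa = {rec.id: str(rec.seq) for rec in SeqIO.parse(msa, "fasta")}
    if reference_id not in msa:
        raise MappingError(f"reference {reference_id!r} not in alignment")
    if isinstance(structure, str):
        structure = load_structure(structure)
    model = structure[0]
    if chain not in [c.id for c in model]:
        raise MappingError(f"chain {chain!r} not in structure")

    row = msa[reference_id].upper()
    columns = [i + 1 for i, c in enumerate(row) if c not in "-."]
    ref_seq = "".join(c for c in row if c not in "-.")
    residues = _chain_residues(model[chain])
    chain_seq = "".join(r[1] for r in residues)
    if not ref_seq or not chain_seq:
        raise MappingError("empty reference or chain sequence")

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(ref_seq, chain_seq)[0]

    matches = aligned = 0
    mapping = {}
    for (r0, r1), (c0, c1) in zip(*aln.aligned):
        for off in range(r1 - r0):
            aligned += 1
            if ref_seq[r0 + off] == chain_seq[c0 + off]:
                matches += 1
            mapping[columns[r0 + off]] = residues[c0 + off][0]
    identity = matches / aligned if aligned else 0.0
    if identity < identity_floor:
        raise MappingError(
            f"alignment identity {identity:.2f} below floor {identity_floor:.2f}; "
            "wrong chain or reference?"
        )
    atoms = {}
    for res in model[chain]:
        key = (chain, res.id[1], res.id[2])
        if key in set(mapping.values()):
            xyz = _heavy_coords(res)
            if len(xyz):
                atoms[key] = xyz
    mapping = {c: k for c, k in mapping.items() if k in atoms}
    return StructureMap(
        chain=chain, column_to_residue=mapping, residue_atoms=atoms, identity=identity
    )


def build_contact_graph(smap: StructureMap, cutoff: float = 4.0) -> nx.Graph:
    """Edges between mapped columns with heavy atoms closer than ``cutoff``."""
    cols = smap.mapped_columns
    g = nx.Graph()
    g.add_nodes_from(cols)
    coords, owner = [], []
    for i, c in enumerate(cols):
        xyz = smap.residue_atoms[smap.column_to_residue[c]]
        coords.append(xyz)
        owner.extend([i] * len(xyz))
    if not coords:
        return g
    pts = np.vstack(coords)
    owner = np.asarray(owner)
    tree = cKDTree(pts)
    for a, b in tree.query_pairs(cutoff):
        ia, ib = owner[a], owner[b]
        if ia != ib:
            g.add_edge(cols[ia], cols[ib])
    return g


def classify_residues(
    structure,
    chain: str,
    contact_cutoff: float = 4.0,
    buried_below: float = 5.0,
    enc_tolerance: float = 0.1,
) -> dict:
    """Residue class per (chain, resseq, icode) key of one chain.

    buried: relative accessibility in the isolated subunit below 5%.
    contact: any heavy atom within ``contact_cutoff`` of another chain.
    ENC_interface: exposed non-contact whose relative accessibility in the
    complex is lower than in isolation by more than ``enc_tolerance``
    percentage points.  ENC_noninterface: the rest.
    """
    if isinstance(structure, str):
        structure = load_structure(structure)
    model = structure[0]
    sr = ShrakeRupley()

    def rsa(entity):
        sr.compute(entity, level="R")
        out = {}
        for ch in entity if entity.level == "M" else [entity]:
            for res in ch:
                if res.id[0] == " " and res.resname in THREE_TO_ONE:
                    rel = 100.0 * res.sasa / MAX_ASA[THREE_TO_ONE[res.resname]]
                    out[(ch.id, res.id[1], res.id[2])] = rel
        return out

    rsa_complex = rsa(model)
    rsa_isolated = rsa(model[chain])

    # heavy atoms of every other chain, for inter-subunit contacts
    other = []
    for ch in model:
        if ch.id == chain:
            continue
        for res in ch:
            for a in res.get_atoms():
                if a.element not in ("H", "D"):
                    other.append(a.coord)
    other_tree = cKDTree(np.asarray(other)) if other else None

    classes = {}
    for res in model[chain]:
        if res.id[0] != " " or res.resname not in THREE_TO_ONE:
            continue
        key = (chain, res.id[1], res.id[2])
        iso = rsa_isolated.get(key)
        if iso is None:
            continue
        if iso < buried_below:
            classes[key] = "buried"
            continue
        xyz = _heavy_coords(res)
        if other_tree is not None and len(xyz) and (
            other_tree.query(xyz, k=1)[0].min() < contact_cutoff
        ):
            classes[key] = "contact"
        elif rsa_complex.get(key, iso) < iso - enc_tolerance:
            classes[key] = "ENC_interface"
        else:
            classes[key] = "ENC_noninterface"
    return classes


# ---------------------------------------------------------------------------
# contact-density test


@dataclass
class ContactDensityResult:
    per_group: pd.DataFrame     # group, n_sites, density, expected, p
    total_density: float
    total_expected: float
    total_p: float


def contact_density_test(
    partition: dict,
    contact_graph: nx.Graph,
    n_samples: int = 10000,
    seed: int = 0,
) -> ContactDensityResult:
    """Are sites of a coevolving group in contact more often than random?

    Group density: edges within the group over edges touching the group.
    Total density: same-group edges over all edges.  The null permutes
    group labels over the contact-graph nodes.
    """
    nodes = [v for v in sorted(contact_graph.nodes) if v in partition]
    labels = np.asarray([partition[v] for v in nodes])
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.asarray(
        [(idx[u], idx[v]) for u, v in contact_graph.edges if u in idx and v in idx]
    )
    groups = sorted(set(labels))
    rng = np.random.default_rng(seed)

    def densities(lab):
        if len(edges) == 0:
            return {g: np.nan for g in groups}, np.nan
        lu, lv = lab[edges[:, 0]], lab[edges[:, 1]]
        same = lu == lv
        per = {}
        for g in groups:
            touch = (lu == g) | (lv == g)
            within = same & (lu == g)
            per[g] = within.sum() / touch.sum() if touch.sum() else np.nan
        return per, same.sum() / len(edges)

    obs_per, obs_total = densities(labels)
    null_per = {g: np.zeros(n_samples) for g in groups}
    null_total = np.zeros(n_samples)
    for r in range(n_samples):
        per, tot = densities(labels[rng.permutation(len(labels))])
        for g in groups:
            null_per[g][r] = per[g]
        null_total[r] = tot

    rows = []
    for g in groups:
        null = null_per[g][~np.isnan(null_per[g])]
        exp = float(null.mean()) if len(null) else np.nan
        p = (
            (np.sum(null >= obs_per[g]) + 1.0) / (len(null) + 1.0)
            if len(null) and not np.isnan(obs_per[g])
            else np.nan
        )
        n_sites = int(np.sum(labels == g))
        rows.append((g, n_sites, obs_per[g], exp, p))
    total_p = (np.sum(null_total >= obs_total) + 1.0) / (n_samples + 1.0)
    return ContactDensityResult(
        per_group=pd.DataFrame(
            rows, columns=["group", "n_sites", "density", "expected", "p"]
        ),
        total_density=float(obs_total),
        total_expected=float(null_total.mean()),
        total_p=float(total_p),
    )


# ---------------------------------------------------------------------------
# matched-subgraph sampler and interface enrichment


def _grow_connected(graph, size, allowed, rng):
    """One attempt at a random connected subgraph of ``size`` vertices."""
    pool = sorted(allowed)
    if len(pool) < size:
        return None
    start = pool[rng.integers(len(pool))]
    chosen = {start}
    frontier = sorted(set(graph[start]) & allowed)
    while len(chosen) < size:
        if not frontier:
            return None
        v = frontier[rng.integers(len(frontier))]
        chosen.add(v)
        frontier = sorted((set(frontier) | (set(graph[v]) & allowed)) - chosen)
    return chosen


def sample_matched_subgraphs(
    contact_graph: nx.Graph,
    testing_subset,
    n: int,
    seed: int = 0,
    max_trials: int = 10000,
    max_backoffs: int = 100,
) -> list:
    """Random subsets matched to the testing subset's spatial clustering.

    For each connected component of the subgraph induced by the testing
    subset, a random connected subgraph with the same vertex count and at
    least as many edges is grown from the contact graph; component samples
    are vertex-disjoint.  A component that cannot be sampled within
    ``max_trials`` attempts triggers a one-step back-off (the previous
    component is resampled); ``max_backoffs`` failures raise.
    """
    subset = set(testing_subset)
    missing = subset - set(contact_graph.nodes)
    if missing:
        raise ValueError(f"testing subset contains unknown nodes: {sorted(missing)[:5]}")
    if not subset:
        raise ValueError("empty testing subset")
    comps = sorted(
        (sorted(c) for c in nx.connected_components(contact_graph.subgraph(subset))),
        key=lambda c: (-len(c), c[0]),
    )
    targets = [
        (len(c), contact_graph.subgraph(c).number_of_edges()) for c in comps
    ]
    rng = np.random.default_rng(seed)
    all_nodes = set(contact_graph.nodes)

    samples = []
    for _ in range(n):
        order = list(rng.permutation(len(comps)))
        chosen: list = []
        backoffs = 0
        i = 0
        while i < len(order):
            size, min_edges = targets[order[i]]
            allowed = all_nodes - set().union(*chosen) if chosen else all_nodes
            found = None
            for _trial in range(max_trials):
                cand = _grow_connected(contact_graph, size, allowed, rng)
                if cand is None:
                    continue
                if contact_graph.subgraph(cand).number_of_edges() >= min_edges:
                    found = cand
                    break
            if found is None:
                backoffs += 1
                if backoffs > max_backoffs or i == 0:
                    raise SamplingInfeasibleError(
                        f"cannot sample component of size {size} with >= {min_edges} edges"
                    )
                chosen.pop()
                i -= 1
                continue
            chosen.append(found)
            i += 1
        samples.append(frozenset().union(*chosen))
    return samples


@dataclass
class EnrichmentResult:
    table: pd.DataFrame          # group, n_sites, observed, expected, jaccard, p_upper, p_lower
    chi2: float
    table_p: float
    n_samples: int


def interface_enrichment_test(
    partition: dict,
    testing_subset,
    samples: list,
) -> EnrichmentResult:
    """Association between coevolving groups and a structural site class.

    Observed per-group counts of testing-subset members are compared with
    expectations over the matched subgraph samples; the chi-square
    statistic over the groups x (in, out) contingency table gets its
    p-value from the sampled null, and each group additionally gets a
    Jaccard index with upper (enrichment) and lower (avoidance) p-values.
    """
    subset = set(testing_subset)
    if not subset:
        raise ValueError("empty testing subset")
    groups = {}
    for v, g in partition.items():
        groups.setdefault(g, set()).add(v)
    gids = sorted(groups)
    n = len(samples)

    def counts(sel):
        return np.asarray([len(groups[g] & sel) for g in gids], dtype=float)

    obs = counts(subset)
    sample_counts = np.stack([counts(set(s)) for s in samples])
    exp = sample_counts.mean(axis=0)
    sizes = np.asarray([len(groups[g]) for g in gids], dtype=float)

    def chi2(cnt):
        e_in = np.maximum(exp, 1e-12)
        e_out = np.maximum(sizes - exp, 1e-12)
        return float(np.sum((cnt - exp) ** 2 / e_in + ((sizes - cnt) - e_out) ** 2 / e_out))

    obs_chi2 = chi2(obs)
    null_chi2 = np.asarray([chi2(c) for c in sample_counts])
    table_p = (np.sum(null_chi2 >= obs_chi2) + 1.0) / (n + 1.0)

    rows = []
    for k, g in enumerate(gids):
        jac_obs = len(groups[g] & subset) / len(groups[g] | subset)
        jac_null = np.asarray(
            [len(groups[g] & set(s)) / len(groups[g] | set(s)) for s in samples]
        )
        pu = (np.sum(jac_null >= jac_obs) + 1.0) / (n + 1.0)
        pl = (np.sum(jac_null <= jac_obs) + 1.0) / (n + 1.0)
        rows.append((g, len(groups[g]), obs[k], exp[k], jac_obs, pu, pl))
    return EnrichmentResult(
        table=pd.DataFrame(
            rows,
            columns=["group", "n_sites", "observed", "expected", "jaccard", "p_upper", "p_lower"],
        ),
        chi2=obs_chi2,
        table_p=float(table_p),
        n_samples=n,
    )
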