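"""End-to-end orchestration: history -> pair table -> graph -> groups.

`analyze_history` is the in-memory core used by the CLI, the examples and
the simulation experiments: it runs the epistatic statistics against the
rewired null, converts them to pseudo-correlations, partial correlations
and association statistics, estimates FDR thresholds for both directions,
builds the signed coevolution graph and partitions it into coevolving
groups.  `run_pipeline` is the file-based wrapper with resumable stages
and a checksum manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association as assoc
from . import epistat, graphs
from .phylo import SubstitutionHistory, load_substitutions, parse_newick, weight_hemiplasies


@dataclass
class PipelineResult:
    pair_table: pd.DataFrame
    thresholds: dict          # direction -> nominal p threshold (or None)
    fdr: dict                 # direction -> FdrResult
    graph: "graphs.nx.Graph"
    partition: graphs.GroupPartition | None
    pair_results: epistat.PairResults


def associate_pairs(results: epistat.PairResults, lam: float = 0.9) -> pd.DataFrame:
    """Extend the pair table with rho, partial correlation and association."""
    df = results.to_frame()
    S = len(results.sites)
    rho_vec = assoc.pseudo_correlations(results.z)
    rho_mat = np.eye(S)
    iu = np.triu_indices(S, k=1)
    rho_mat[iu] = rho_vec
    rho_mat.T[iu] = rho_vec
    partial = assoc.partial_correlations(rho_mat, lam=lam)[iu]
    df["rho"] = rho_vec
    df["partial"] = partial
    df["a"] = assoc.association_statistics(rho_vec, partial)
    return df


def analyze_history(
    history: SubstitutionHistory,
    config: epistat.EpistatConfig,
    lam: float = 0.9,
    detect: bool = True,
) -> PipelineResult:
    results = epistat.analyze_pairs(history, config)
    table = associate_pairs(results, lam=lam)
    fdr = {
        "concordant": results.fdr_threshold("concordant"),
        "discordant": results.fdr_threshold("discordant"),
    }
    thresholds = {d: r.threshold for d, r in fdr.items()}
    graph = graphs.build_coevolution_graph(table, thresholds, p_cap=config.p_cap)
    partition = None
    if detect and graph.number_of_nodes() > 0:
        partition = graphs.detect_groups(graph, seed=config.seed)
    return PipelineResult(
        pair_table=table,
        thresholds=thresholds,
        fdr=fdr,
        graph=graph,
        partition=partition,
        pair_results=results,
    )


def significant_pairs(result: PipelineResult, direction: str, p_cap: float = 0.05) -> pd.DataFrame:
    """Pairs passing min(p_cap, FDR threshold) in the given direction."""
    thr = result.thresholds[direction]
    if thr is None:
        return result.pair_table.iloc[0:0]
    cut = min(p_cap, thr)
    col = "p_upper" if direction == "concordant" else "p_lower"
    return result.pair_table[result.pair_table[col] <= cut]


# ---------------------------------------------------------------------------
# file-based pipeline


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: str, chash: str):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_history(config: dict) -> SubstitutionHistory:
    tree = parse_newick(open(config["tree"]).read())
    history = load_substitutions(config["subs"], tree,
                                 same_branch_pairs=config.get("same_branch_pairs", True))
    thr = config.get("support_threshold")
    if thr is not None:
        history = weight_hemiplasies(history, thr)
    return history


def run_pipeline(config: dict) -> dict:
    """Execute pairs -> associate -> graph -> groups (-> episodic) on files.

    ``config`` holds input paths (tree, subs), an output directory, a
    master seed and per-stage options.  Returns the manifest (stage ->
    output path and checksum); a failing stage raises with its name.
    """
    out = config["out_dir"]
    os.makedirs(out, exist_ok=True)
    chash = _config_hash(config)
    manifest = {"config_hash": chash, "stages": {}}

    def record(stage, path):
        digest = hashlib.sha256(open(path, "rb").read()).hexdigest()[:16]
        manifest["stages"][stage] = {"path": path, "sha256": digest}

    try:
        history = load_history(config)
        ecfg = epistat.EpistatConfig(seed=config.get("seed", 0), **config.get("epistat", {}))
        result = analyze_history(history, ecfg, lam=config.get("lambda", 0.9))
    except Exception as exc:
        raise RuntimeError(f"stage 'pairs' failed: {exc}") from exc

    pairs_path = os.path.join(out, "pairs.tsv")
    _write_tsv(result.pair_table, pairs_path, chash)
    record("pairs", pairs_path)

    thr_path = os.path.join(out, "thresholds.json")
    with open(thr_path, "w") as fh:
        json.dump(
            {
                d: {"threshold": r.threshold, "capped": r.threshold_capped,
                    "n_significant": r.n_significant}
                for d, r in result.fdr.items()
            },
            fh, indent=1,
        )
    record("thresholds", thr_path)

    edges = pd.DataFrame(
        [
            {"site_i": u, "site_j": v, "sign": d["sign"], "weight": d["weight"], "p": d["p"]}
            for u, v, d in result.graph.edges(data=True)
        ],
        columns=["site_i", "site_j", "sign", "weight", "p"],
    )
    graph_path = os.path.join(out, "edges.tsv")
    _write_tsv(edges, graph_path, chash)
    record("graph", graph_path)

    if result.partition is not None:
        groups_path = os.path.join(out, "groups.tsv")
        _write_tsv(result.partition.to_frame(), groups_path, chash)
        record("groups", groups_path)

        if "structure" in config:
            scfg = config["structure"]
            for key in ("pdb", "msa"):
                if key not in scfg or not os.path.exists(scfg[key]):
                    raise RuntimeError(
                        f"stage 'structure' failed: missing or nonexistent {key!r} input"
                    )
            from . import structure as st

            smap = st.map_msa_to_structure(
                scfg["msa"], scfg["reference"], scfg["pdb"], scfg["chain"]
            )
            cg = st.build_contact_graph(smap, cutoff=scfg.get("cutoff", 4.0))
            part = {
                s: g for s, g in result.partition.assignment.items() if s in cg.nodes
            }
            dens = st.contact_density_test(
                part, cg, n_samples=scfg.get("n_samples", 1000),
                seed=config.get("seed", 0),
            )
            dens_path = os.path.join(out, "contact_density.tsv")
            _write_tsv(dens.per_group, dens_path, chash)
            record("structure", dens_path)

        if config.get("episodic", True) and result.partition is not None:
            from . import episodic as epi

            try:
                shifts, tested = epi.detect_rate_shifts(
                    history,
                    result.partition.assignment,
                    alpha=config.get("alpha", 0.05),
                    n_mc=config.get("n_mc", 10000),
                    seed=config.get("seed", 0),
                    return_tested=True,
                )
            except Exception as exc:
                raise RuntimeError(f"stage 'episodic' failed: {exc}") from exc
            shifts_path = os.path.join(out, "shifts.tsv")
            _write_tsv(epi.shifts_to_frame(shifts), shifts_path, chash)
            record("episodic", shifts_path)
            meta_path = os.path.join(out, "episodic_meta.json")
            with open(meta_path, "w") as fh:
                json.dump(
                    {
                        "tested_branches": [history.tree.names[b] for b in tested],
                        "shift_branches": [s.branch_name for s in shifts],
                    },
                    fh,
                )
            record("episodic_meta", meta_path)

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
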