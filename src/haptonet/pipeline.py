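"""End-to-end orchestration: simulate/load -> rarefy -> alpha -> beta ->
drivers -> co-occurrence network -> robustness, as one seeded, logged run.

Every stochastic stage derives its own seed deterministically from the
global seed and the stage name, so re-running any stage from persisted
intermediates reproduces the full-run output.  ``run_pipeline`` returns a
results bundle (plain dict) and, when an output directory is given, writes
every table/graph plus a manifest with provenance (config hash, stage
seeds, package versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta as _beta
from . import diversity as _div
from . import drivers as _drv
from . import network as _net
from . import robustness as _rob
from . import synthetic as _syn
from .io import (
    ENV_VARIABLES,
    ZotuTable,
    read_metadata,
    read_newick,
    read_zotu_table,
    write_distance_matrix,
    write_graph,
    write_json,
    write_metadata,
    write_newick,
    write_zotu_table,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("haptonet")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) ^ global_seed) % (2 ** 31)


@dataclass
class RunConfig:
    """Declarative configuration of one full analysis run."""

    seed: int = 0
    # either a synthetic design ...
    design: _syn.SyntheticDesign | None = None
    # ... or paths to real inputs
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    # rarefaction depth policy: "min" or a fixed integer
    rarefaction: str | int = "min"
    anosim_permutations: int = 999
    mantel_permutations: int = 999
    driver_variables: list[str] = field(default_factory=lambda: list(ENV_VARIABLES))
    lmg_predictors: list[str] = field(
        default_factory=lambda: [
            "temperature", "salinity", "chl_gt20", "chl_2_20", "chl_lt2",
            "HP_abundance", "PPE_abundance", "geographic",
        ]
    )
    taxonomy_rank: int = 3
    min_rel_abund: float = 1e-4
    min_prevalence: float = 0.25
    rho_min: float = 0.6
    network_alpha: float = 0.01
    enrichment_alpha: float = 0.05
    attack_strategies: list[str] = field(
        default_factory=lambda: ["degree", "betweenness", "random"]
    )
    attack_step: int | None = None  # None -> ~50 curve points per subnetwork
    attack_max_fraction: float = 0.8
    attack_repetitions: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "design" in raw and raw["design"] is not None:
            d = raw["design"]
            if "depth_range" in d:
                d["depth_range"] = tuple(d["depth_range"])
            if "layers" in d:
                d["layers"] = tuple(d["layers"])
            if "module_spec" in d:
                d["module_spec"] = [
                    (m[0], list(m[1]), float(m[2])) for m in d["module_spec"]
                ]
            raw["design"] = _syn.SyntheticDesign(**d)
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.design is not None:
        design = config.design
        meta = _syn.generate_metadata(design)
        table, truth = _syn.generate_counts(design, meta)
        tree = _syn.generate_tree(
            design.n_zotus, stage_seed(config.seed, "tree")
        )
        return table, meta, tree, truth
    if config.table_path is None or config.metadata_path is None:
        raise ValueError("config needs either a design or table/metadata paths")
    table = read_zotu_table(config.table_path)
    meta = read_metadata(config.metadata_path)
    tree = read_newick(config.tree_path) if config.tree_path else None
    return table, meta, tree, None


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the full analysis; returns the results bundle.

    Stage order: (simulate|load) -> rarefy -> alpha diversity + habitat
    comparison + alpha-environment correlations -> Bray-Curtis / weighted
    UniFrac + PCoA + ANOSIM -> Mantel table + LMG decomposition +
    taxon-environment screen -> filtered co-occurrence network with
    enrichment classes, modules, topology and habitat subnetworks ->
    attack curves and surface-vs-SCM robustness comparison -> qualitative
    pattern flags.
    """
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"provenance": {
        "config_hash": config.config_hash(),
        "global_seed": config.seed,
        "stage_seeds": {},
    }}

    def seed_of(stage: str) -> int:
        s = stage_seed(config.seed, stage)
        bundle["provenance"]["stage_seeds"][stage] = s
        return s

    table, meta, tree, truth = _load_inputs(config)
    habitats = meta["habitat"]
    log.info("inputs: %d samples x %d ZOTUs", table.n_samples, table.n_zotus)
    if out:
        write_zotu_table(table, out / "zotu_table.tsv")
        write_metadata(meta, out / "metadata.tsv")
        if tree is not None:
            write_newick(tree, out / "tree.nwk")
        if truth is not None:
            write_json(truth.to_json(), out / "ground_truth.json")

    # ---- rarefaction ------------------------------------------------------
    depth = (
        int(table.sample_totals().min())
        if config.rarefaction == "min"
        else int(config.rarefaction)
    )
    rarefied = _div.rarefy(table, depth, seed_of("rarefy"))
    bundle["rarefaction_depth"] = depth
    log.info("rarefied to %d reads per sample", depth)

    # ---- alpha diversity --------------------------------------------------
    alpha = _div.alpha_diversity(rarefied, tree=tree)
    comparisons = _div.compare_alpha(alpha, habitats)
    alpha_env = _div.alpha_env_spearman(alpha, meta, config.driver_variables)
    bundle["alpha"] = alpha
    bundle["alpha_comparisons"] = {
        c.metric: {
            "statistic": c.statistic,
            "p_value": c.p_value,
            "group_medians": c.group_medians,
        }
        for c in comparisons
    }
    bundle["alpha_env"] = alpha_env
    if out:
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", float_format="%.6g")
        alpha_env.to_csv(out / "alpha_env_spearman.tsv", sep="\t",
                         index=False, float_format="%.6g")
        write_json(bundle["alpha_comparisons"], out / "alpha_comparisons.json")

    # ---- beta diversity ---------------------------------------------------
    bc = _beta.bray_curtis(rarefied)
    bundle["bray_curtis"] = bc
    anosim_bc = _beta.anosim(
        bc, habitats.loc[rarefied.sample_ids], config.anosim_permutations,
        seed_of("anosim_bc"),
    )
    pcoa_bc = _beta.pcoa(bc)
    bundle["anosim"] = {"bray_curtis": {
        "R": anosim_bc.R, "p_value": anosim_bc.p_value,
        "n_permutations": anosim_bc.n_permutations,
    }}
    bundle["pcoa"] = {"bray_curtis": pcoa_bc}
    if tree is not None:
        wu = _beta.weighted_unifrac(rarefied, tree, normalized=False)
        anosim_wu = _beta.anosim(
            wu, habitats.loc[rarefied.sample_ids], config.anosim_permutations,
            seed_of("anosim_wu"),
        )
        bundle["weighted_unifrac"] = wu
        bundle["anosim"]["weighted_unifrac"] = {
            "R": anosim_wu.R, "p_value": anosim_wu.p_value,
            "n_permutations": anosim_wu.n_permutations,
        }
        bundle["pcoa"]["weighted_unifrac"] = _beta.pcoa(wu)
    if out:
        write_distance_matrix(bc, out / "bray_curtis.tsv")
        if tree is not None:
            write_distance_matrix(bundle["weighted_unifrac"],
                                  out / "weighted_unifrac.tsv")
        write_json(bundle["anosim"], out / "anosim.json")
        coords = pd.DataFrame(
            pcoa_bc.coordinates,
            index=pcoa_bc.sample_ids,
            columns=[f"PCo{k+1}" for k in range(pcoa_bc.coordinates.shape[1])],
        )
        coords.to_csv(out / "pcoa_bray_curtis.tsv", sep="\t", float_format="%.6g")

    # ---- environmental drivers -------------------------------------------
    env = _drv.env_distances(meta.loc[rarefied.sample_ids],
                             config.driver_variables)
    mantel_rows = []
    mantel_seed = seed_of("mantel")
    for k, var in enumerate(env.matrices):
        res = _drv.mantel(bc, env[var], config.mantel_permutations,
                          (mantel_seed + k) % (2 ** 31))
        mantel_rows.append((var, res.r, res.r_squared, res.p_value))
    mantel_table = pd.DataFrame(
        mantel_rows, columns=["variable", "r", "r_squared", "p"]
    )
    lmg_predictors = [
        v for v in config.lmg_predictors if v in env.matrices
    ]
    lmg = _drv.distance_mlr_lmg(bc, env, predictors=lmg_predictors,
                                seed=seed_of("lmg"))
    taxa_env = _drv.taxa_env_spearman(
        rarefied, config.taxonomy_rank, meta, config.driver_variables
    )
    bundle["mantel"] = mantel_table
    bundle["lmg"] = {
        "total_r_squared": lmg.total_r_squared,
        "contribution": lmg.contribution,
        "cumulative_percent": lmg.cumulative_percent,
    }
    bundle["taxa_env"] = taxa_env
    if out:
        mantel_table.to_csv(out / "mantel.tsv", sep="\t", index=False,
                            float_format="%.6g")
        write_json(bundle["lmg"], out / "lmg.json")
        taxa_env.to_csv(out / "taxa_env_spearman.tsv", sep="\t", index=False,
                        float_format="%.6g")

    # ---- co-occurrence network -------------------------------------------
    filtered = _net.filter_zotus(
        rarefied, config.min_rel_abund, config.min_prevalence
    )
    log.info("network input: %d ZOTUs after filtering", filtered.n_zotus)
    G = _net.network_edges_from_table(
        filtered, config.rho_min, config.network_alpha
    )
    enrichment = _net.classify_enrichment(
        filtered, habitats, config.enrichment_alpha
    )
    bundle["enrichment"] = enrichment
    network_block: dict = {"meta": None, "surface": None, "SCM": None}
    sub_graphs: dict = {}
    if G.number_of_nodes() > 0:
        modules, q_mod = _net.detect_modules(G, seed=seed_of("louvain"))
        nm = _net.node_metrics(G)
        nm["module"] = [modules[n] for n in nm.index]
        nm["enrichment"] = [
            enrichment.loc[n, "enrichment"] if n in enrichment.index else "none"
            for n in nm.index
        ]
        for n in G.nodes():
            G.nodes[n]["module"] = int(modules[n])
            G.nodes[n]["enrichment"] = str(nm.loc[n, "enrichment"])
            G.nodes[n]["degree"] = int(nm.loc[n, "degree"])
        network_block["meta"] = {
            "metrics": _net.network_metrics(G).to_json(),
            "modularity": q_mod,
        }
        bundle["node_metrics"] = nm
        for habitat in ("surface", "SCM"):
            ids = [
                z for z in enrichment.index[enrichment["enrichment"] == habitat]
                if z in G
            ]
            if len(ids) >= 2:
                sub = _net.subnetwork(G, ids)
                sub_graphs[habitat] = sub
                network_block[habitat] = {
                    "n_enriched": int(
                        (enrichment["enrichment"] == habitat).sum()
                    ),
                    "metrics": _net.network_metrics(sub).to_json()
                    if sub.number_of_nodes() else None,
                }
            else:
                network_block[habitat] = {
                    "n_enriched": int(
                        (enrichment["enrichment"] == habitat).sum()
                    ),
                    "metrics": None,
                }
        if out:
            write_graph(G, out / "network.graphml", "graphml")
            write_graph(G, out / "network.gml", "gml")
            nm.to_csv(out / "node_metrics.tsv", sep="\t", float_format="%.6g")
    bundle["network"] = network_block
    bundle["graph"] = G
    if out:
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.6g")
        write_json(network_block, out / "network_metrics.json")

    # ---- robustness -------------------------------------------------------
    attack_block: dict = {}
    attack_seed = seed_of("attack")
    for habitat, sub in sub_graphs.items():
        if sub.number_of_nodes() < 3:
            continue
        attack_block[habitat] = {}
        n_remove = int(config.attack_max_fraction * sub.number_of_nodes())
        step = config.attack_step or max(1, n_remove // 50)
        for strat in config.attack_strategies:
            curve = _rob.attack(
                sub, strat,
                step=step,
                max_fraction=config.attack_max_fraction,
                repetitions=config.attack_repetitions,
                seed=attack_seed,
            )
            attack_block[habitat][strat] = curve
    comparison = None
    if "surface" in attack_block and "SCM" in attack_block:
        strat = "random" if "random" in config.attack_strategies else \
            config.attack_strategies[0]
        comparison = _rob.compare_robustness(
            attack_block["surface"][strat], attack_block["SCM"][strat]
        )
    bundle["attack"] = attack_block
    bundle["robustness_comparison"] = comparison
    if out:
        for habitat, curves in attack_block.items():
            for strat, curve in curves.items():
                rows = curve.as_table()
                cols = ["fraction_removed", "mean_nc"] + (
                    ["sd_nc"] if curve.sd is not None else []
                )
                pd.DataFrame(rows, columns=cols).to_csv(
                    out / f"attack_{habitat}_{strat}.tsv", sep="\t",
                    index=False, float_format="%.6g",
                )

    # ---- qualitative pattern flags ---------------------------------------
    surface_higher = {
        c.metric: (
            c.group_medians.get("surface", np.nan)
            > c.group_medians.get("SCM", np.nan)
            and c.p_value < 0.05
        )
        for c in comparisons
    }
    dens_s = (network_block["surface"] or {}).get("metrics")
    dens_c = (network_block["SCM"] or {}).get("metrics")
    patterns = {
        "surface_alpha_higher": bool(all(surface_higher.values())),
        "habitat_anosim_significant": bool(
            anosim_bc.R > 0 and anosim_bc.p_value < 0.05
        ),
        "surface_subnetwork_denser": bool(
            dens_s and dens_c
            and dens_s["density"] > dens_c["density"]
            and dens_s["average_degree"] > dens_c["average_degree"]
        ),
        "surface_network_more_robust": bool(
            comparison and comparison["fraction_a_above_b"] >= 0.9
        ),
    }
    bundle["patterns"] = patterns
    if out:
        write_json(patterns, out / "patterns.json")
        manifest = {
            "provenance": bundle["provenance"],
            "rarefaction_depth": depth,
            "n_samples": table.n_samples,
            "n_zotus_input": table.n_zotus,
            "n_zotus_network": filtered.n_zotus,
            "n_edges": G.number_of_edges(),
            "patterns": patterns,
        }
        write_json(manifest, out / "manifest.json")
    return bundle
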