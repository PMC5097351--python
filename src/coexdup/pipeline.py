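"""End-to-end pipeline orchestration with a single config and derived seeds.

Stages run in dependency order: simulate -> preprocess -> network ->
[paralogs] -> divergence -> subgenome. One master seed deterministically
derives a per-stage substream (stage-name keyed), so changing one stage's
seed does not perturb the others. A manifest records the config hash, seeds,
thresholds and per-output row counts; a rerun with the same config and seed
is bit-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
import zlib
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cdio
from .expression import ExpressionAtlas, preprocess as preprocess_atlas
from .network import CoexpressionNetwork, build_network, detect_modules_mcl
from .divergence import classify_network_pairs, ds_by_type_summary, type_by_duptype_enrichment
from .simulate import AtlasSpec, PlantedPairSpec, SubgenomeSpec, generate_linked_dataset
from . import subgenome as sg

SCHEMA_VERSION = "1"

DEFAULT_CONFIG: Dict[str, object] = {
    "seed": 0,
    "stages": ["simulate", "preprocess", "network", "divergence", "subgenome"],
    "simulate": {
        "n_tissues": 64,
        "replicates_per_tissue": 2,
        "within_module_corr": 1.0,
        "noise_sd": 0.1,
        "n_pairs": 300,
        "n_maize1": 1100,
        "n_maize2": 800,
        "n_ambiguous": 100,
        "fractionation_rate": 0.3,
        "n_pathways": 20,
        "pathway_size_range": [12, 24],
    },
    "preprocess": {"min_expressed_tissues": 3, "high_tpm": 5.0},
    "network": {"cutoff": 2.5, "block_size": 1024, "inflation": 2.0},
    "divergence": {"radius": 0.1, "min_neighbors": 10},
    "subgenome": {
        "min_edges": 7,
        "min_wgd_pairs": 2,
        "min_labeled": 20,
        "alpha": 0.05,
        "n_perm": 1000,
    },
    "inputs": {
        "expression": None,
        "replicate_map": None,
        "pairs": None,
        "subgenome_map": None,
        "homeologs": None,
        "pathways": None,
    },
}


class PipelineError(RuntimeError):
    pass


def load_config(path: Optional[str] = None) -> Dict[str, object]:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: Dict[str, object]) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _rows(path: str) -> int:
    header = 1 if path.endswith(".tsv") else 0
    with open(path) as fh:
        return max(sum(1 for _ in fh) - header, 0)


def run_pipeline(cfg: Dict[str, object], outdir: str) -> Dict[str, object]:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cdio.ensure_dir(outdir)
    stages: List[str] = list(cfg["stages"])
    seed = int(cfg["seed"])
    manifest: Dict[str, object] = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": stages,
        "outputs": {},
        "stats": {},
    }
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "replicate_map": os.path.join(outdir, "replicate_map.tsv"),
        "pairs": os.path.join(outdir, "pairs.tsv"),
        "subgenome_map": os.path.join(outdir, "subgenome_map.tsv"),
        "homeologs": os.path.join(outdir, "homeologs.tsv"),
        "pathways": os.path.join(outdir, "pathways.gmt"),
        "modules_truth": os.path.join(outdir, "modules_truth.tsv"),
        "expression_processed": os.path.join(outdir, "expression_processed.tsv"),
        "edges": os.path.join(outdir, "edges.tsv"),
        "modules": os.path.join(outdir, "modules.tsv"),
        "divergence": os.path.join(outdir, "divergence.tsv"),
        "enrichment": os.path.join(outdir, "enrichment.tsv"),
        "ds_summary": os.path.join(outdir, "ds_summary.tsv"),
        "fractionation": os.path.join(outdir, "fractionation.tsv"),
        "pathway_tests": os.path.join(outdir, "pathway_tests.tsv"),
        "module_enrichment": os.path.join(outdir, "module_enrichment.tsv"),
        "hubs": os.path.join(outdir, "hubs.tsv"),
    }
    inputs = dict(cfg.get("inputs") or {})

    def _input(name: str) -> str:
        if inputs.get(name):
            return str(inputs[name])
        path = paths[name]
        if os.path.exists(path):
            return path
        raise PipelineError(
            f"missing upstream output {name!r}; enable the stage that produces it"
        )

    if "simulate" in stages:
        sim = dict(cfg["simulate"])
        sim_seed = stage_seed(seed, "simulate")
        n_genes = int(sim["n_maize1"]) + int(sim["n_maize2"]) + int(sim.get("n_ambiguous", 0))
        atlas_spec = AtlasSpec(
            n_genes=n_genes,
            n_tissues=int(sim["n_tissues"]),
            replicates_per_tissue=int(sim["replicates_per_tissue"]),
            within_module_corr=float(sim["within_module_corr"]),
            noise_sd=float(sim["noise_sd"]),
            seed=sim_seed,
        )
        pair_spec = PlantedPairSpec(n_pairs=int(sim["n_pairs"]))
        sub_spec = SubgenomeSpec(
            n_maize1=int(sim["n_maize1"]),
            n_maize2=int(sim["n_maize2"]),
            fractionation_rate=float(sim["fractionation_rate"]),
            n_pathways=int(sim["n_pathways"]),
            pathway_size_range=tuple(sim["pathway_size_range"]),
            n_ambiguous=int(sim.get("n_ambiguous", 0)),
            seed=sim_seed + 1,
        )
        data = generate_linked_dataset(atlas_spec, pair_spec, sub_spec)
        data["atlas"].write(paths["expression"], paths["replicate_map"])
        cdio.write_pair_table(data["pairs"], paths["pairs"])
        cdio.write_subgenome_map(data["map"], paths["subgenome_map"])
        data["homeologs"].to_csv(paths["homeologs"], sep="\t", index=False)
        cdio.write_gmt(data["pathways"], paths["pathways"])
        cdio.write_module_table(
            {g: int(m) for g, m in data["module_labels"].items()}, paths["modules_truth"]
        )

    if "preprocess" in stages:
        atlas = ExpressionAtlas.from_files(_input("expression"), _input("replicate_map"))
        pre = dict(cfg["preprocess"])
        processed, removed = preprocess_atlas(
            atlas, int(pre["min_expressed_tissues"]), float(pre["high_tpm"])
        )
        cdio.write_expression_tsv(processed.values, paths["expression_processed"])
        manifest["stats"]["genes_removed_by_filter"] = len(removed)

    network: Optional[CoexpressionNetwork] = None
    if "network" in stages:
        net_cfg = dict(cfg["network"])
        if not os.path.exists(paths["expression_processed"]):
            raise PipelineError("network stage requires the preprocess stage output")
        processed = ExpressionAtlas.from_files(paths["expression_processed"])
        network = build_network(
            processed, cutoff=float(net_cfg["cutoff"]), block_size=int(net_cfg["block_size"])
        )
        network.write_edges(paths["edges"])
        modules = detect_modules_mcl(network, inflation=float(net_cfg["inflation"]))
        cdio.write_module_table(modules.assignment, paths["modules"])
        manifest["stats"]["n_edges"] = len(network.edges)
        manifest["stats"]["n_modules_ge10"] = len(modules.large_modules(10))
        manifest["stats"]["fisher_sd"] = round(network.fisher_sd, 10)

    if "divergence" in stages:
        if network is None:
            raise PipelineError("divergence stage requires the network stage")
        div_cfg = dict(cfg["divergence"])
        pairs = cdio.read_pair_table(_input("pairs"))
        records = classify_network_pairs(
            network,
            pairs,
            radius=float(div_cfg["radius"]),
            min_neighbors=int(div_cfg["min_neighbors"]),
        )
        records.to_csv(paths["divergence"], sep="\t", index=False)
        enrich = type_by_duptype_enrichment(records)
        enrich.to_csv(paths["enrichment"], sep="\t", index=False)
        summary = ds_by_type_summary(records)
        summary["per_type"].to_csv(paths["ds_summary"], sep="\t", index=False)
        manifest["stats"]["type_counts"] = records["type"].value_counts().to_dict()
        manifest["stats"]["ds_rank_sum_p"] = summary["rank_sum_p"]

    if "subgenome" in stages:
        if network is None:
            raise PipelineError("subgenome stage requires the network stage")
        sub_cfg = dict(cfg["subgenome"])
        sub_seed = stage_seed(seed, "subgenome")
        smap = cdio.read_subgenome_map(_input("subgenome_map"))
        pathways = cdio.read_gmt(_input("pathways"))
        pairs = cdio.read_pair_table(_input("pairs"))
        homeologs = pd.read_csv(_input("homeologs"), sep="\t")

        frac_rows = []
        retained = homeologs[homeologs["status"] == "retained"]
        retained_genes = sorted(set(retained["gene1"]) | set(retained["gene2"]))
        lost_m1 = homeologs[homeologs["status"] == "lost"]["gene1"].tolist()
        lost_side = sorted(
            set(lost_m1)
            | set(smap[(smap["subgenome"] == "maize2") & (smap["block_id"] == ".")]["gene_id"])
        )
        for name, subset in (("retained_pairs", retained_genes), ("fractionated", lost_side)):
            try:
                frac = sg.count_subgenome_edges(network, smap, subset)
            except ValueError:
                continue
            perm = sg.permute_edge_null(
                frac.n_maize1,
                frac.n_maize2,
                frac.total_edges,
                frac.inter,
                n_perm=int(sub_cfg["n_perm"]),
                seed=sub_seed,
            )
            try:
                chi_stat, chi_p = sg.contingency_edge_test(frac)
            except ValueError:
                chi_stat, chi_p = float("nan"), float("nan")
            d1, d2, di = frac.densities
            frac_rows.append(
                (name, frac.n_maize1, frac.n_maize2, frac.m1_intra, frac.m2_intra,
                 frac.inter, d1, d2, di, perm["p_value"], chi_stat, chi_p)
            )
        pd.DataFrame(
            frac_rows,
            columns=["subset", "n_maize1", "n_maize2", "m1_intra", "m2_intra", "inter",
                     "density_m1", "density_m2", "density_inter", "perm_p", "chi2", "chi2_p"],
        ).to_csv(paths["fractionation"], sep="\t", index=False)

        # pathway filter uses every retained recent-WGD pair, not only the
        # pairs sampled into the duplicate table
        wgd_table = retained.rename(columns={"status": "dup_type"}).assign(dup_type="WGD")
        try:
            per_pathway, tests = sg.pathway_fractionation(
                network, smap, pathways, pairs=wgd_table,
                min_edges=int(sub_cfg["min_edges"]),
                min_wgd_pairs=int(sub_cfg["min_wgd_pairs"]),
            )
            per_pathway.to_csv(paths["pathway_tests"], sep="\t", index=False)
            manifest["stats"]["pathway_tests"] = {k: list(v) for k, v in tests.items()}
            manifest["stats"]["n_pathways_tested"] = len(per_pathway)
        except ValueError as exc:
            manifest["stats"]["pathway_tests"] = f"skipped: {exc}"

        modules = cdio.read_module_table(paths["modules"]) if os.path.exists(paths["modules"]) else None
        if modules is not None:
            from .network import ModuleAssignment

            assign = ModuleAssignment(
                assignment={g: int(m) for g, m in modules.items()}, n_iterations=0
            )
            enr = sg.module_subgenome_enrichment(assign, smap, min_labeled=int(sub_cfg["min_labeled"]))
            enr.to_csv(paths["module_enrichment"], sep="\t", index=False)
            manifest["stats"]["n_modules_tested"] = len(enr)

        hubs = sg.detect_hub_genes(
            network,
            n_perm=int(sub_cfg["n_perm"]),
            alpha=float(sub_cfg["alpha"]),
            seed=stage_seed(seed, "hubs"),
        )
        hub_df = pd.DataFrame(
            {"gene_id": hubs.degrees.index, "degree": hubs.degrees.values, "is_hub": hubs.hub_flags.values}
        )
        hub_df.to_csv(paths["hubs"], sep="\t", index=False)
        manifest["stats"]["hub_cutoff"] = hubs.cutoff
        manifest["stats"]["n_hubs"] = int(hubs.hub_flags.sum())
        try:
            bias_stat, bias_p = sg.hub_subgenome_bias(hubs, smap)
            manifest["stats"]["hub_bias_chi2"] = round(bias_stat, 10)
            manifest["stats"]["hub_bias_p"] = round(bias_p, 10)
        except ValueError:
            manifest["stats"]["hub_bias_chi2"] = None

    manifest["outputs"] = {
        name: _rows(path) for name, path in paths.items() if os.path.exists(path)
    }
    manifest["thresholds"] = {
        "z_cutoff": cfg["network"]["cutoff"],
        "radius": cfg["divergence"]["radius"],
        "min_neighbors": cfg["divergence"]["min_neighbors"],
        "min_edges": cfg["subgenome"]["min_edges"],
        "min_labeled": cfg["subgenome"]["min_labeled"],
        "alpha": cfg["subgenome"]["alpha"],
        "n_perm": cfg["subgenome"]["n_perm"],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return manifest
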