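"""End-to-end orchestration: structures -> CIGs -> mining -> counting -> analyses.

A single structured config (YAML mapping) drives the run; one global seed is
fanned out to per-stage integer streams, and a machine-readable manifest
records versions, the config hash, per-stage record counts and skipped
stages. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from . import io as cio
from .enrichment import classify_communities, enrich_clusters
from .errors import ConfigurationError
from .graphs import build_cigs, contract
from .isomorphism import count_variants
from .mining import FrequentClusterMiner
from .simulate import (
    PlantedCluster,
    SimulationConfig,
    SubstateSpec,
    generate_population,
    generate_signals,
)
from .spatial import compute_cluster_geometry, domain_occurrence_profile
from .substates import build_occurrence_matrix, filter_prevalent, nmf_bicluster

log = logging.getLogger("cigmine")

_STAGE_SEEDS = {"simulate": 1, "mine": 2, "enrich": 3, "analyze": 4, "substates": 5}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    # keep derived seeds below 2**31 for portability
    return (int(global_seed) * 1000 + _STAGE_SEEDS[stage]) % (2**31)


def simulation_config_from_dict(entries: dict, seed: int) -> SimulationConfig:
    planted = [
        PlantedCluster(
            members=tuple((int(a), int(b)) for a, b in pc["members"]),
            frequency=float(pc.get("frequency", 0.06)),
            contact_probability=float(pc.get("contact_probability", 0.9)),
            epsilon=float(pc.get("epsilon", 0.05)),
            cross_copy=tuple(
                (int(a), int(b)) for a, b in pc.get("cross_copy", [])
            ),
        )
        for pc in entries.get("planted_clusters", [])
    ]
    substates = None
    if "substates" in entries:
        substates = [
            SubstateSpec(float(s["fraction"]), tuple(int(i) for i in s["clusters"]))
            for s in entries["substates"]
        ]
    return SimulationConfig(
        n_chrom=int(entries.get("n_chrom", 3)),
        domains_per_chrom=int(entries.get("domains_per_chrom", 20)),
        radius=float(entries.get("radius", 0.03)),
        K=int(entries.get("K", 500)),
        planted_clusters=planted,
        substates=substates,
        background_occurrence=float(entries.get("background_occurrence", 0.02)),
        factors=tuple(entries.get("factors", ("TF1", "TF2", "TF3", "TF4"))),
        enrichments=[
            (str(f), int(c), float(d)) for f, c, d in entries.get("enrichments", [])
        ],
        centromere_bias=bool(entries.get("centromere_bias", False)),
        seed=seed,
    )


def run_pipeline(config: dict, base_dir=".") -> dict:
    """Execute the full pipeline per the config mapping; returns the manifest.

    Stages: load/simulate inputs -> build CIGs -> contract -> mine -> count
    variants -> (optional) enrichment -> spatial analyses -> substates. A
    missing signal matrix skips the enrichment stage with a manifest note.
    """
    if "seed" not in config:
        raise ConfigurationError("config must set a global seed")
    seed = int(config["seed"])
    base = Path(base_dir)
    outdir = base / config.get("output_dir", "results")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cigmine_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in _STAGE_SEEDS},
        "records": {},
        "skipped": [],
        "outputs": {},
    }

    # ---- inputs -----------------------------------------------------------
    signals = None
    if "simulate" in config:
        sim_cfg = simulation_config_from_dict(
            config["simulate"], stage_seed(seed, "simulate")
        )
        population, domains, gt = generate_population(sim_cfg)
        if sim_cfg.enrichments or config["simulate"].get("write_signals", True):
            signals = generate_signals(domains, gt, sim_cfg)
        cio.write_domain_table(domains, outdir / "domains.tsv")
        cio.write_structure_population(population, domains, outdir / "structures.tsv")
        if signals is not None:
            cio.write_signal_matrix(signals, outdir / "signals.tsv")
        manifest["records"]["simulate"] = {
            "structures": population.K,
            "domains": domains.n,
            "planted_clusters": len(sim_cfg.planted_clusters),
        }
    else:
        inputs = config.get("inputs", {})
        if "domains" not in inputs or "structures" not in inputs:
            raise ConfigurationError("config.inputs needs 'domains' and 'structures'")
        domains = cio.read_domain_table(base / inputs["domains"])
        population = cio.read_structure_population(base / inputs["structures"], domains)
        if "signals" in inputs:
            signals = cio.read_signal_matrix(base / inputs["signals"], domains)
        manifest["records"]["inputs"] = {
            "structures": population.K,
            "domains": domains.n,
        }
    log.info("inputs: %d structures x %d domains", population.K, domains.n)

    # ---- graphs -----------------------------------------------------------
    contact_scale = float(config.get("contact_scale", 1.0))
    cigs = build_cigs(population, domains, contact_scale)
    ccigs = [contract(g) for g in cigs]
    manifest["records"]["graphs"] = {
        "cigs": len(cigs),
        "mean_cig_edges": float(np.mean([g.adj.sum() / 2 for g in cigs])),
    }
    log.info("built %d CIGs", len(cigs))

    # ---- mining -----------------------------------------------------------
    mcfg = dict(config.get("mining", {}))
    miner = FrequentClusterMiner(seed=stage_seed(seed, "mine"), **mcfg)
    miner.fit([g.adj for g in ccigs])
    manifest["records"]["mine"] = {"candidates": len(miner.patterns_)}
    log.info("mined %d candidate patterns", len(miner.patterns_))

    # ---- coupled-isomorphism counting --------------------------------------
    params = miner._params()
    clusters = count_variants(
        miner.patterns_, cigs, domains, params.min_density, params.min_freq
    )
    cluster_path = outdir / "clusters.json"
    cio.write_clusters(
        clusters,
        cluster_path,
        population.K,
        params={
            "min_size": params.min_size,
            "min_density": params.min_density,
            "min_freq": params.min_freq,
            "contact_scale": contact_scale,
            "seed": seed,
        },
    )
    cio.write_cluster_summary(clusters, outdir / "clusters.tsv")
    manifest["records"]["count"] = {"clusters": len(clusters)}
    manifest["outputs"]["clusters"] = cluster_path.name
    log.info("counted %d frequent clusters", len(clusters))

    # ---- enrichment --------------------------------------------------------
    enrichment = None
    ecfg = config.get("enrichment", {})
    if signals is None:
        manifest["skipped"].append("enrichment: no signal matrix provided")
    elif not clusters:
        manifest["skipped"].append("enrichment: no clusters to test")
    else:
        enrichment = enrich_clusters(
            clusters,
            signals,
            domains,
            B=int(ecfg.get("B", 10_000)),
            alpha=float(ecfg.get("alpha", 0.05)),
            seed=stage_seed(seed, "enrich"),
        )
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        communities = classify_communities(
            enrichment, clusters, dict(ecfg.get("factor_labels", {}))
        )
        communities.to_csv(outdir / "communities.tsv", sep="\t", index=False)
        manifest["records"]["enrich"] = {
            "tests": len(enrichment),
            "communities": int(communities["is_community"].sum()),
        }

    # ---- spatial analyses ---------------------------------------------------
    if clusters:
        geometry = compute_cluster_geometry(
            clusters, population, cigs, domains, params.min_density
        )
        geometry.to_csv(outdir / "geometry.tsv", sep="\t", index=False)
        counts, trend = domain_occurrence_profile(clusters, domains)
        trend.to_csv(outdir / "occurrence_trend.tsv", sep="\t", index=False)
        manifest["records"]["analyze"] = {"clusters": len(geometry)}
    else:
        manifest["skipped"].append("analyze: no clusters")

    # ---- substates -----------------------------------------------------------
    scfg = config.get("substates", {})
    inter = [c for c in clusters if c.is_inter_chromosomal]
    if len(inter) < 2:
        manifest["skipped"].append("substates: fewer than 2 inter-chromosomal clusters")
    else:
        C, ids = build_occurrence_matrix(inter, population.K)
        try:
            C, ids, dropped = filter_prevalent(
                C, ids, float(scfg.get("prevalent_fraction", 0.10))
            )
        except Exception as exc:  # all rows prevalent
            manifest["skipped"].append(f"substates: {exc}")
            C = None
        if C is not None and C.shape[0] >= 2:
            assignment = nmf_bicluster(
                C,
                k=int(scfg.get("k", 8)),
                seed=stage_seed(seed, "substates"),
                restarts=int(scfg.get("restarts", 10)),
            )
            with open(outdir / "substates.tsv", "w") as fh:
                fh.write("structure_id\tsubstate\n")
                for sid, lab in zip(population.structure_ids, assignment.structure_labels):
                    fh.write(f"{sid}\t{lab}\n")
            manifest["records"]["substates"] = {
                "clusters_used": C.shape[0],
                "dropped_prevalent": len(dropped),
                "substates": int(assignment.k),
            }

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
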