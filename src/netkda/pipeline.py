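"""End-to-end orchestration: simulate/load -> DE -> overlap -> KDA -> modules.

Stages mirror the study's analysis order: differential-expression
signatures across the six genotype contrasts, direction-aware signature
overlap, layered key-driver analysis on the (union) causal network, and
co-expression module enrichment. Every output table carries the seed and
a configuration hash in a ``#`` header line, and a machine-readable
manifest records what ran.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import (
    DEFAULT_CONTRASTS,
    call_signature,
    contrast_table,
    filter_expressed,
    fit_moderated_model,
    log_cpm,
    tmm_factors,
)
from .io import (
    load_counts,
    load_network,
    signatures_to_gmt,
    write_counts,
    write_gmt,
    write_network,
    write_table,
)
from .keydriver import downstream_layers, layer_enrichment, rank_key_drivers, union_network
from .modules import detect_modules, module_enrichment, topological_overlap, correlation_adjacency
from .overlap import SignatureCollection, overlap_matrix
from .simulate import (
    SimulationConfig,
    simulate_causal_network,
    simulate_coexpression,
    simulate_counts,
)
from .stats import StatsConfig

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, thresholds, and simulation settings for one pipeline run.

    With no count/metadata paths the synthetic generator supplies the
    data; with no network paths the synthetic causal network is used when
    ``simulate_network`` is set, otherwise the KDA stage is skipped.
    """

    outdir: str = "netkda_out"
    seed: int = 0
    counts_path: Optional[str] = None
    metadata_path: Optional[str] = None
    network_paths: tuple[str, ...] = ()
    network_dialect: str = "edge_tsv"
    simulate_network: bool = True
    simulate_modules: bool = True
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    kda_signature: str = "APP_PSEN1_ko_vs_APP_PSEN1_DN"
    kda_seed_gene: Optional[str] = None
    max_depth: int = 4
    cumulative_layers: bool = False
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stats" in raw:
            raw["stats"] = StatsConfig(**raw["stats"])
        sim = raw.get("simulation", {})
        sim.setdefault("seed", raw.get("seed", 0))
        raw["simulation"] = SimulationConfig(**sim)
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "network_paths" in raw:
            raw["network_paths"] = tuple(raw["network_paths"])
        return cls(**raw)

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where it is written
        payload = asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Reruns with the same config are bit-identical: all randomness flows
    from ``config.seed`` through the synthetic generators.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"netkda {__version__} seed={config.seed} config={config.config_hash()}"
    manifest: dict = {
        "tool": "netkda",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": asdict(config),
        "stages": {},
    }

    # -- stage 1: data ------------------------------------------------
    stage = "data"
    try:
        sim_cfg = config.simulation
        if config.counts_path and config.metadata_path:
            cm = load_counts(config.counts_path, config.metadata_path)
            truth = None
        else:
            sim_cfg = (
                sim_cfg
                if sim_cfg.seed == config.seed
                else SimulationConfig(**{**asdict(sim_cfg), "seed": config.seed})
            )
            cm, truth = simulate_counts(sim_cfg)
            write_counts(cm, out / "counts.tsv", out / "metadata.tsv", header)
            with open(out / "truth_counts.json", "w") as fh:
                json.dump(
                    {
                        "planted_up_in_APP": sorted(truth.planted_up_in_APP),
                        "reverted_by_ko": sorted(truth.reverted_by_ko),
                    },
                    fh,
                    indent=1,
                )
        manifest["stages"][stage] = {
            "status": "ok",
            "n_genes": cm.n_genes,
            "n_samples": cm.n_samples,
            "simulated": truth is not None,
        }
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        raise StageError(stage, exc) from exc

    # -- stage 2: differential expression -----------------------------
    stage = "de"
    try:
        expressed = filter_expressed(cm)
        norm = tmm_factors(expressed)
        logexpr = log_cpm(expressed, norm)
        fit = fit_moderated_model(logexpr, expressed.genotype)
        signatures = []
        deg_counts = {}
        for test, base in config.contrasts:
            table = contrast_table(fit, (test, base))
            write_table(table, out / f"de_{test}_vs_{base}.tsv", header)
            sig = call_signature(table, config.stats.fdr_threshold)
            signatures.append(sig)
            deg_counts[sig.contrast] = {"up": len(sig.up), "down": len(sig.down)}
        gmt = signatures_to_gmt(signatures)
        write_gmt(gmt, out / "signatures.gmt")
        universe = frozenset(expressed.gene_ids)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_expressed": expressed.n_genes,
            "deg_counts": deg_counts,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage 3: signature overlap ------------------------------------
    stage = "overlap"
    try:
        collection = SignatureCollection(
            signatures=dict(gmt), universe=universe, species_tag="mouse"
        )
        pairs = [
            (a, b)
            for a, b in combinations(collection.names(), 2)
            if a.rsplit("_", 1)[0] != b.rsplit("_", 1)[0]
        ]
        overlaps = overlap_matrix(collection, pairs)
        write_table(overlaps, out / "signature_overlaps.tsv", header)
        manifest["stages"][stage] = {"status": "ok", "n_pairs": len(overlaps)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage 4: key-driver analysis ----------------------------------
    stage = "kda"
    try:
        nets = []
        if config.network_paths:
            nets = [
                load_network(p, config.network_dialect) for p in config.network_paths
            ]
        elif config.simulate_network:
            net, net_truth = simulate_causal_network(sim_cfg)
            write_network(net, out / "network.tsv", header)
            nets = [net]
        if not nets:
            manifest["stages"][stage] = {"status": "skipped", "reason": "no networks"}
        else:
            net = union_network(nets) if len(nets) > 1 else nets[0]
            kda_sig = gmt.get(config.kda_signature, frozenset())
            net_universe = net.nodes & universe
            ranking = rank_key_drivers(
                net, kda_sig & net_universe, net_universe, config.max_depth
            )
            write_table(ranking, out / "driver_ranking.tsv", header)
            seed_gene = config.kda_seed_gene or str(ranking.iloc[0]["driver"])
            nbhd = downstream_layers(net, seed_gene, config.max_depth)
            per_layer = layer_enrichment(
                nbhd, kda_sig & net_universe, net_universe, config.cumulative_layers
            )
            layer_df = pd.DataFrame(
                {
                    "layer": range(1, len(per_layer) + 1),
                    "layer_size": [r.set1_size for r in per_layer],
                    "overlap": [r.overlap for r in per_layer],
                    "fold_enrichment": [r.fold_enrichment for r in per_layer],
                    "p": [r.p_value for r in per_layer],
                }
            )
            write_table(layer_df, out / f"layers_{seed_gene}.tsv", header)
            write_gmt(
                {f"{seed_gene}_L{i + 1}": layer for i, layer in enumerate(nbhd.layers)},
                out / "neighborhood.gmt",
            )
            manifest["stages"][stage] = {
                "status": "ok",
                "seed_gene": seed_gene,
                "top_driver": str(ranking.iloc[0]["driver"]),
                "n_candidates": len(ranking),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage 5: co-expression modules --------------------------------
    stage = "modules"
    try:
        if not config.simulate_modules:
            manifest["stages"][stage] = {"status": "skipped", "reason": "disabled"}
        else:
            expr, mod_truth = simulate_coexpression(sim_cfg)
            tom = topological_overlap(correlation_adjacency(expr))
            partition = detect_modules(tom)
            mod_sig = gmt.get(config.kda_signature, frozenset())
            mod_universe = frozenset(expr.index)
            enr = module_enrichment(partition, mod_sig & mod_universe, mod_universe)
            write_table(enr, out / "module_enrichment.tsv", header)
            part_df = pd.DataFrame(
                sorted(partition.labels.items()), columns=["gene", "module"]
            )
            write_table(part_df, out / "module_partition.tsv", header)
            manifest["stages"][stage] = {
                "status": "ok",
                "n_modules": len(partition.modules()),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage 6: report ----------------------------------------------
    stage = "report"
    manifest["stages"][stage] = {"status": "ok"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
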