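"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the study's data-generating structure:

* ``simulate_counts`` — negative-binomial bulk RNA-seq counts for the
  six-genotype, 24-sample cross (4/3/4/4/4/5 animals per group) with a
  planted gene module upregulated by the amyloid genotype and largely
  reverted by knockout of the driver gene (gene-dose intermediate in
  heterozygotes).
* ``simulate_causal_network`` — a directed acyclic causal network in
  which the planted module concentrates in the first few layers
  downstream of a designated driver node.
* ``simulate_coexpression`` — latent-factor expression whose first
  module is drawn from the planted gene set.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .de import GENOTYPES, CountMatrix
from .keydriver import CausalNetwork
from .modules import UNASSIGNED, ModulePartition

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_counts",
    "simulate_causal_network",
    "simulate_coexpression",
]

_DEFAULT_GROUP_SIZES = {
    "WT": 4,
    "Tyrobp_het": 3,
    "Tyrobp_ko": 4,
    "APP_PSEN1": 4,
    "APP_PSEN1_het": 4,
    "APP_PSEN1_ko": 5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Count model: ``n_genes`` genes, log-normal baseline abundances,
    negative-binomial noise at ``nb_dispersion``, library sizes uniform in
    ``library_size_range``. A module of ``planted_module_size`` genes is
    shifted by ``planted_log2fc`` in amyloid (APP_PSEN1*) genotypes;
    driver knockout removes ``reversal_fraction`` of the shift and
    heterozygotes remove ``het_effect_fraction`` of that reversal
    (set ``het_effect_fraction = 0`` for the silent-het preset).

    Network model: ``n_network_nodes`` genes plus a driver node whose
    downstream layers have the configured sizes and carry
    ``layer_planted_fraction`` planted genes each; background genes form a
    random DAG that is unreachable from the driver.
    """

    n_genes: int = 5000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_SIZES)
    )
    planted_module_size: int = 100
    planted_log2fc: float = 2.0
    reversal_fraction: float = 0.8
    het_effect_fraction: float = 0.5
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (8e6, 12e6)
    seed: int = 0
    # causal-network generator
    n_network_nodes: int = 1000
    layer_sizes: tuple[int, ...] = (25, 50, 100, 200)
    layer_planted_fraction: float = 0.25
    background_out_degree: float = 2.0
    driver_name: str = "DRIVER"
    # co-expression generator
    coexpr_n_genes: int = 500
    coexpr_n_modules: int = 5
    coexpr_module_size: int = 60
    coexpr_n_samples: int = 60
    coexpr_loading: float = 0.8

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples, got {n}")
        for name in ("reversal_fraction", "het_effect_fraction", "layer_planted_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module larger than the gene universe")
        needed = sum(round(s * self.layer_planted_fraction) for s in self.layer_sizes)
        if needed > self.planted_module_size:
            raise ValueError(
                f"layer seeding needs {needed} planted genes but the module has "
                f"{self.planted_module_size}"
            )
        if 1 + sum(self.layer_sizes) > self.n_network_nodes:
            raise ValueError("layers do not fit inside n_network_nodes")
        if self.n_network_nodes - 1 > self.n_genes:
            raise ValueError(
                "network gene nodes exceed the gene universe "
                f"({self.n_network_nodes - 1} > {self.n_genes})"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: DE genes, effects, driver, and layer memberships."""

    planted_up_in_APP: frozenset[str]
    reverted_by_ko: frozenset[str]
    true_log2fc: Optional[pd.DataFrame] = None  # genes x genotypes, vs WT baseline
    planted_driver: Optional[str] = None
    planted_layers: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if not self.reverted_by_ko <= self.planted_up_in_APP:
            raise ValueError("reverted genes must be a subset of the planted module")
        seen: set[str] = set()
        for layer in self.planted_layers:
            if layer & seen:
                raise ValueError("planted layers must be disjoint")
            seen |= layer


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def _planted_set(config: SimulationConfig) -> np.ndarray:
    """Indices of the planted module; shared across generators for one seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    return rng.choice(config.n_genes, size=config.planted_module_size, replace=False)


def _genotype_shift(config: SimulationConfig) -> dict[str, float]:
    """True log2 shift of planted genes in each genotype, relative to WT."""
    full = config.planted_log2fc
    rev = config.reversal_fraction
    het = config.het_effect_fraction
    return {
        "WT": 0.0,
        "Tyrobp_het": 0.0,
        "Tyrobp_ko": 0.0,
        "APP_PSEN1": full,
        "APP_PSEN1_het": full * (1.0 - rev * het),
        "APP_PSEN1_ko": full * (1.0 - rev),
    }


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial counts for the six-genotype design with a planted module."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = _gene_ids(config.n_genes)
    planted_idx = _planted_set(config)
    planted = frozenset(genes[i] for i in planted_idx)

    # log-normal relative abundances, heavy-tailed like real transcriptomes
    weights = rng.lognormal(mean=0.0, sigma=1.8, size=config.n_genes)
    rel = weights / weights.sum()

    shifts = _genotype_shift(config)
    order = [g for g in GENOTYPES if g in config.group_sizes] + [
        g for g in config.group_sizes if g not in GENOTYPES
    ]
    sample_ids: list[str] = []
    genotype: list[str] = []
    for g in order:
        for i in range(config.group_sizes[g]):
            sample_ids.append(f"{g}_{i + 1}")
            genotype.append(g)
    n_samples = len(sample_ids)
    lo, hi = config.library_size_range
    lib = rng.uniform(lo, hi, size=n_samples)

    effect = np.zeros((config.n_genes, n_samples))
    for j, g in enumerate(genotype):
        effect[planted_idx, j] = shifts[g]
    mu = rel[:, None] * lib[None, :] * (2.0 ** effect)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    true_lfc = pd.DataFrame(0.0, index=genes, columns=list(shifts))
    for g, s in shifts.items():
        true_lfc.loc[list(planted), g] = s
    truth = SyntheticTruth(
        planted_up_in_APP=planted,
        reverted_by_ko=planted if config.reversal_fraction > 0 else frozenset(),
        true_log2fc=true_lfc,
    )
    cm = CountMatrix(
        counts=counts,
        gene_ids=tuple(genes),
        sample_ids=tuple(sample_ids),
        genotype=tuple(genotype),
    )
    return cm, truth


def simulate_causal_network(
    config: SimulationConfig,
) -> tuple[CausalNetwork, SyntheticTruth]:
    """Random DAG with a driver whose downstream layers carry planted genes.

    Layer i nodes receive 1-2 parents from layer i-1 (layer 1 hangs off
    the driver), so the shortest-distance layers below the driver are
    exactly the constructed ones. Background genes form a sparse random
    DAG among themselves and are unreachable from the driver.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = np.array(_gene_ids(config.n_genes), dtype=object)
    planted_idx = _planted_set(config)
    planted_pool = list(genes[planted_idx])
    rng.shuffle(planted_pool)
    other_pool = list(genes[np.setdiff1d(np.arange(config.n_genes), planted_idx)])
    rng.shuffle(other_pool)

    layers: list[list[str]] = []
    for size in config.layer_sizes:
        n_planted = round(size * config.layer_planted_fraction)
        members = [planted_pool.pop() for _ in range(n_planted)]
        members += [other_pool.pop() for _ in range(size - n_planted)]
        rng.shuffle(members)
        layers.append(members)

    n_background = config.n_network_nodes - 1 - sum(config.layer_sizes)
    background_pool = planted_pool + other_pool
    rng.shuffle(background_pool)
    background = [background_pool.pop() for _ in range(n_background)]

    driver = config.driver_name
    edges: list[tuple[str, str]] = [(driver, node) for node in layers[0]]
    for i in range(1, len(layers)):
        prev = layers[i - 1]
        for node in layers[i]:
            n_par = int(rng.integers(1, 3))
            for p in rng.choice(len(prev), size=min(n_par, len(prev)), replace=False):
                edges.append((prev[p], node))
    # sparse random DAG over background: edges only go forward in index order
    p_edge = min(1.0, config.background_out_degree / max(1, n_background - 1))
    for i in range(n_background):
        later = n_background - i - 1
        if later == 0:
            continue
        n_out = rng.binomial(later, p_edge)
        if n_out:
            for j in rng.choice(later, size=n_out, replace=False):
                edges.append((background[i], background[i + 1 + j]))

    net = CausalNetwork.from_edges(
        edges, name="synthetic", nodes=[driver] + background
    )
    truth = SyntheticTruth(
        planted_up_in_APP=frozenset(genes[planted_idx]),
        reverted_by_ko=frozenset(genes[planted_idx]),
        planted_driver=driver,
        planted_layers=tuple(frozenset(l) for l in layers),
    )
    return net, truth


def simulate_coexpression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, ModulePartition]:
    """Latent-factor expression with planted co-expression modules.

    Each module gene is loading * factor + sqrt(1 - loading^2) * noise with
    a module-specific standard-normal factor per sample; background genes
    are pure noise. Module M1 is drawn from the planted DE gene set so
    that module-signature enrichment has a planted positive. Returns the
    expression (genes x samples) and the true partition.
    """
    cfg = config
    n_mod_genes = cfg.coexpr_n_modules * cfg.coexpr_module_size
    if n_mod_genes > cfg.coexpr_n_genes:
        raise ValueError("modules do not fit inside coexpr_n_genes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    genes = np.array(_gene_ids(cfg.n_genes), dtype=object)
    planted_idx = _planted_set(cfg)
    planted = list(genes[planted_idx])
    others = list(genes[np.setdiff1d(np.arange(cfg.n_genes), planted_idx)])
    rng.shuffle(planted)
    rng.shuffle(others)

    module_genes: list[list[str]] = []
    for m in range(cfg.coexpr_n_modules):
        pool = planted if m == 0 and len(planted) >= cfg.coexpr_module_size else others
        module_genes.append([pool.pop() for _ in range(cfg.coexpr_module_size)])
    background = [others.pop() for _ in range(cfg.coexpr_n_genes - n_mod_genes)]

    a = cfg.coexpr_loading
    n_s = cfg.coexpr_n_samples
    rows: list[np.ndarray] = []
    index: list[str] = []
    labels: dict[str, str] = {}
    for m, members in enumerate(module_genes, start=1):
        factor = rng.standard_normal(n_s)
        for g in members:
            noise = rng.standard_normal(n_s)
            rows.append(a * factor + np.sqrt(max(0.0, 1.0 - a * a)) * noise)
            index.append(g)
            labels[g] = f"M{m}"
    for g in background:
        rows.append(rng.standard_normal(n_s))
        index.append(g)
        labels[g] = UNASSIGNED
    expr = pd.DataFrame(
        np.vstack(rows), index=index, columns=[f"S{j + 1:03d}" for j in range(n_s)]
    )
    # shuffle gene order so downstream clustering cannot exploit construction order
    perm = rng.permutation(len(index))
    expr = expr.iloc[perm]
    truth = ModulePartition(
        labels=labels,
        params={"loading": a, "module_size": cfg.coexpr_module_size},
    )
    return expr, truth
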