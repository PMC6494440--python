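"""Key-driver analysis on directed causal gene networks.

A key driver is a node whose downstream neighborhood — the genes reachable
within a few directed hops — is statistically enriched for a
trait-associated signature. This module builds the union of causal
networks from multiple cohorts, extracts shortest-distance layers below a
seed gene, scores per-layer (or cumulative) signature enrichment, and
ranks every candidate node genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .overlap import overlap_enrichment
from .stats import EnrichmentResult, bh_adjust

__all__ = [
    "CausalNetwork",
    "LayeredNeighborhood",
    "union_network",
    "downstream_layers",
    "layer_enrichment",
    "rank_key_drivers",
]


@dataclass
class CausalNetwork:
    """Directed graph over gene symbols with per-edge cohort provenance.

    Self-loops are rejected at construction; a duplicate edge merges its
    cohort tags onto the existing arc. Oppositely directed arcs between
    the same pair are distinct edges.
    """

    graph: nx.DiGraph
    name: str = ""
    n_self_loops_dropped: int = 0

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, str]],
        name: str = "",
        nodes: Optional[Iterable[str]] = None,
        drop_self_loops: bool = False,
    ) -> "CausalNetwork":
        g = nx.DiGraph()
        n_loops = 0
        for edge in edges:
            src, dst = edge[0], edge[1]
            cohort = edge[2] if len(edge) > 2 and edge[2] else name
            if src == dst:
                if drop_self_loops:
                    n_loops += 1
                    continue
                raise ValueError(f"self-loop on node {src!r}")
            if g.has_edge(src, dst):
                g.edges[src, dst]["cohorts"].add(cohort)
            else:
                g.add_edge(src, dst, cohorts={cohort})
        if nodes is not None:
            g.add_nodes_from(nodes)
        net = cls(graph=g, name=name)
        net.n_self_loops_dropped = n_loops
        return net

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, frozenset[str]]]:
        return [
            (u, v, frozenset(d["cohorts"])) for u, v, d in self.graph.edges(data=True)
        ]


@dataclass(frozen=True)
class LayeredNeighborhood:
    """Disjoint shortest-distance layers downstream of a seed gene.

    ``layers[i]`` holds the nodes at directed distance i+1 from the seed;
    the seed itself belongs to no layer and cycles cause no revisit.
    """

    seed: str
    layers: tuple[frozenset[str], ...]
    max_depth: int

    def __post_init__(self) -> None:
        seen: set[str] = {self.seed}
        for layer in self.layers:
            if layer & seen:
                raise ValueError("layers must be pairwise disjoint and exclude the seed")
            seen |= layer

    def cumulative(self, depth: Optional[int] = None) -> frozenset[str]:
        """Union of layers 1..depth (all layers when depth is None)."""
        depth = len(self.layers) if depth is None else depth
        out: set[str] = set()
        for layer in self.layers[:depth]:
            out |= layer
        return frozenset(out)


def union_network(networks: Sequence[CausalNetwork], name: str = "union") -> CausalNetwork:
    """Edge-set union of causal networks with cohort tags merged.

    Idempotent and commutative up to tags; the result is a general digraph
    (cycles allowed) even when every input is a DAG.
    """
    if not networks:
        raise ValueError("need at least one network")
    g = nx.DiGraph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            if g.has_edge(u, v):
                g.edges[u, v]["cohorts"] |= set(d["cohorts"])
            else:
                g.add_edge(u, v, cohorts=set(d["cohorts"]))
    return CausalNetwork(graph=g, name=name)


def downstream_layers(
    network: CausalNetwork, seed: str, max_depth: int = 4
) -> LayeredNeighborhood:
    """Breadth-first shortest-distance layers below a seed over outgoing edges."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if seed not in network.graph:
        raise ValueError(f"seed gene {seed!r} not in network")
    dist = nx.single_source_shortest_path_length(network.graph, seed, cutoff=max_depth)
    layers = [set() for _ in range(max_depth)]
    for node, d in dist.items():
        if d >= 1:
            layers[d - 1].add(node)
    return LayeredNeighborhood(
        seed=seed,
        layers=tuple(frozenset(s) for s in layers),
        max_depth=max_depth,
    )


def layer_enrichment(
    neighborhood: LayeredNeighborhood,
    signature: Iterable[str],
    universe: Iterable[str],
    cumulative: bool = False,
) -> list[EnrichmentResult]:
    """Signature enrichment of each neighborhood layer within a universe.

    Layers (and the signature) are first restricted to the universe. With
    ``cumulative`` the i-th result scores the union of layers 1..i+1
    instead of layer i+1 alone.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    sig = frozenset(signature) & uni
    results = []
    for i in range(len(neighborhood.layers)):
        genes = (
            neighborhood.cumulative(i + 1) if cumulative else neighborhood.layers[i]
        ) & uni
        results.append(
            overlap_enrichment(genes, sig, uni, name=f"{neighborhood.seed}_L{i + 1}")
        )
    return results


def rank_key_drivers(
    network: CausalNetwork,
    signature: Iterable[str],
    universe: Iterable[str],
    max_depth: int = 4,
) -> pd.DataFrame:
    """Rank every node by enrichment of its cumulative downstream neighborhood.

    Candidates are the nodes with a non-empty downstream neighborhood
    (restricted to the universe) within ``max_depth`` hops. P-values are
    BH-adjusted across candidates; ties break deterministically by larger
    fold enrichment, then larger neighborhood, then node name.
    """
    uni = frozenset(universe)
    sig = frozenset(signature) & uni
    if not sig:
        raise ValueError("signature is empty within the universe")
    rows = []
    for node in sorted(network.graph.nodes):
        nbhd = downstream_layers(network, node, max_depth).cumulative() & uni
        if not nbhd:
            continue
        res = overlap_enrichment(nbhd, sig, uni, name=node)
        rows.append(
            {
                "driver": node,
                "neighborhood_size": len(nbhd),
                "overlap": res.overlap,
                "fold_enrichment": res.fold_enrichment,
                "p": res.p_value,
            }
        )
    if not rows:
        raise ValueError("no node has a non-empty downstream neighborhood")
    table = pd.DataFrame(rows)
    table["adjusted_p"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(
        by=["adjusted_p", "fold_enrichment", "neighborhood_size", "driver"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    return table
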