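"""Weighted co-expression modules and module-signature enrichment.

An unsigned weighted network is built by soft-thresholding absolute
Pearson correlations, converted to the topological overlap measure (TOM),
and clustered by average-linkage hierarchical clustering on 1 - TOM with
a static tree cut. Modules below the minimum size are labelled
"unassigned". Each module is then scored against a gene signature by
hypergeometric enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .overlap import overlap_enrichment
from .stats import bh_adjust

__all__ = [
    "ModulePartition",
    "UNASSIGNED",
    "correlation_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_enrichment",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ModulePartition:
    """Gene -> module label partition with the parameters that produced it."""

    labels: dict[str, str]
    params: dict[str, float]

    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def modules(self) -> dict[str, frozenset[str]]:
        """Assigned modules only (the unassigned remainder is excluded)."""
        out: dict[str, set[str]] = {}
        for gene, lab in self.labels.items():
            if lab != UNASSIGNED:
                out.setdefault(lab, set()).add(gene)
        return {k: frozenset(v) for k, v in out.items()}


def correlation_adjacency(expression: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |pearson(g_i, g_j)|^beta.

    Rows are genes, columns samples; the diagonal is 1. A zero-variance
    gene has no defined correlation and raises, naming the gene.
    """
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    vals = expression.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = list(expression.index[sd == 0][:5])
        raise ValueError(f"zero-variance gene(s): {bad}")
    adj = np.abs(np.corrcoef(vals)) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expression.index, columns=expression.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap measure from an adjacency in [0, 1] with unit diagonal.

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    the numerator sum and the connectivities k exclude i and j themselves;
    the diagonal is 1. Values stay in [0, 1].
    """
    a = adjacency.to_numpy(dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    k = a.sum(axis=0) - 1.0  # connectivity excluding self
    shared = a @ a - 2.0 * a  # sum over u != i, j of a_iu * a_uj
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame, min_size: int = 30, cut_height: float = 0.98
) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM with a static cut.

    The dendrogram is cut at ``cut_height`` on the dissimilarity scale;
    resulting clusters smaller than ``min_size`` are labelled
    ``unassigned``. Surviving modules are named M1, M2, ... in decreasing
    size (ties broken by first member) so labels are gene-order invariant
    up to renaming.
    """
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    genes = list(tom.index)
    clusters: dict[int, list[str]] = {}
    for gene, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(gene)
    kept = [m for m in clusters.values() if len(m) >= min_size]
    kept.sort(key=lambda m: (-len(m), sorted(m)[0]))
    labels = {g: UNASSIGNED for g in genes}
    for i, members in enumerate(kept, start=1):
        for g in members:
            labels[g] = f"M{i}"
    return ModulePartition(
        labels=labels, params={"min_size": min_size, "cut_height": cut_height}
    )


def module_enrichment(
    partition: ModulePartition,
    signature: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of the signature in each module, BH across modules."""
    uni = frozenset(universe)
    sig = frozenset(signature) & uni
    modules = partition.modules()
    for name, genes in modules.items():
        extra = genes - uni
        if extra:
            raise ValueError(
                f"module {name!r} contains genes outside the universe: {sorted(extra)[:5]}"
            )
    names = sorted(modules, key=lambda n: (-len(modules[n]), n))
    results = [overlap_enrichment(modules[n], sig, uni, name=n) for n in names]
    table = pd.DataFrame(
        {
            "module": names,
            "size": [len(modules[n]) for n in names],
            "overlap": [r.overlap for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "p": [r.p_value for r in results],
        }
    )
    table["adjusted_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table.sort_values(["adjusted_p", "p"], kind="mergesort").reset_index(drop=True)
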