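"""Readers and writers for the pipeline's plain-text formats.

Counts and metadata travel as TSV, networks as 2-3 column edge lists or
SIF, gene-set collections as GMT. Lines starting with ``#`` are treated
as comments everywhere, which is how output headers carry the seed and
configuration hash.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .de import CountMatrix, Signature
from .keydriver import CausalNetwork

__all__ = [
    "load_counts",
    "write_counts",
    "load_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_mapping",
]

logger = logging.getLogger("netkda")


def load_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus sample metadata into a CountMatrix.

    The count file's first column holds gene symbols, the header sample
    identifiers. Metadata needs ``sample_id`` and ``genotype`` columns
    covering every count sample. Non-integer cells, duplicated genes, and
    metadata/sample mismatches raise specific errors.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicated gene symbol(s) in {counts_path}: {dups[:5]}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        as_float = df.to_numpy(dtype=float)
        if np.any(as_float != np.round(as_float)) or np.any(~np.isfinite(as_float)):
            bad = df.columns[np.any(as_float != np.round(as_float), axis=0)]
            raise ValueError(f"non-integer counts in column(s): {list(bad)[:5]}")
        vals = as_float.astype(np.int64)
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "genotype"):
        if col not in meta.columns:
            raise ValueError(f"metadata {metadata_path} lacks required column {col!r}")
    meta = meta.set_index("sample_id")
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing sample(s): {missing}")
    return CountMatrix(
        counts=vals,
        gene_ids=tuple(df.index),
        sample_ids=tuple(df.columns),
        genotype=tuple(meta.loc[s, "genotype"] for s in df.columns),
    )


def write_counts(
    cm: CountMatrix,
    counts_path: str | Path,
    metadata_path: str | Path,
    header_comment: Optional[str] = None,
) -> None:
    df = pd.DataFrame(
        cm.counts, index=list(cm.gene_ids), columns=list(cm.sample_ids)
    )
    df.index.name = "gene"
    _write_tsv(df, counts_path, header_comment, index=True)
    meta = pd.DataFrame(
        {"sample_id": list(cm.sample_ids), "genotype": list(cm.genotype)}
    )
    _write_tsv(meta, metadata_path, header_comment, index=False)


def load_network(
    path: str | Path, dialect: str = "edge_tsv", name: str = ""
) -> CausalNetwork:
    """Read a directed network from an edge-list TSV or a SIF file.

    ``edge_tsv`` lines are ``source<TAB>target[<TAB>cohort]``; ``sif``
    lines are whitespace-separated ``source relation target [target ...]``.
    Self-loops are dropped with a logged count; malformed lines raise with
    their line number.
    """
    if dialect not in ("edge_tsv", "sif"):
        raise ValueError(f"unknown network dialect {dialect!r}")
    edges: list[tuple[str, str, str]] = []
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "edge_tsv":
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}:{lineno}: malformed edge line: {line!r}")
                cohort = parts[2] if len(parts) > 2 else ""
                edges.append((parts[0], parts[1], cohort))
                nodes.update(parts[:2])
            else:
                parts = line.split()
                if len(parts) == 1:
                    nodes.add(parts[0])
                    continue
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed SIF line: {line!r}")
                src, relation = parts[0], parts[1]
                for dst in parts[2:]:
                    edges.append((src, dst, relation))
                    nodes.update((src, dst))
    net = CausalNetwork.from_edges(
        edges, name=name or Path(path).stem, nodes=nodes, drop_self_loops=True
    )
    if net.n_self_loops_dropped:
        logger.warning(
            "%s: dropped %d self-loop(s)", path, net.n_self_loops_dropped
        )
    return net


def write_network(
    net: CausalNetwork, path: str | Path, header_comment: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for u, v, cohorts in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{','.join(sorted(cohorts))}\n")


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set file: name <TAB> description <TAB> gene..."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            if parts[0] in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {parts[0]!r}")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    description: str = "netkda",
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def signatures_to_gmt(signatures: Iterable[Signature]) -> dict[str, frozenset[str]]:
    """Directional GMT naming convention: <contrast>_UP / <contrast>_DN."""
    out: dict[str, frozenset[str]] = {}
    for sig in signatures:
        out[f"{sig.contrast}_UP"] = frozenset(sig.up)
        out[f"{sig.contrast}_DN"] = frozenset(sig.down)
    return out


def read_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV symbol mapping (source, target)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed mapping line")
            out[parts[0]] = parts[1]
    return out


def _write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    header_comment: Optional[str],
    index: bool,
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_table(
    df: pd.DataFrame, path: str | Path, header_comment: Optional[str] = None
) -> None:
    """Write a result table as TSV with an optional ``#`` header line."""
    _write_tsv(df, path, header_comment, index=False)
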