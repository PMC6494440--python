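"""Direction-aware intersection of gene signatures with enrichment statistics.

Every pairwise overlap is scored by the hypergeometric upper tail (the
one-sided Fisher exact test) and fold enrichment within an explicit gene
universe, then BH-adjusted across the requested family of pairs. Also
provides symbol-level ortholog mapping for cross-species intersections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .stats import EnrichmentResult, bh_adjust, fold_enrichment, hypergeom_tail

__all__ = [
    "SignatureCollection",
    "OrthologReport",
    "overlap_enrichment",
    "overlap_matrix",
    "map_orthologs",
]


@dataclass(frozen=True)
class SignatureCollection:
    """Named direction-tagged gene sets over a shared universe."""

    signatures: dict[str, frozenset[str]]
    universe: frozenset[str]
    species_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "signatures",
            {name: frozenset(genes) for name, genes in self.signatures.items()},
        )
        object.__setattr__(self, "universe", frozenset(self.universe))
        for name, genes in self.signatures.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"signature {name!r} contains genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.signatures[name]

    def names(self) -> list[str]:
        return list(self.signatures)


@dataclass(frozen=True)
class OrthologReport:
    """Outcome of a symbol mapping: the mapped set plus what was dropped."""

    mapped: frozenset[str]
    dropped: frozenset[str]

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def overlap_enrichment(
    sig_a: Iterable[str],
    sig_b: Iterable[str],
    universe: Iterable[str],
    name: str = "",
) -> EnrichmentResult:
    """Hypergeometric enrichment of the intersection of two gene sets.

    Symmetric in its two sets. An empty set yields p = 1 and fold
    enrichment 0 (no evidence either way).
    """
    a, b, uni = frozenset(sig_a), frozenset(sig_b), frozenset(universe)
    if len(uni) < 2:
        raise ValueError("universe must contain at least 2 genes")
    for label, s in (("first", a), ("second", b)):
        extra = s - uni
        if extra:
            raise ValueError(
                f"{label} set contains genes outside the universe: {sorted(extra)[:5]}"
            )
    k, n1, n2, N = len(a & b), len(a), len(b), len(uni)
    if n1 == 0 or n2 == 0:
        return EnrichmentResult(k, n1, n2, N, 0.0, 1.0, name=name)
    return EnrichmentResult(
        overlap=k,
        set1_size=n1,
        set2_size=n2,
        universe_size=N,
        fold_enrichment=fold_enrichment(k, n1, n2, N),
        p_value=hypergeom_tail(k, n1, n2, N),
        name=name,
    )


def overlap_matrix(
    collection: SignatureCollection,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Enrichment for each requested signature pair, BH-adjusted as a family.

    Duplicate pairs collapse to a single row; rows are sorted by adjusted
    p (then raw p). All counts are carried so every p is recomputable.
    """
    seen: list[tuple[str, str]] = []
    for pair in pairs:
        for name in pair:
            if name not in collection.signatures:
                raise ValueError(f"unknown signature name {name!r}")
        if pair not in seen:
            seen.append(pair)
    results = [
        overlap_enrichment(
            collection[a], collection[b], collection.universe, name=f"{a}|{b}"
        )
        for a, b in seen
    ]
    adj = bh_adjust([r.p_value for r in results])
    rows = pd.DataFrame(
        {
            "set_a": [a for a, _ in seen],
            "set_b": [b for _, b in seen],
            "overlap": [r.overlap for r in results],
            "n_a": [r.set1_size for r in results],
            "n_b": [r.set2_size for r in results],
            "universe": [r.universe_size for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "p": [r.p_value for r in results],
            "adjusted_p": adj,
        }
    )
    return rows.sort_values(["adjusted_p", "p"], kind="mergesort").reset_index(drop=True)


def map_orthologs(
    signature: Iterable[str],
    mapping: Optional[Mapping[str, str]] = None,
) -> OrthologReport:
    """Map gene symbols across species, dropping unmapped/ambiguous genes.

    With no explicit table the default policy is case-insensitive symbol
    identity rendered in upper case (mouse "Trem2" -> human "TREM2"). An
    explicit mapping is applied case-insensitively on its keys; genes
    whose key maps to more than one target are dropped and reported.
    """
    genes = set(signature)
    if mapping is None:
        return OrthologReport(
            mapped=frozenset(g.upper() for g in genes), dropped=frozenset()
        )
    by_key: dict[str, set[str]] = {}
    for src, dst in mapping.items():
        by_key.setdefault(src.upper(), set()).add(dst)
    mapped: set[str] = set()
    dropped: set[str] = set()
    for g in genes:
        targets = by_key.get(g.upper(), set())
        if len(targets) == 1:
            mapped.add(next(iter(targets)))
        else:
            dropped.add(g)
    return OrthologReport(mapped=frozenset(mapped), dropped=frozenset(dropped))
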