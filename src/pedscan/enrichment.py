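"""Hypergeometric over-representation analysis of gene lists.

Given a query gene list of size n drawn from a universe of N genes and a
term annotating K genome genes, the enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution at the observed overlap k.
Bonferroni adjustment multiplies by the number of annotations in the
term's category.  A sensitivity rerun drops all but one query gene per
linkage region before recomputing, to guard against colocated genes
inflating a term through a single shared haplotype.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .linkage import LinkageRegion

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "bonferroni_adjust",
    "colocated_sensitivity",
    "read_gmt",
    "enrichment_table",
]

CATEGORIES = (
    "biological_process",
    "molecular_function",
    "disease",
    "transcription_factor",
    "pathway",
)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: term id, label, category, members, genome hits."""

    id: str
    label: str
    category: str
    members: frozenset
    genome_hits: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(str(g).upper() for g in self.members)
        )
        if self.genome_hits is not None and self.genome_hits < len(self.members):
            # genome annotation count can exceed, never undercut, the listed members
            raise ValueError(f"{self.id}: genome_hits < number of member genes")

    @property
    def K(self) -> int:
        return self.genome_hits if self.genome_hits is not None else len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    term: GeneSet
    k: int
    n: int
    K: int
    N: int
    p: float
    p_adjusted: float | None = None
    overlap: frozenset = frozenset()


def hypergeometric_enrichment(
    query: Iterable[str], term: GeneSet, N: int = 20_000
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``query`` in ``term``.

    N is the universe size (default: ~20,000 protein-coding genes); the
    term's K is its genome annotation count.  k = 0 gives p = 1 by the
    vacuous upper tail.
    """
    q = {str(g).upper() for g in query}
    n, K = len(q), term.K
    if K > N or n > N:
        raise ValueError(f"{term.id}: K={K} or n={n} exceeds universe N={N}")
    overlap = q & term.members
    k = len(overlap)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(term=term, k=k, n=n, K=K, N=N, p=min(p, 1.0), overlap=frozenset(overlap))


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, p * m) for m annotations tested in the category."""
    if m < 1:
        raise ValueError("annotation count m must be >= 1")
    return min(1.0, p * m)


def colocated_sensitivity(
    query: Iterable[str],
    term: GeneSet,
    regions: Sequence[LinkageRegion],
    gene_positions: Mapping[str, tuple[str, int]],
    N: int = 20_000,
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Enrichment rerun after thinning colocated overlap genes.

    For every linkage region contributing two or more overlap genes to the
    term, all but one are dropped from the query (keeping the gene with the
    lowest genomic position) and the enrichment is recomputed.  Genes whose
    position cannot be resolved are retained with a warning.  Returns
    (original, rerun); with no colocated pair the rerun equals the original.
    """
    q = {str(g).upper() for g in query}
    original = hypergeometric_enrichment(q, term, N)
    positions = {str(g).upper(): v for g, v in gene_positions.items()}
    drop: set[str] = set()
    for region in regions:
        in_region = []
        for g in sorted(original.overlap):
            if g not in positions:
                warnings.warn(f"no position for gene {g}; retained in rerun")
                continue
            chrom, pos = positions[g]
            if str(chrom) == region.chrom and region.start <= pos <= region.end:
                in_region.append((pos, g))
        if len(in_region) >= 2:
            in_region.sort()
            drop.update(g for _, g in in_region[1:])
    rerun = hypergeometric_enrichment(q - drop, term, N)
    return original, rerun


def read_gmt(
    path: str | Path,
    category: str = "pathway",
    genome_hits: Mapping[str, int] | None = None,
) -> list[GeneSet]:
    """Read GMT gene sets (term id, description, member symbols per line).

    GMT carries no category or genome-count fields; ``category`` applies to
    every set and ``genome_hits`` may supply per-term genome annotation
    counts (defaulting to the member count).
    """
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        tid, label, members = fields[0], fields[1], fields[2:]
        sets.append(
            GeneSet(
                id=tid,
                label=label,
                category=category,
                members=frozenset(members),
                genome_hits=(genome_hits or {}).get(tid),
            )
        )
    return sets


def enrichment_table(
    query: Iterable[str],
    terms: Sequence[GeneSet],
    N: int = 20_000,
    category_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Enrichment of a query against many terms, Bonferroni-adjusted.

    ``category_counts`` maps category -> number of annotations tested in
    that category (the Bonferroni multiplier); by default the number of
    supplied terms per category.
    """
    q = {str(g).upper() for g in query}
    if category_counts is None:
        category_counts = {}
        for t in terms:
            category_counts[t.category] = category_counts.get(t.category, 0) + 1
    rows = []
    for t in terms:
        r = hypergeometric_enrichment(q, t, N)
        m = category_counts.get(t.category, 1)
        rows.append(
            (
                t.category,
                t.id,
                t.label,
                ",".join(sorted(r.overlap)),
                r.k,
                r.K,
                r.p,
                bonferroni_adjust(r.p, m),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "CATEGORY",
            "TERM",
            "DESCRIPTION",
            "GENES",
            "K_SELECTED",
            "K_GENOME",
            "P",
            "P_ADJUSTED",
        ],
    ).sort_values("P").reset_index(drop=True)
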