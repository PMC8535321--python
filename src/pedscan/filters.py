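"""Category-specific rare-variant prioritization cascade.

Stages, applied as independent predicates whose conjunction defines the
surviving set:

1. segregation: carried by every affected family member (healthy carriage
   does not exclude a variant);
2. frequency: below the MAF threshold in every populated reference
   database column, or absent from all of them;
3. function: category-specific in-silico evidence (high-impact categories
   always qualify; missense needs CADD or a 2-of-5 tool consensus;
   synonymous and - in the exome context - non-coding classes need any one
   regulatory/splicing predictor; in the genome context non-coding classes
   need SpliceAI alone);
4. optional linkage-region intersection;
5. association evidence: nominally significant in at least one external
   cohort, or absent from all of them.

Absent scores never satisfy a criterion: a missing prediction is not
evidence of impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SummaryStatsTable, VariantKey
from .linkage import LinkageRegion

__all__ = [
    "CATEGORIES",
    "HIGH_IMPACT_CATEGORIES",
    "NONCODING_CATEGORIES",
    "MISSENSE_TOOLS",
    "AnnotatedVariant",
    "FilterReport",
    "shared_by_affected",
    "frequency_pass",
    "functional_pass",
    "association_evidence_pass",
    "intersect_linkage_regions",
    "run_cascade",
]

CATEGORIES = frozenset(
    {
        "missense",
        "synonymous",
        "splicing",
        "frameshift_indel",
        "nonframeshift_indel",
        "stopgain",
        "stoploss",
        "ncRNA",
        "UTR",
        "intronic",
        "upstream",
    }
)
HIGH_IMPACT_CATEGORIES = frozenset(
    {"splicing", "frameshift_indel", "nonframeshift_indel", "stopgain", "stoploss"}
)
NONCODING_CATEGORIES = frozenset({"ncRNA", "UTR", "intronic", "upstream"})
MISSENSE_TOOLS = ("sift", "polyphen", "mutation_taster", "mutation_assessor", "fathmm")
FREQUENCY_COLUMNS = ("kg_eur", "gnomad_nfe", "exac_nfe")

STAGES = ("shared", "frequency", "functional", "linkage", "association")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated variant record: the substrate of the cascade."""

    key: VariantKey
    gene: str
    category: str
    freqs: Mapping[str, float] = field(default_factory=dict)
    scores: Mapping[str, float] = field(default_factory=dict)
    missense_calls: Mapping[str, str] = field(default_factory=dict)
    carriers: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown variant category {self.category!r}")
        for col, v in self.freqs.items():
            if not _missing(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.key}: frequency {col}={v} outside [0, 1]")
        for tool, call in self.missense_calls.items():
            if call not in ("damaging", "tolerated", "absent"):
                raise ValueError(f"{self.key}: invalid {tool} call {call!r}")


def shared_by_affected(v: AnnotatedVariant, affected: Iterable[str]) -> bool:
    """True iff every affected member is a carrier (strict subset rule)."""
    affected = set(affected)
    if not affected:
        raise ValueError("affected set must be non-empty")
    return affected <= set(v.carriers)


def frequency_pass(
    v: AnnotatedVariant, threshold: float = 0.05, mode: str = "all"
) -> bool:
    """MAF filter against the reference database columns.

    ``mode='all'`` (default): every populated column must be below the
    threshold; ``mode='any'``: one populated column below threshold
    suffices.  A variant absent from all databases passes either way.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    populated = [
        v.freqs[c] for c in FREQUENCY_COLUMNS if c in v.freqs and not _missing(v.freqs[c])
    ]
    if not populated:
        return True
    if mode == "all":
        return all(f < threshold for f in populated)
    if mode == "any":
        return any(f < threshold for f in populated)
    raise ValueError(f"unknown frequency mode {mode!r}")


def _score(v: AnnotatedVariant, name: str) -> float | None:
    x = v.scores.get(name)
    return None if _missing(x) else float(x)


def _regulatory_evidence(v: AnnotatedVariant) -> bool:
    cadd = _score(v, "cadd_phred")
    gwava = _score(v, "gwava")
    gerp = _score(v, "gerp")
    spidex = _score(v, "spidex")
    splice_ai = _score(v, "splice_ai")
    return (
        (cadd is not None and cadd > 10)
        or (gwava is not None and gwava > 0.5)
        or (gerp is not None and gerp > 4)
        or (spidex is not None and abs(spidex) > 4)
        or (splice_ai is not None and splice_ai > 0.4)
    )


def functional_pass(v: AnnotatedVariant, context: str = "wes") -> bool:
    """Category-specific functional-impact rule.

    ``context`` is ``'wes'`` (exome: non-coding classes use the full
    predictor battery) or ``'wgs'`` (genome: non-coding classes require
    SpliceAI > 0.4 alone).
    """
    if context not in ("wes", "wgs"):
        raise ValueError(f"unknown context {context!r}")
    if v.category in HIGH_IMPACT_CATEGORIES:
        return True
    if v.category == "missense":
        cadd = _score(v, "cadd_phred")
        if cadd is not None and cadd > 10:
            return True
        damaging = sum(
            1 for t in MISSENSE_TOOLS if v.missense_calls.get(t) == "damaging"
        )
        return damaging >= 2
    if v.category == "synonymous":
        return _regulatory_evidence(v)
    if v.category in NONCODING_CATEGORIES:
        if context == "wes":
            return _regulatory_evidence(v)
        splice_ai = _score(v, "splice_ai")
        return splice_ai is not None and splice_ai > 0.4
    raise ValueError(f"unknown variant category {v.category!r}")


def association_evidence_pass(
    v: AnnotatedVariant, stats: SummaryStatsTable, alpha: float = 0.05
) -> bool:
    """Retain variants nominally significant in, or absent from, all cohorts.

    True iff the key is nominally significant (p < alpha) in at least one
    cohort where it is present, or absent from every cohort.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    ps = stats.pvalues(v.key)
    if not ps:
        return True
    return any(p < alpha for p in ps.values())


def intersect_linkage_regions(
    variants: Sequence[AnnotatedVariant], regions: Sequence[LinkageRegion]
) -> list[AnnotatedVariant]:
    """Variants whose position falls inside any region (inclusive ends)."""
    return [v for v in variants if _in_regions(v, regions)]


def _in_regions(v: AnnotatedVariant, regions: Sequence[LinkageRegion]) -> bool:
    return any(
        v.key.chrom == r.chrom and r.start <= v.key.pos <= r.end for r in regions
    )


class FilterReport:
    """Per-variant, per-stage outcomes of the cascade.

    ``frame`` has one row per (variant, applicable stage) with PASS and the
    failing rule name; ``survivors`` is the conjunction of all stages.
    """

    def __init__(self, frame: pd.DataFrame, variants: Sequence[AnnotatedVariant]):
        self.frame = frame
        self._variants = {str(v.key): v for v in variants}

    @property
    def survivors(self) -> list[AnnotatedVariant]:
        ok = self.frame.groupby("KEY", sort=False).PASS.all()
        return [self._variants[k] for k in ok.index[ok]]

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for v in self.survivors:
            if v.gene not in out:
                out.append(v.gene)
        return out

    def failing_stage(self, key: VariantKey | str) -> str | None:
        """First failing stage for a variant, or None if it survives."""
        sub = self.frame[self.frame.KEY == str(key)]
        failed = sub[~sub.PASS]
        return None if failed.empty else str(failed.STAGE.iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    affected: Iterable[str],
    stats: SummaryStatsTable | None = None,
    context: str = "wes",
    regions: Sequence[LinkageRegion] | None = None,
    maf_threshold: float = 0.05,
    freq_mode: str = "all",
    alpha: float = 0.05,
    healthy_members: Iterable[str] | None = None,
) -> FilterReport:
    """Full prioritization cascade with per-stage bookkeeping.

    Stage order: segregation, frequency, function, linkage intersection
    (when regions are given), association evidence (when summary stats are
    given).  The stages are independent predicates, so the surviving set
    does not depend on their order; the report records each stage's verdict
    for every variant regardless of earlier failures.

    ``healthy_members``, when given, adds a NOT_IN_HEALTHY annotation flag
    (variant carried by no listed healthy member) used for prioritization
    commentary, never as a filter.
    """
    affected = set(affected)
    rows = []
    healthy = set(healthy_members) if healthy_members is not None else None
    for v in variants:
        checks: list[tuple[str, bool, str]] = [
            ("shared", shared_by_affected(v, affected), "not carried by every affected"),
            (
                "frequency",
                frequency_pass(v, threshold=maf_threshold, mode=freq_mode),
                f"MAF >= {maf_threshold} in a populated database",
            ),
            (
                "functional",
                functional_pass(v, context=context),
                "no qualifying functional prediction",
            ),
        ]
        if regions is not None:
            checks.append(
                ("linkage", _in_regions(v, regions), "outside all linkage regions")
            )
        if stats is not None:
            checks.append(
                (
                    "association",
                    association_evidence_pass(v, stats, alpha=alpha),
                    "present but not nominally significant in any cohort",
                )
            )
        flag = bool(healthy and not (set(v.carriers) & healthy)) if healthy is not None else None
        for stage, ok, rule in checks:
            rows.append(
                {
                    "KEY": str(v.key),
                    "GENE": v.gene,
                    "CATEGORY": v.category,
                    "STAGE": stage,
                    "PASS": ok,
                    "RULE": "" if ok else rule,
                    "NOT_IN_HEALTHY": flag,
                }
            )
    frame = pd.DataFrame(rows)
    return FilterReport(frame, variants)
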