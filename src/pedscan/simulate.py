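"""Synthetic pedigree genotypes, annotated variant tables and score cohorts.

Everything downstream of raw sequencing is exercisable on data produced
here: Mendelian gene dropping through an arbitrary pedigree with
map-based recombination and an optional disease-linked locus; annotated
variant fixtures whose ground-truth pass/fail design labels every stage
of the filtering cascade; and case/control dosage cohorts drawn under a
logistic liability model for risk-score analyses.

A single integer seed drives one pseudo-random stream per call; a fixed
seed reproduces every table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filters import AnnotatedVariant
from .io import (
    GenotypeTable,
    SummaryStatsTable,
    VariantKey,
    haldane_theta,
)
from .pedigree import Pedigree, index_family

__all__ = [
    "SimulationConfig",
    "DiseaseLocus",
    "AnnotationProfile",
    "CohortModel",
    "SimulationError",
    "gene_drop",
    "gene_drop_with_origins",
    "simulate_annotated_variants",
    "simulate_wgrs_cohort",
    "AnnotatedVariantFixture",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class DiseaseLocus:
    """A disease-linked locus for conditioned gene dropping.

    The disease allele rides on one designated founder haplotype
    (``founder``/``haplotype``; default: first founder, haplotype 0).
    Rules:

    * ``shared``: every affected member carries the designated haplotype
      identical by descent at the locus;
    * ``penetrant``: additionally, no unaffected non-founder carries it
      (founders are exempt: the transmitting founder necessarily carries).
    """

    chrom: str = "1"
    pos: int = 0
    rule: str = "shared"
    founder: str | None = None
    haplotype: int = 0

    def __post_init__(self) -> None:
        if self.rule not in ("shared", "penetrant"):
            raise SimulationError(f"unknown disease-locus rule {self.rule!r}")


@dataclass(frozen=True)
class AnnotationProfile:
    """Design of a filter-cascade fixture: how many variants pass, and how
    the failing ones are spread across the stages."""

    n_variants: int = 20
    n_pass: int = 5
    fail_stages: Sequence[str] = ("shared", "frequency", "functional", "association")
    score_columns: Sequence[str] = (
        "cadd_phred",
        "gwava",
        "gerp",
        "spidex",
        "splice_ai",
    )
    maf_threshold: float = 0.05


@dataclass(frozen=True)
class CohortModel:
    """Case/control cohort drawn under a logistic liability model."""

    n_cases: int = 500
    n_controls: int = 500
    odds_ratios: Sequence[float] = (1.2,) * 10
    freqs: Sequence[float] = (0.3,) * 10
    prevalence: float = 0.15


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for every generator in this module.

    Defaults emulate the data structure of a single three-generation
    multiplex family scanned with a sparse panel of common biallelic
    markers: 20 markers at 2 cM spacing (1 Mb/cM), marker alternate-allele
    frequency 0.4, no disease locus.
    """

    seed: int = 0
    pedigree: Pedigree = field(default_factory=index_family)
    n_markers: int = 20
    allele_freq: float | tuple[float, float] = 0.4
    map_spacing_cm: float = 2.0
    chrom: str = "1"
    start_pos: int = 1_000_000
    bp_per_cm: int = 1_000_000
    disease_locus: DiseaseLocus | None = None
    annotation: AnnotationProfile = field(default_factory=AnnotationProfile)
    cohort: CohortModel = field(default_factory=CohortModel)
    max_rejection_tries: int = 100_000


def _marker_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    af = config.allele_freq
    if isinstance(af, tuple):
        lo, hi = af
        out = rng.uniform(lo, hi, size=config.n_markers)
    else:
        out = np.full(config.n_markers, float(af))
    if np.any((out < 0) | (out > 1)):
        raise SimulationError("allele frequencies outside [0, 1]")
    return out


def _drop_once(
    config: SimulationConfig,
    rng: np.random.Generator,
    afs: np.ndarray,
    thetas: np.ndarray,
):
    """One unconditioned gene drop; returns haplotypes and founder origins."""
    ped = config.pedigree
    M = config.n_markers
    founders = ped.founders
    slot = {f.id: i for i, f in enumerate(founders)}
    haps: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    for f in founders:
        haps[f.id] = (rng.random((2, M)) < afs).astype(np.int8)
        origins[f.id] = np.array(
            [[2 * slot[f.id]] * M, [2 * slot[f.id] + 1] * M], dtype=np.int16
        )
    cols = np.arange(M)
    for nf in ped.nonfounders:
        child_h, child_o = [], []
        for pid in (nf.father_id, nf.mother_id):
            first = rng.integers(0, 2)
            switches = rng.random(M - 1) < thetas
            bits = np.empty(M, dtype=np.int64)
            bits[0] = first
            if M > 1:
                bits[1:] = first ^ np.logical_xor.accumulate(switches)
            child_h.append(haps[pid][bits, cols])
            child_o.append(origins[pid][bits, cols])
        haps[nf.id] = np.stack(child_h)
        origins[nf.id] = np.stack(child_o)
    return haps, origins


def _locus_index(config: SimulationConfig, pos_bp: np.ndarray) -> int:
    dl = config.disease_locus
    if dl.chrom != config.chrom or not (pos_bp[0] <= dl.pos <= pos_bp[-1]):
        raise SimulationError(
            f"disease locus {dl.chrom}:{dl.pos} outside the simulated map"
        )
    return int(np.argmin(np.abs(pos_bp - dl.pos)))


def _locus_condition_met(
    config: SimulationConfig, origins: Mapping[str, np.ndarray], locus_idx: int
) -> bool:
    ped = config.pedigree
    dl = config.disease_locus
    founders = ped.founders
    founder_id = dl.founder or founders[0].id
    slot = {f.id: i for i, f in enumerate(founders)}
    if founder_id not in slot:
        raise SimulationError(f"disease-locus founder {founder_id!r} is not a founder")
    target = 2 * slot[founder_id] + dl.haplotype
    for iid in ped.affected_ids:
        if target not in origins[iid][:, locus_idx]:
            return False
    if dl.rule == "penetrant":
        for m in ped.members:
            if m.affected == "no" and not m.is_founder:
                if target in origins[m.id][:, locus_idx]:
                    return False
    return True


def gene_drop_with_origins(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Gene drop returning both the genotype table and founder-origin labels.

    Origins map each individual to a (2, M) array of founder haplotype
    labels (2f for founder f's first haplotype, 2f+1 for the second); they
    make identity-by-descent directly observable for testing.
    """
    if config.n_markers < 1:
        raise SimulationError("n_markers must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ped = config.pedigree
    M = config.n_markers
    cm = np.arange(M) * config.map_spacing_cm
    pos_bp = (config.start_pos + cm * config.bp_per_cm).astype(np.int64)
    afs = _marker_freqs(config, rng)
    thetas = np.array([haldane_theta(d) for d in np.diff(cm)])
    if config.disease_locus is not None:
        locus_idx = _locus_index(config, pos_bp)
        for _ in range(config.max_rejection_tries):
            haps, origins = _drop_once(config, rng, afs, thetas)
            if _locus_condition_met(config, origins, locus_idx):
                break
        else:
            raise SimulationError(
                "disease-locus conditioning not satisfied within the try budget"
            )
    else:
        haps, origins = _drop_once(config, rng, afs, thetas)
    variants = pd.DataFrame(
        {
            "CHROM": config.chrom,
            "POS": pos_bp,
            "REF": "A",
            "ALT": "G",
            "AF": afs,
            "CM": cm,
        }
    )
    calls = pd.DataFrame(
        {m.id: haps[m.id].sum(axis=0).astype(float) for m in ped.members}
    )
    return GenotypeTable(variants, calls), origins


def gene_drop(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeTable:
    """Mendelian gene drop through the configured pedigree.

    Founder alleles are drawn from the marker allele frequency; transmission
    follows Mendelian segregation with recombination between adjacent
    markers at the Haldane fraction of their cM gap.  With a disease locus
    configured, inheritance is rejection-sampled until the carrier rule
    holds at the locus.
    """
    table, _ = gene_drop_with_origins(config, rng)
    return table


# -- annotated variant fixtures -------------------------------------------

_PASS_CATEGORY_CYCLE = ("missense", "stopgain", "synonymous", "intronic", "splicing")
_FAIL_CATEGORY_CYCLE = ("missense", "synonymous", "intronic", "UTR", "ncRNA")


@dataclass(frozen=True)
class AnnotatedVariantFixture:
    """A designed cascade fixture: variants, ground truth and summary stats."""

    variants: tuple[AnnotatedVariant, ...]
    truth: pd.DataFrame
    stats: SummaryStatsTable


def _passing_annotations(category: str, rng: np.random.Generator):
    scores: dict[str, float] = {}
    calls: dict[str, str] = {}
    if category == "missense":
        if rng.random() < 0.5:
            scores["cadd_phred"] = float(rng.uniform(12, 35))
        else:
            scores["cadd_phred"] = float(rng.uniform(0, 8))
            calls = {"sift": "damaging", "polyphen": "damaging"}
    elif category in ("synonymous", "intronic", "UTR", "ncRNA", "upstream"):
        # SpliceAI evidence passes in both exome and genome contexts
        scores["splice_ai"] = float(rng.uniform(0.45, 0.95))
    # high-impact categories need no scores
    return scores, calls


def _functional_fail_annotations(category: str, rng: np.random.Generator):
    scores = {
        "cadd_phred": float(rng.uniform(0, 6)),
        "gwava": float(rng.uniform(0.0, 0.4)),
        "gerp": float(rng.uniform(-2, 3)),
        "spidex": float(rng.uniform(-3, 3)),
        "splice_ai": float(rng.uniform(0.0, 0.3)),
    }
    calls = {"sift": "damaging"} if category == "missense" else {}
    return scores, calls


def simulate_annotated_variants(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> AnnotatedVariantFixture:
    """Annotated variant table with known per-stage ground truth.

    Each variant is constructed to survive the whole cascade or to fail
    exactly one designated stage (passing every other), so per-stage
    failure attribution is unambiguous.  Carrier lists are drawn over the
    configured pedigree; a companion summary-statistics table drives the
    association stage.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    prof = config.annotation
    ped = config.pedigree
    affected = ped.affected_ids
    if not affected:
        raise SimulationError("pedigree has no affected members")
    healthy = [m.id for m in ped.members if m.affected == "no"]
    needed = {"cadd_phred", "splice_ai"}
    if not needed <= set(prof.score_columns):
        raise SimulationError(
            f"annotation profile must include score columns {sorted(needed)}"
        )
    if prof.n_pass > prof.n_variants:
        raise SimulationError("n_pass exceeds n_variants")
    cohorts = ("immunochip", "exomechip", "mschip")
    stats = SummaryStatsTable()
    variants: list[AnnotatedVariant] = []
    truth_rows = []
    n_fail = prof.n_variants - prof.n_pass
    designs = [None] * prof.n_pass + [
        prof.fail_stages[i % len(prof.fail_stages)] for i in range(n_fail)
    ]
    rng.shuffle(designs)
    for i, fail_stage in enumerate(designs):
        key = VariantKey(config.chrom, 10_000_000 + 1_000 * i, "A", "G")
        gene = f"GENE{i:03d}"
        category = (
            _PASS_CATEGORY_CYCLE[i % len(_PASS_CATEGORY_CYCLE)]
            if fail_stage in (None, "shared", "frequency", "association")
            else _FAIL_CATEGORY_CYCLE[i % len(_FAIL_CATEGORY_CYCLE)]
        )
        carriers = set(affected)
        if healthy and rng.random() < 0.3:
            carriers.add(str(rng.choice(healthy)))
        if fail_stage == "shared":
            carriers.discard(str(rng.choice(affected)))
        if fail_stage == "frequency":
            freqs = {"gnomad_nfe": float(rng.uniform(prof.maf_threshold + 0.01, 0.5))}
        elif rng.random() < 0.2:
            freqs = {}  # absent from every database: passes by the absence clause
        else:
            freqs = {"gnomad_nfe": float(rng.uniform(1e-4, prof.maf_threshold * 0.8))}
        if fail_stage == "functional":
            scores, calls = _functional_fail_annotations(category, rng)
        else:
            scores, calls = _passing_annotations(category, rng)
        if fail_stage == "association":
            for c in cohorts:
                stats.add(key, c, float(rng.uniform(0.1, 0.9)))
        elif rng.random() < 0.5:
            stats.add(key, cohorts[int(rng.integers(len(cohorts)))], float(rng.uniform(1e-4, 0.045)))
        # else: absent from every cohort, passes by the absence clause
        variants.append(
            AnnotatedVariant(
                key=key,
                gene=gene,
                category=category,
                freqs=freqs,
                scores={k: v for k, v in scores.items() if k in prof.score_columns},
                missense_calls=calls,
                carriers=frozenset(carriers),
            )
        )
        truth_rows.append(
            {
                "KEY": str(key),
                "GENE": gene,
                "CATEGORY": category,
                "DESIGN_SURVIVES": fail_stage is None,
                "DESIGN_FAIL_STAGE": fail_stage or "",
            }
        )
    return AnnotatedVariantFixture(
        variants=tuple(variants), truth=pd.DataFrame(truth_rows), stats=stats
    )


# -- multiplex burden cohorts ----------------------------------------------


def multiplex_cohort_pedigrees(
    n_families: int = 28, n_unrelated: int = 30
) -> list[Pedigree]:
    """Pedigree structure of a multiplex replication cohort.

    ``n_families`` nuclear families with at least three affected members
    each (an affected mother and her affected children; every other family
    has a third child, one of whom stays unaffected), plus ``n_unrelated``
    unaffected singleton subjects.  The default sizes mirror a cohort of 28
    multiplex families and 30 unrelated controls (~154 subjects, 84
    affected).
    """
    from .pedigree import Individual

    peds: list[Pedigree] = []
    for f in range(n_families):
        fam = f"FAM{f:02d}"
        three_kids = f % 2 == 1
        members = [
            Individual(f"{fam}_F", sex="male", affected="no"),
            Individual(f"{fam}_M", sex="female", affected="yes"),
            Individual(f"{fam}_C1", f"{fam}_F", f"{fam}_M", affected="yes"),
            Individual(f"{fam}_C2", f"{fam}_F", f"{fam}_M", affected="yes"),
        ]
        if three_kids:
            members.append(
                Individual(f"{fam}_C3", f"{fam}_F", f"{fam}_M", affected="no")
            )
        peds.append(Pedigree(members, family_id=fam))
    for u in range(n_unrelated):
        peds.append(
            Pedigree(
                [Individual(f"HC{u:02d}", affected="no")], family_id=f"HC{u:02d}"
            )
        )
    return peds


def simulate_burden_cohort(
    n_genes: int,
    seed: int = 0,
    pedigrees: Sequence[Pedigree] | None = None,
    variants_per_gene: tuple[int, int] = (2, 5),
    freq_range: tuple[float, float] = (0.01, 0.05),
):
    """Null gene dosages over a multiplex cohort (dosages independent of
    affection): the substrate for burden-test calibration.

    Each gene carries a number of low-frequency variants drawn uniformly
    from ``variants_per_gene`` (inclusive), each an independent biallelic
    marker gene-dropped through every family.  Returns ``(pedigrees,
    genotypes, variant_gene)`` ready for :class:`pedscan.burden.FamilyCohort`.
    """
    rng = np.random.default_rng(seed)
    peds = list(pedigrees) if pedigrees is not None else multiplex_cohort_pedigrees()
    counts = rng.integers(
        variants_per_gene[0], variants_per_gene[1] + 1, size=n_genes
    )
    labels, genes = [], {}
    for g, c in enumerate(counts):
        gene = f"GENE{g:05d}"
        for j in range(c):
            v = f"{gene}_v{j}"
            labels.append(v)
            genes[v] = gene
    n_var = len(labels)
    freqs = rng.uniform(freq_range[0], freq_range[1], size=n_var)
    columns: dict[str, np.ndarray] = {}
    for ped in peds:
        haps: dict[str, np.ndarray] = {}
        for m in ped.topological_order():
            if m.is_founder:
                haps[m.id] = (rng.random((2, n_var)) < freqs).astype(np.int8)
            else:
                pick_f = rng.integers(0, 2, size=n_var)
                pick_m = rng.integers(0, 2, size=n_var)
                cols = np.arange(n_var)
                haps[m.id] = np.stack(
                    [haps[m.father_id][pick_f, cols], haps[m.mother_id][pick_m, cols]]
                )
            columns[m.id] = haps[m.id].sum(axis=0).astype(float)
    genotypes = pd.DataFrame(columns, index=labels)
    return peds, genotypes, genes


# -- case/control dosage cohorts ------------------------------------------


def simulate_wgrs_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Case/control dosages under a logistic liability model.

    Population genotypes are Hardy-Weinberg draws at the configured locus
    frequencies; disease status follows a logistic model whose log odds
    ratios are the configured per-locus effects, with the intercept set so
    the population risk at the mean burden equals the configured
    prevalence.  Subjects are sampled until both quotas are filled.

    Returns ``(dosages, status)``: a subject-by-locus DataFrame and a
    0/1 Series (1 = case).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cm = config.cohort
    if cm.n_cases == 0 or cm.n_controls == 0:
        raise SimulationError("n_cases and n_controls must both be positive")
    ors = np.asarray(cm.odds_ratios, dtype=float)
    freqs = np.asarray(cm.freqs, dtype=float)
    if ors.shape != freqs.shape:
        raise SimulationError("odds_ratios and freqs must have equal length")
    if np.any(ors <= 0):
        raise SimulationError("odds ratios must be positive")
    beta = np.log(ors)
    intercept = np.log(cm.prevalence / (1 - cm.prevalence)) - beta @ (2 * freqs)
    loci = [f"locus{j:02d}" for j in range(len(ors))]
    cases, controls = [], []
    batch = max(4 * (cm.n_cases + cm.n_controls), 256)
    guard = 0
    while len(cases) < cm.n_cases or len(controls) < cm.n_controls:
        guard += 1
        if guard > 1000:
            raise SimulationError("cohort sampling failed to fill quotas")
        g = (rng.random((batch, len(ors))) < freqs).astype(np.int8) + (
            rng.random((batch, len(ors))) < freqs
        ).astype(np.int8)
        eta = intercept + g @ beta
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        for row, case in zip(g, is_case):
            if case and len(cases) < cm.n_cases:
                cases.append(row)
            elif not case and len(controls) < cm.n_controls:
                controls.append(row)
    dosages = pd.DataFrame(
        np.vstack([cases, controls]),
        columns=loci,
        index=[f"case{i:04d}" for i in range(cm.n_cases)]
        + [f"ctrl{i:04d}" for i in range(cm.n_controls)],
        dtype=float,
    )
    status = pd.Series(
        [1] * cm.n_cases + [0] * cm.n_controls, index=dosages.index, name="status"
    )
    return dosages, status
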